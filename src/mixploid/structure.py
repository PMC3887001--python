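"""Population structure: PCA, BIC-selected Gaussian mixtures, Nei distance
and neighbor-joining.

The workflow mirrors standard SNP-panel practice: the presence/absence
encoded, mean-imputed matrix is column-centred (covariance PCA, no scaling)
and decomposed; the leading principal components (default 5) are clustered
with Gaussian mixtures over a range of component counts and covariance
models, the winner chosen by BIC in the ``2·logL − m·ln n`` (maximise)
orientation used by mclust; cluster allele-frequency tables give Nei (1972)
standard genetic distances, and the distance matrix feeds a Saitou–Nei
neighbor-joining tree.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .qc import EncodedMatrix, FreqTable

logger = logging.getLogger(__name__)

_SKLEARN_COV = {"spherical": "spherical", "diagonal": "diag", "full": "full"}


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    """Principal-component scores and spectrum.

    ``explained_fraction`` holds the *full* spectrum (sums to 1 at full
    rank); ``scores``/``loadings`` are truncated to the requested number of
    components.  Signs are fixed deterministically: each loading vector's
    largest-magnitude entry is positive.
    """

    scores: np.ndarray
    explained_fraction: np.ndarray
    loadings: np.ndarray
    sample_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca(encoded: EncodedMatrix, n_components: int = 5) -> PcaResult:
    """Covariance PCA (column-centred, unscaled) of an imputed matrix."""
    if not encoded.is_imputed:
        raise ValueError("PCA requires an imputed matrix (no missing entries)")
    X = encoded.values - encoded.values.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int(np.sum(s > tol))
    k = n_components
    if k > rank:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; truncating",
            stacklevel=2,
        )
        k = rank
    # deterministic sign: largest-|entry| of each loading vector positive
    for j in range(k):
        i_max = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    total = float(np.sum(s**2))
    explained = (s**2 / total) if total > 0 else np.zeros_like(s)
    return PcaResult(
        scores=U[:, :k] * s[:k],
        explained_fraction=explained,
        loadings=Vt[:k].T,
        sample_ids=list(encoded.sample_ids),
    )


# ---------------------------------------------------------------------------
# Gaussian-mixture clustering with BIC model selection
# ---------------------------------------------------------------------------


@dataclass
class GmmModel:
    """A fitted Gaussian mixture and its BIC score.

    ``bic`` uses the maximise orientation ``2·logL − m·ln n`` (m = number of
    free parameters), so larger is better; ``assignments`` are hard
    max-posterior labels 0..K−1.
    """

    K: int
    covariance_model: str
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    loglik: float
    bic: float
    assignments: np.ndarray
    bic_table: pd.DataFrame | None = None


def fit_gmm_bic(
    scores: np.ndarray,
    K_range: Iterable[int] = range(1, 8),
    covariance_models: Sequence[str] = ("spherical", "diagonal", "full"),
    seed: int = 0,
    n_init: int = 5,
    max_iter: int = 500,
    reg_covar: float = 1e-6,
) -> GmmModel:
    """Fit mixtures over (K, covariance model) and return the BIC winner.

    EM runs from k-means-based initialisations with a fixed seed;
    near-singular covariances are regularised by a ridge on the diagonal
    (``reg_covar``); non-convergence falls back to the best iterate with a
    warning (sklearn semantics).
    """
    from sklearn.exceptions import ConvergenceWarning
    from sklearn.mixture import GaussianMixture

    X = np.asarray(scores, dtype=float)
    n = X.shape[0]
    K_range = sorted(set(int(k) for k in K_range))
    if max(K_range) >= n:
        raise ValueError("n_samples must exceed max(K_range)")
    unknown = set(covariance_models) - set(_SKLEARN_COV)
    if unknown:
        raise ValueError(f"unknown covariance model(s): {unknown}")

    best: GmmModel | None = None
    rows = []
    for K in K_range:
        for cm in covariance_models:
            gm = GaussianMixture(
                n_components=K,
                covariance_type=_SKLEARN_COV[cm],
                random_state=seed,
                n_init=n_init,
                max_iter=max_iter,
                reg_covar=reg_covar,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gm.fit(X)
            loglik = float(gm.score(X) * n)
            bic = -float(gm.bic(X))  # 2·logL − m·ln n
            rows.append({"K": K, "model": cm, "loglik": loglik, "bic": bic})
            if best is None or bic > best.bic:
                best = GmmModel(
                    K=K,
                    covariance_model=cm,
                    weights=gm.weights_.copy(),
                    means=gm.means_.copy(),
                    covariances=np.asarray(gm.covariances_).copy(),
                    loglik=loglik,
                    bic=bic,
                    assignments=gm.predict(X),
                )
    assert best is not None
    best.bic_table = pd.DataFrame(rows)
    logger.info(
        "GMM/BIC selected K=%d (%s), BIC=%.2f", best.K, best.covariance_model, best.bic
    )
    return best


# ---------------------------------------------------------------------------
# Nei (1972) standard genetic distance
# ---------------------------------------------------------------------------


def nei_distance(freqs: FreqTable, pop_a: str, pop_b: str) -> float:
    """Nei's standard genetic distance D = −ln(J_XY / √(J_X·J_Y)).

    Identity sums J are accumulated across loci *before* the ratio (GenAlEx
    convention): J_XY = Σ_loci Σ_alleles x·y and similarly for J_X, J_Y.
    Loci with an undefined frequency in either population are dropped.
    Complete divergence (J_XY = 0) returns +inf.  D(X, X) = 0 and D is
    symmetric.
    """
    x = freqs.freq_a.loc[pop_a].to_numpy(dtype=float)
    y = freqs.freq_a.loc[pop_b].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if not ok.any():
        raise ValueError(
            f"no locus with defined frequencies in both {pop_a!r} and {pop_b!r}"
        )
    x, y = x[ok], y[ok]
    j_xy = float(np.sum(x * y + (1 - x) * (1 - y)))
    j_x = float(np.sum(x**2 + (1 - x) ** 2))
    j_y = float(np.sum(y**2 + (1 - y) ** 2))
    if j_xy == 0.0:
        logger.warning("Nei distance %s vs %s: J_XY = 0 → +inf", pop_a, pop_b)
        return float("inf")
    # Cauchy–Schwarz gives J_XY ≤ √(J_X·J_Y), so D ≥ 0 up to rounding
    return max(float(-np.log(j_xy / np.sqrt(j_x * j_y))), 0.0)


def nei_distance_matrix(freqs: FreqTable, groups: Sequence[str] | None = None) -> pd.DataFrame:
    """Symmetric zero-diagonal matrix of pairwise Nei distances."""
    groups = list(groups) if groups is not None else freqs.groups
    D = pd.DataFrame(0.0, index=groups, columns=groups)
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            d = nei_distance(freqs, a, b)
            D.loc[a, b] = D.loc[b, a] = d
    return D


# ---------------------------------------------------------------------------
# Neighbor-joining (Saitou–Nei)
# ---------------------------------------------------------------------------


def neighbor_joining(D: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None):
    """Saitou–Nei neighbor-joining tree from a distance matrix.

    Input must be symmetric with zero diagonal over ≥ 3 labels.  For an
    additive matrix the topology and branch lengths are recovered exactly.
    Negative branch-length estimates are clamped to zero with the deficit
    transferred to the sibling edge, so path lengths through the joined pair
    are preserved.  Returns an ``skbio.TreeNode`` (arbitrarily rooted at the
    final join of the unrooted topology).
    """
    from skbio import TreeNode

    if isinstance(D, pd.DataFrame):
        labels = list(D.index)
        mat = D.to_numpy(dtype=float)
    else:
        mat = np.asarray(D, dtype=float)
        if labels is None:
            labels = [f"t{i + 1}" for i in range(mat.shape[0])]
        labels = list(labels)
    n = mat.shape[0]
    if mat.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix and labels have inconsistent shapes")
    if n < 3:
        raise ValueError("neighbor joining requires ≥ 3 taxa")
    if not np.allclose(mat, mat.T, atol=1e-12) or not np.allclose(np.diag(mat), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")

    nodes = [TreeNode(name=lab) for lab in labels]
    d = mat.copy()
    active = list(range(n))

    def _clamp(li: float, lj: float) -> tuple[float, float]:
        # negative estimate → 0, deficit moved to the sibling edge
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 2:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = np.unravel_index(np.argmin(q), q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp(li, lj)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = li
        child_j.length = lj
        new = TreeNode(children=[child_i, child_j])
        # distances from the new node u: d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2
        for ak in active:
            if ak in (i, j):
                continue
            d_new = 0.5 * (d[i, ak] + d[j, ak] - dij)
            d[i, ak] = d[ak, i] = d_new
        d[i, i] = 0.0
        nodes[i] = new
        active.remove(j)

    i, j = active
    if len(nodes[i].children) == 0:  # root at the internal node
        i, j = j, i
    child = nodes[j]
    child.length = max(d[i, j], 0.0)
    root = nodes[i]
    root.append(child)
    root.length = None
    return root
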