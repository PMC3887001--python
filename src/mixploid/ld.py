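"""Linkage disequilibrium from unphased collapsed genotypes.

Pairwise r² is estimated by maximum likelihood over the four two-locus
haplotype frequencies with an EM algorithm: every genotype class except the
double heterozygote determines its haplotype pair; double heterozygotes are
split between the coupling (AB/ab) and repulsion (Ab/aB) configurations by
their posterior under the current estimate.  All samples are treated as
diploid-equivalent under the collapsed three-class coding — the convention
implied by feeding three-class tetraploid calls to a diploid LD estimator —
and the resulting bias is documented rather than corrected.

LD decay with physical distance d is summarised by fitting
``E(r²) = 1/(1 + C)`` with ``C = 4·a·d`` (the drift–recombination
equilibrium expectation) or the Hill & Weir (1988) finite-sample form

    E(r²) = [(10+C) / ((2+C)(11+C))] · [1 + ((3+C)(12+12C+C²)) / (n(2+C)(11+C))]

by nonlinear least squares in the single coefficient ``a``; the distance at
which the fitted curve crosses a target r² (0.2 by convention) is the
"LD decay distance".  Cross-population LD consistency (r_LD) is the
correlation of r² over shared SNP pairs within a distance window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import AA, AB, BB, MISSING, GenotypePanel
from .qc import maf_filter

logger = logging.getLogger(__name__)

EM_MAX_ITER = 1000
EM_TOL = 1e-10


# ---------------------------------------------------------------------------
# Two-locus EM
# ---------------------------------------------------------------------------


class MonomorphicLocusError(ValueError):
    """A locus is monomorphic among jointly-called samples; r² undefined."""


def _joint_counts(calls_i: np.ndarray, calls_j: np.ndarray) -> tuple[np.ndarray, int]:
    """3×3 table of joint genotype counts (allele-B dosage 0/1/2 per axis)."""
    mask = (calls_i != MISSING) & (calls_j != MISSING)
    gi = calls_i[mask].astype(np.int64)
    gj = calls_j[mask].astype(np.int64)
    table = np.bincount(gi * 3 + gj, minlength=9).reshape(3, 3)
    return table, int(mask.sum())


def r2_em(
    calls_i: np.ndarray,
    calls_j: np.ndarray,
    max_iter: int = EM_MAX_ITER,
    tol: float = EM_TOL,
) -> tuple[float, int]:
    """Maximum-likelihood r² between two loci from unphased calls.

    Samples missing at either locus are dropped pairwise.  Raises
    :class:`MonomorphicLocusError` if either locus is monomorphic among the
    jointly-called samples.  Returns ``(r², n_used)``.
    """
    table, n = _joint_counts(np.asarray(calls_i), np.asarray(calls_j))
    if n == 0:
        raise MonomorphicLocusError("no jointly-called samples")
    # allele-B frequencies from genotype margins
    margin_i = table.sum(axis=1)
    margin_j = table.sum(axis=0)
    p_i = float(margin_i @ np.array([0, 1, 2])) / (2 * n)
    p_j = float(margin_j @ np.array([0, 1, 2])) / (2 * n)
    if p_i in (0.0, 1.0) or p_j in (0.0, 1.0):
        raise MonomorphicLocusError("monomorphic locus among jointly-called samples")
    f = em_haplotype_freqs(table, max_iter=max_iter, tol=tol)
    d_coef = f[1, 1] - p_i * p_j
    r2 = d_coef**2 / (p_i * (1 - p_i) * p_j * (1 - p_j))
    return float(min(max(r2, 0.0), 1.0)), n


def em_haplotype_freqs(
    table: np.ndarray, max_iter: int = EM_MAX_ITER, tol: float = EM_TOL
) -> np.ndarray:
    """EM for the 2×2 haplotype-frequency table given 3×3 genotype counts.

    ``table[g_i, g_j]`` counts individuals with allele-B dosage g at each
    locus.  Returns ``f`` with ``f[x, y]`` the frequency of the haplotype
    carrying allele x at locus 1 and allele y at locus 2 (1 = allele B).
    Initialised at linkage equilibrium; converges monotonically in
    likelihood to a stationary point.
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    two_n = 2.0 * n
    p_i = (table.sum(axis=1) @ np.array([0, 1, 2])) / two_n
    p_j = (table.sum(axis=0) @ np.array([0, 1, 2])) / two_n
    # f indices: [allele at locus i, allele at locus j]
    f00 = (1 - p_i) * (1 - p_j)
    f01 = (1 - p_i) * p_j
    f10 = p_i * (1 - p_j)
    f11 = p_i * p_j
    n_dh = table[1, 1]
    # fixed haplotype contributions from phase-unambiguous genotypes
    base00 = 2 * table[0, 0] + table[0, 1] + table[1, 0]
    base01 = 2 * table[0, 2] + table[0, 1] + table[1, 2]
    base10 = 2 * table[2, 0] + table[1, 0] + table[2, 1]
    base11 = 2 * table[2, 2] + table[1, 2] + table[2, 1]
    for _ in range(max_iter):
        coup = f00 * f11
        rep = f01 * f10
        pc = coup / (coup + rep) if (coup + rep) > 0 else 0.5
        new00 = (base00 + n_dh * pc) / two_n
        new01 = (base01 + n_dh * (1 - pc)) / two_n
        new10 = (base10 + n_dh * (1 - pc)) / two_n
        new11 = (base11 + n_dh * pc) / two_n
        delta = max(
            abs(new00 - f00), abs(new01 - f01), abs(new10 - f10), abs(new11 - f11)
        )
        f00, f01, f10, f11 = new00, new01, new10, new11
        if delta < tol:
            break
    return np.array([[f00, f01], [f10, f11]])


def genotype_log_likelihood(table: np.ndarray, f: np.ndarray) -> float:
    """Log-likelihood of a 3×3 genotype count table under haplotype freqs f.

    Assumes random union of haplotypes (diploid-equivalent samples).  Used
    both by the EM (implicitly) and by brute-force grid oracles.
    """
    f00, f01, f10, f11 = f[0, 0], f[0, 1], f[1, 0], f[1, 1]
    probs = np.array(
        [
            [f00**2, 2 * f00 * f01, f01**2],
            [2 * f00 * f10, 2 * (f00 * f11 + f01 * f10), 2 * f01 * f11],
            [f10**2, 2 * f10 * f11, f11**2],
        ]
    )
    table = np.asarray(table, dtype=float)
    with np.errstate(divide="ignore"):
        logp = np.where(table > 0, np.log(np.maximum(probs, 1e-300)), 0.0)
    return float(np.sum(table * logp))


# ---------------------------------------------------------------------------
# Panel-wide LD
# ---------------------------------------------------------------------------


def compute_ld(
    panel: GenotypePanel,
    group: Sequence[str] | None = None,
    maf: float = 0.05,
    max_d: float = np.inf,
) -> pd.DataFrame:
    """All intra-chromosome pairwise r² within a sample group.

    SNPs are MAF-filtered within the analysis group (MAF < ``maf``
    excluded), position-less SNPs are excluded with a log message, and only
    pairs on the same chromosome with distance ``d ≤ max_d`` are emitted, in
    deterministic (chrom, pos_i, pos_j) order.  Pairs whose loci become
    monomorphic after pairwise deletion are skipped and counted.

    Returns columns ``snp_i, snp_j, chrom, d, r2, n``.
    """
    idx = panel.sample_indices(group)
    if len(idx) < 10:
        logger.warning("LD group has only %d samples; estimates will be noisy", len(idx))
    sub = panel.subset(sample_idx=idx)
    has_pos = ~sub.snps["pos"].isna().to_numpy()
    if (~has_pos).any():
        logger.info("excluding %d position-less SNPs from LD", int((~has_pos).sum()))
        sub = sub.subset(snp_idx=np.where(has_pos)[0])
    sub = maf_filter(sub, threshold=maf)

    rows = []
    n_skipped = 0
    snps = sub.snps
    for chrom in sorted(snps["chrom"].unique()):
        on_chrom = np.where((snps["chrom"] == chrom).to_numpy())[0]
        order = on_chrom[np.argsort(snps["pos"].iloc[on_chrom].to_numpy())]
        pos = snps["pos"].iloc[order].to_numpy(dtype=float)
        ids = snps["snp_id"].iloc[order].to_numpy()
        for a in range(len(order)):
            for b in range(a + 1, len(order)):
                d = pos[b] - pos[a]
                if d > max_d:
                    break
                try:
                    r2, n_used = r2_em(sub.calls[:, order[a]], sub.calls[:, order[b]])
                except MonomorphicLocusError:
                    n_skipped += 1
                    continue
                rows.append((ids[a], ids[b], chrom, int(d), r2, n_used))
    if n_skipped:
        logger.info("skipped %d pairs monomorphic after pairwise deletion", n_skipped)
    return pd.DataFrame(rows, columns=["snp_i", "snp_j", "chrom", "d", "r2", "n"])


# ---------------------------------------------------------------------------
# Decay-model fitting
# ---------------------------------------------------------------------------


def expected_r2_sved(d: np.ndarray, a: float) -> np.ndarray:
    """Drift–recombination equilibrium expectation 1/(1 + 4·a·d)."""
    return 1.0 / (1.0 + 4.0 * a * np.asarray(d, dtype=float))


def expected_r2_hill_weir(d: np.ndarray, a: float, n: int) -> np.ndarray:
    """Hill & Weir (1988) finite-sample expectation of r² at C = 4·a·d."""
    c = 4.0 * a * np.asarray(d, dtype=float)
    term1 = (10.0 + c) / ((2.0 + c) * (11.0 + c))
    term2 = 1.0 + ((3.0 + c) * (12.0 + 12.0 * c + c**2)) / (
        n * (2.0 + c) * (11.0 + c)
    )
    return term1 * term2


@dataclass
class DecayFit:
    """Fitted LD-decay model: variant, coefficient a (per bp), fit quality
    and the distances at requested r² thresholds."""

    variant: str
    a: float
    n: int | None
    rss: float
    n_pairs: int
    d_at: dict[float, float] = field(default_factory=dict)

    def expected(self, d: np.ndarray) -> np.ndarray:
        if self.variant == "sved":
            return expected_r2_sved(d, self.a)
        return expected_r2_hill_weir(d, self.a, int(self.n))


def fit_decay(
    d: np.ndarray | pd.DataFrame,
    r2: np.ndarray | None = None,
    variant: str = "sved",
    n: int | None = None,
    thresholds: Sequence[float] = (0.2,),
) -> DecayFit:
    """Nonlinear least-squares fit of observed r² against distance.

    ``d`` may be the DataFrame produced by :func:`compute_ld` (columns
    ``d``, ``r2`` and, for the finite-sample variant, ``n``), or an array of
    distances with ``r2`` given separately.  Observations enter unbinned,
    one residual per pair.  The coefficient is optimised in log space
    (enforcing a > 0) from a closed-form start through the median point;
    threshold distances are closed-form for the equilibrium variant and
    solved numerically otherwise.
    """
    if isinstance(d, pd.DataFrame):
        pairs = d
        if n is None and variant == "hill_weir_n" and "n" in pairs:
            n = int(round(float(pairs["n"].median())))
        r2 = pairs["r2"].to_numpy(dtype=float)
        d = pairs["d"].to_numpy(dtype=float)
    else:
        d = np.asarray(d, dtype=float)
        r2 = np.asarray(r2, dtype=float)
    if len(d) != len(r2) or len(d) == 0:
        raise ValueError("d and r2 must be equal-length, non-empty")
    if variant not in ("sved", "hill_weir_n"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "hill_weir_n":
        if n is None or n < 2:
            raise ValueError("hill_weir_n variant requires sample size n ≥ 2")
    if len(d) < 10 or (d.max() / max(d.min(), 1.0)) < 100:
        logger.warning(
            "decay fit on %d pairs spanning < 2 distance decades; "
            "estimates may be unstable",
            len(d),
        )

    # start: equilibrium curve through the median observation
    d_med = float(np.median(d))
    r2_med = float(np.clip(np.median(r2), 1e-3, 1 - 1e-3))
    a0 = max((1.0 / r2_med - 1.0) / (4.0 * max(d_med, 1.0)), 1e-12)

    def model(a: float) -> np.ndarray:
        if variant == "sved":
            return expected_r2_sved(d, a)
        return expected_r2_hill_weir(d, a, int(n))

    def residuals(theta: np.ndarray) -> np.ndarray:
        return model(np.exp(theta[0])) - r2

    sol = optimize.least_squares(
        residuals,
        x0=np.array([np.log(a0)]),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        method="lm",
    )
    if not sol.success:
        raise RuntimeError(
            f"decay fit did not converge: {sol.message}; best a = {np.exp(sol.x[0])}"
        )
    a_hat = float(np.exp(sol.x[0]))
    if a_hat <= 0 or not np.isfinite(a_hat):
        raise RuntimeError(f"decay fit rejected: a = {a_hat}")
    rss = float(np.sum(sol.fun**2))

    d_at: dict[float, float] = {}
    for t in thresholds:
        if variant == "sved":
            d_at[t] = (1.0 / t - 1.0) / (4.0 * a_hat)
        else:
            at0 = float(expected_r2_hill_weir(np.array([0.0]), a_hat, int(n))[0])
            if t >= at0:
                d_at[t] = 0.0
            else:
                f = lambda x: float(
                    expected_r2_hill_weir(np.array([x]), a_hat, int(n))[0] - t
                )
                hi = 1.0
                while f(hi) > 0 and hi < 1e15:
                    hi *= 10.0
                d_at[t] = float(optimize.brentq(f, 0.0, hi, xtol=1e-6, rtol=1e-12))
    return DecayFit(
        variant=variant,
        a=a_hat,
        n=(int(n) if variant == "hill_weir_n" else None),
        rss=rss,
        n_pairs=len(d),
        d_at=d_at,
    )


def bin_pairs(pairs: pd.DataFrame, n_bins: int = 25) -> pd.DataFrame:
    """Geometric distance bins with mean r² per bin — for plotting only."""
    d = pairs["d"].to_numpy(dtype=float)
    lo, hi = max(d.min(), 1.0), d.max()
    edges = np.geomspace(lo, hi * (1 + 1e-9), n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        rows.append(
            {
                "d_mean": float(d[mask].mean()),
                "r2_mean": float(pairs["r2"].to_numpy()[mask].mean()),
                "n_pairs": int(mask.sum()),
            }
        )
    return pd.DataFrame(rows)


def plot_decay(pairs: pd.DataFrame, fit: DecayFit, path) -> None:
    """Observed (binned) r² vs distance with the fitted decay curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    binned = bin_pairs(pairs)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(binned["d_mean"], binned["r2_mean"], s=18, label="binned mean r²")
    grid = np.geomspace(max(pairs["d"].min(), 1.0), pairs["d"].max(), 200)
    ax.plot(grid, fit.expected(grid), "r-", label=f"{fit.variant} fit (a={fit.a:.3g})")
    for t, dd in fit.d_at.items():
        ax.axhline(t, color="grey", lw=0.6, ls="--")
        ax.annotate(f"r²={t} at {dd / 1e3:.1f} kbp", (grid[0], t), fontsize=8)
    ax.set_xscale("log")
    ax.set_xlabel("physical distance (bp)")
    ax.set_ylabel("r²")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Cross-population LD consistency
# ---------------------------------------------------------------------------


@dataclass
class ConsistencyPoint:
    """Correlation of r² over shared SNP pairs within a distance window."""

    pop_pair: tuple[str, str]
    window: float
    r_ld: float
    n_pairs: int
    genetic_distance: float | None = None


def ld_consistency(
    pairs_a: pd.DataFrame,
    pairs_b: pd.DataFrame,
    windows: Sequence[float] = (1e5, 2e5, 1e6),
    genetic_distance: float | None = None,
    pop_pair: tuple[str, str] = ("A", "B"),
    method: str = "pearson",
) -> list[ConsistencyPoint]:
    """Correlation of LD (r_LD) between two populations per distance window.

    For each window w, r² values are correlated over the intersection of
    SNP pairs with d < w present in both lists (Pearson by default,
    Spearman optional).  Windows with fewer than 2 shared pairs are omitted
    with a log message.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    merged = pairs_a.merge(
        pairs_b, on=["snp_i", "snp_j"], suffixes=("_a", "_b"), how="inner"
    )
    out = []
    for w in windows:
        sub = merged[merged["d_a"] < w]
        if len(sub) < 2:
            logger.info(
                "window %g bp: only %d shared pairs, point omitted", w, len(sub)
            )
            continue
        x = sub["r2_a"].to_numpy(dtype=float)
        y = sub["r2_b"].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            r = 1.0 if np.allclose(x, y) else float("nan")
        elif method == "pearson":
            r = float(stats.pearsonr(x, y).statistic)
        else:
            r = float(stats.spearmanr(x, y).statistic)
        out.append(
            ConsistencyPoint(
                pop_pair=pop_pair,
                window=float(w),
                r_ld=r,
                n_pairs=len(sub),
                genetic_distance=genetic_distance,
            )
        )
    return out
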