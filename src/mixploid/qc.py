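"""Encoding, imputation, filtering and diversity summaries.

The multivariate pipeline scores each allele of a SNP as present (1) or
absent (0), giving two columns per SNP: AA → (1, 0), AB → (1, 1),
BB → (0, 1).  Missing calls leave both columns missing and are replaced by
the per-column mean across individuals before PCA.

Allele frequencies are computed from the collapsed three-class calls with
every sample treated as diploid-equivalent (an AB call contributes one copy
of each allele regardless of ploidy).  For tetraploids, whose heterozygous
dosage is unobservable after collapse, this biases frequencies toward 0.5;
the bias is inherent to three-class scoring and is shared by every
downstream quantity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .datamodel import AA, AB, BB, MISSING, GenotypePanel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Presence/absence encoding + mean imputation
# ---------------------------------------------------------------------------


@dataclass
class EncodedMatrix:
    """Samples × (2·n_snps) presence/absence matrix.

    Columns alternate (A-presence, B-presence) per SNP, in SNP order;
    ``column_map[(snp_id, allele)]`` gives the column index, allele in
    {"A", "B"}.  Missing entries are NaN until imputation; afterwards all
    entries lie in [0, 1].
    """

    values: np.ndarray
    column_map: dict[tuple[str, str], int]
    snp_ids: list[str]
    sample_ids: list[str]

    @property
    def is_imputed(self) -> bool:
        return not np.isnan(self.values).any()


def encode_presence(panel: GenotypePanel) -> EncodedMatrix:
    """Score each allele as 1 (present) / 0 (absent); missing → NaN, NaN."""
    calls = panel.calls
    n, m = calls.shape
    values = np.full((n, 2 * m), np.nan)
    a_col = np.zeros((n, m))
    b_col = np.zeros((n, m))
    a_col[(calls == AA) | (calls == AB)] = 1.0
    b_col[(calls == BB) | (calls == AB)] = 1.0
    a_col[calls == MISSING] = np.nan
    b_col[calls == MISSING] = np.nan
    values[:, 0::2] = a_col
    values[:, 1::2] = b_col
    column_map = {}
    for j, sid in enumerate(panel.snp_ids):
        column_map[(sid, "A")] = 2 * j
        column_map[(sid, "B")] = 2 * j + 1
    return EncodedMatrix(
        values=values,
        column_map=column_map,
        snp_ids=panel.snp_ids,
        sample_ids=panel.sample_ids,
    )


def impute_mean(encoded: EncodedMatrix) -> EncodedMatrix:
    """Replace each missing entry by its column's non-missing mean.

    A column with no observed value (SNP missing in every sample) is an
    error naming the SNP.
    """
    values = encoded.values.copy()
    n_obs = np.sum(~np.isnan(values), axis=0)
    if np.any(n_obs == 0):
        bad_cols = np.where(n_obs == 0)[0]
        bad_snps = sorted({encoded.snp_ids[c // 2] for c in bad_cols})
        raise ValueError(f"cannot impute: all calls missing for SNP(s) {bad_snps}")
    col_means = np.nanmean(values, axis=0)
    nan_r, nan_c = np.where(np.isnan(values))
    values[nan_r, nan_c] = col_means[nan_c]
    return EncodedMatrix(
        values=values,
        column_map=dict(encoded.column_map),
        snp_ids=list(encoded.snp_ids),
        sample_ids=list(encoded.sample_ids),
    )


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class FreqTable:
    """Per-group, per-locus allele-A frequencies.

    ``freq_a`` is a groups × SNPs DataFrame (NaN where a group has no called
    sample at a locus — such loci are dropped from distances involving that
    group); ``n_called`` holds the matching called-sample counts.
    """

    freq_a: pd.DataFrame
    n_called: pd.DataFrame

    @property
    def groups(self) -> list[str]:
        return list(self.freq_a.index)


def allele_freqs(
    panel: GenotypePanel, grouping: Mapping[str, str] | pd.Series | None = None
) -> FreqTable:
    """Allele-A frequency per group per locus from collapsed calls.

    freq(A) = (2·n_AA + n_AB) / (2·n_called); every sample counts as
    diploid-equivalent regardless of ploidy.  ``grouping`` maps sample_id →
    group label (default: the panel's population labels).
    """
    if grouping is None:
        labels = panel.samples["population"].astype(str).to_numpy()
    else:
        labels = np.array(
            [str(grouping[s]) for s in panel.samples["sample_id"]], dtype=object
        )
    calls = panel.calls
    group_names = sorted(set(labels.tolist()))
    freq_rows, n_rows = [], []
    for g in group_names:
        sub = calls[labels == g]
        n_aa = (sub == AA).sum(axis=0)
        n_ab = (sub == AB).sum(axis=0)
        n_bb = (sub == BB).sum(axis=0)
        n_called = n_aa + n_ab + n_bb
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(
                n_called > 0, (2 * n_aa + n_ab) / (2 * n_called), np.nan
            )
        if np.any(n_called == 0):
            logger.warning(
                "group %s: %d locus/loci with zero called samples (frequency undefined)",
                g,
                int((n_called == 0).sum()),
            )
        freq_rows.append(freq)
        n_rows.append(n_called)
    freq_a = pd.DataFrame(freq_rows, index=group_names, columns=panel.snp_ids)
    n_called = pd.DataFrame(n_rows, index=group_names, columns=panel.snp_ids)
    return FreqTable(freq_a=freq_a, n_called=n_called)


# ---------------------------------------------------------------------------
# Per-sample QC
# ---------------------------------------------------------------------------


def sample_qc(panel: GenotypePanel) -> pd.DataFrame:
    """Per-sample call rate and heterozygosity.

    Heterozygosity H is the percentage of non-missing calls that are
    heterozygous (AB); with collapsed tetraploid coding this counts any
    heterozygous dosage class.  H is NaN for a sample with no called SNPs.
    Returns a DataFrame with columns sample_id, call_rate, heterozygosity_pct.
    """
    calls = panel.calls
    n_called = (calls != MISSING).sum(axis=1)
    n_het = (calls == AB).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        het = np.where(n_called > 0, 100.0 * n_het / n_called, np.nan)
    return pd.DataFrame(
        {
            "sample_id": panel.sample_ids,
            "call_rate": n_called / panel.n_snps if panel.n_snps else 0.0,
            "heterozygosity_pct": het,
        }
    )


# ---------------------------------------------------------------------------
# Polymorphism sharing (Venn cells)
# ---------------------------------------------------------------------------


def polymorphism_sharing(
    panel: GenotypePanel, clusters: Mapping[str, str] | None = None
) -> dict[frozenset[str], int]:
    """Count SNPs polymorphic in exactly each subset of clusters.

    A SNP is polymorphic *within* a cluster iff at least two distinct
    non-missing call classes occur among that cluster's samples.  The result
    maps each non-empty cluster subset (a Venn cell) to the number of SNPs
    polymorphic in exactly those clusters; cells sum to the total number of
    SNPs polymorphic in ≥ 1 cluster.
    """
    if clusters is None:
        labels = panel.samples["population"].astype(str).to_numpy()
    else:
        labels = np.array(
            [str(clusters[s]) for s in panel.samples["sample_id"]], dtype=object
        )
    names = sorted(set(labels.tolist()))
    if len(names) < 2:
        raise ValueError("polymorphism sharing requires ≥ 2 clusters")
    poly = {}
    for g in names:
        sub = panel.calls[labels == g]
        n_classes = sum(
            ((sub == code).any(axis=0)).astype(int) for code in (AA, AB, BB)
        )
        poly[g] = n_classes >= 2
    counts: dict[frozenset[str], int] = {}
    for r in range(1, len(names) + 1):
        for subset in combinations(names, r):
            in_all = np.logical_and.reduce([poly[g] for g in subset])
            out_all = np.logical_and.reduce(
                [~poly[g] for g in names if g not in subset]
            ) if len(subset) < len(names) else np.ones(panel.n_snps, dtype=bool)
            counts[frozenset(subset)] = int(np.sum(in_all & out_all))
    return counts


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------


def maf_filter(
    panel: GenotypePanel,
    threshold: float = 0.05,
    group: Iterable[str] | None = None,
) -> GenotypePanel:
    """Drop SNPs whose minor allele frequency is below ``threshold``.

    A SNP is retained iff ``min(freq, 1 − freq) ≥ threshold`` — a frequency
    of exactly the threshold survives (only *lower* frequencies are
    excluded).  Frequency is computed over ``group`` (sample_ids; default:
    all samples), so per-cluster analyses filter within the cluster being
    analysed.  The removed count is logged.
    """
    idx = panel.sample_indices(group)
    calls = panel.calls[idx]
    n_aa = (calls == AA).sum(axis=0)
    n_ab = (calls == AB).sum(axis=0)
    n_bb = (calls == BB).sum(axis=0)
    n_called = n_aa + n_ab + n_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_called > 0, (2 * n_aa + n_ab) / (2 * n_called), np.nan)
    maf = np.minimum(freq, 1 - freq)
    keep = np.where(np.nan_to_num(maf, nan=-1.0) >= threshold)[0]
    logger.info(
        "MAF filter (< %g excluded): kept %d of %d SNPs (%d removed)",
        threshold,
        len(keep),
        panel.n_snps,
        panel.n_snps - len(keep),
    )
    return panel.subset(snp_idx=keep)


def write_qc_report(panel: GenotypePanel, path) -> pd.DataFrame:
    """Write the per-sample QC table (TSV) and return it."""
    report = sample_qc(panel)
    report.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return report


def write_venn_counts(counts: dict[frozenset[str], int], path) -> pd.DataFrame:
    """Write polymorphism-sharing Venn cells as a TSV and return the table."""
    rows = sorted(
        ((",".join(sorted(k)), v) for k, v in counts.items()),
        key=lambda kv: (kv[0].count(",") , kv[0]),
    )
    df = pd.DataFrame(rows, columns=["clusters", "n_polymorphic_only_here"])
    df.to_csv(path, sep="\t", index=False)
    return df
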