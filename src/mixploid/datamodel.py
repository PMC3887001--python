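"""Genotype data model and file I/O for mixed-ploidy SNP panels.

The central container is :class:`GenotypePanel`: a samples × SNPs matrix of
collapsed three-class genotype calls (AA / AB / BB / missing) together with
sample metadata (ploidy, population label) and SNP metadata (chromosome,
1-based bp position on a reference, alleles).

Autotetraploid dosage classes are *never* stored.  On a three-cluster array
call, the tetraploid heterozygous dosage classes AAAB, AABB and ABBB are
indistinguishable, so every heterozygous tetraploid genotype is collapsed to
a single AB class at ingest.  All downstream analyses treat samples as
diploid-equivalent under this coding.

Supported formats:

* panel TSV + SNP-map TSV (read/write; the canonical interchange format),
* VCF 4.x (read only, via pysam; diploid and tetraploid GT fields),
* Newick (write only, for neighbor-joining trees).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Call codes
# ---------------------------------------------------------------------------

#: Integer codes used in ``GenotypePanel.calls`` (int8).
AA: int = 0
AB: int = 1
BB: int = 2
MISSING: int = -1

#: TSV token for each call code.
CALL_TO_TOKEN: dict[int, str] = {AA: "AA", AB: "AB", BB: "BB", MISSING: "--"}
TOKEN_TO_CALL: dict[str, int] = {v: k for k, v in CALL_TO_TOKEN.items()}

_IUPAC_BASES = set("ACGT")

SAMPLE_COLUMNS = ["sample_id", "ploidy", "population", "cluster"]
SNP_COLUMNS = ["snp_id", "chrom", "pos", "allele_a", "allele_b"]


class PanelFormatError(ValueError):
    """Raised when a panel file violates the documented dialect."""


def collapse_gt(alleles: Sequence[int | None]) -> int:
    """Collapse a genotype (multiset of 0/1 allele indices) to a 3-class call.

    All-reference → AA, all-alternate → BB, any mixture → AB; any missing
    allele (``None`` / negative) → MISSING.  This is the rule that maps the
    five tetraploid dosage classes AAAA, AAAB, AABB, ABBB, BBBB onto
    AA, AB, AB, AB, BB, and it is a pure function of the allele multiset.
    """
    if len(alleles) == 0:
        return MISSING
    if any(a is None or a < 0 for a in alleles):
        return MISSING
    n_alt = sum(int(a) for a in alleles)
    if n_alt == 0:
        return AA
    if n_alt == len(alleles):
        return BB
    return AB


# ---------------------------------------------------------------------------
# Panel container
# ---------------------------------------------------------------------------


@dataclass
class GenotypePanel:
    """A samples × SNPs matrix of collapsed three-class genotype calls.

    Parameters
    ----------
    samples
        DataFrame with columns sample_id, ploidy (2 or 4), population and
        optional cluster label.
    snps
        DataFrame with columns snp_id, chrom, pos (1-based bp), allele_a,
        allele_b.  ``pos`` may be a missing value (``pd.NA``/NaN) for SNPs
        without a reference alignment; such SNPs are excluded from
        distance-based (LD) analyses.
    calls
        int8 array, shape ``(n_samples, n_snps)``, values in
        {AA, AB, BB, MISSING}.
    """

    samples: pd.DataFrame
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True).copy()
        if "cluster" not in self.samples.columns:
            self.samples["cluster"] = pd.NA
        self.snps = self.snps.reset_index(drop=True).copy()
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self._validate()

    def _validate(self) -> None:
        missing_cols = set(["sample_id", "ploidy", "population"]) - set(
            self.samples.columns
        )
        if missing_cols:
            raise PanelFormatError(f"sample table missing columns: {missing_cols}")
        missing_cols = set(SNP_COLUMNS) - set(self.snps.columns)
        if missing_cols:
            raise PanelFormatError(f"SNP table missing columns: {missing_cols}")
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise PanelFormatError(
                f"calls shape {self.calls.shape} does not match metadata "
                f"({len(self.samples)} samples × {len(self.snps)} SNPs)"
            )
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples["sample_id"][self.samples["sample_id"].duplicated()]
            raise PanelFormatError(f"duplicated sample_id: {sorted(set(dup))}")
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps["snp_id"][self.snps["snp_id"].duplicated()]
            raise PanelFormatError(f"duplicated snp_id: {sorted(set(dup))}")
        bad_ploidy = set(self.samples["ploidy"]) - {2, 4}
        if bad_ploidy:
            raise PanelFormatError(f"ploidy must be 2 or 4, got {bad_ploidy}")
        pos = pd.to_numeric(self.snps["pos"], errors="coerce")
        if (pos.dropna() < 1).any():
            raise PanelFormatError("SNP positions must be ≥ 1 (1-based)")
        same = self.snps["allele_a"].astype(str) == self.snps["allele_b"].astype(str)
        if same.any():
            raise PanelFormatError(
                f"allele_a == allele_b for SNPs {list(self.snps.loc[same, 'snp_id'])}"
            )
        valid = {AA, AB, BB, MISSING}
        observed = set(np.unique(self.calls).tolist())
        if not observed <= valid:
            raise PanelFormatError(f"illegal call codes in matrix: {observed - valid}")

    # -- basic accessors ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snps["snp_id"])

    def call_rate(self) -> pd.Series:
        """Per-sample fraction of non-missing calls, in [0, 1]."""
        called = (self.calls != MISSING).mean(axis=1)
        return pd.Series(called, index=self.sample_ids, name="call_rate")

    def subset(
        self,
        sample_idx: Sequence[int] | np.ndarray | None = None,
        snp_idx: Sequence[int] | np.ndarray | None = None,
    ) -> "GenotypePanel":
        """Return a new panel restricted to the given positional indices."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypePanel(
            samples=self.samples.iloc[si],
            snps=self.snps.iloc[mi],
            calls=self.calls[np.ix_(si, mi)],
        )

    def sample_indices(self, group: Iterable[str] | None) -> np.ndarray:
        """Positional indices of the given sample_ids (all samples if None)."""
        if group is None:
            return np.arange(self.n_samples)
        wanted = set(group)
        idx = [i for i, s in enumerate(self.samples["sample_id"]) if s in wanted]
        missing = wanted - set(self.samples["sample_id"])
        if missing:
            raise KeyError(f"unknown sample_id(s): {sorted(missing)}")
        return np.asarray(idx, dtype=int)


# ---------------------------------------------------------------------------
# Panel TSV dialect
# ---------------------------------------------------------------------------
#
# panel file : header "sample_id\tploidy\tpopulation\t<snp_id_1>...<snp_id_n>"
#              one row per sample; call tokens AA / AB / BB / -- (missing).
# SNP map    : header "snp_id\tchrom\tpos\tallele_a\tallele_b"; pos may be
#              the empty string for unaligned SNPs.


def read_panel_tsv(panel_path: str | Path, snp_map_path: str | Path) -> GenotypePanel:
    """Read a genotype panel from the panel-TSV + SNP-map-TSV pair.

    Raises :class:`PanelFormatError` naming the offending line for malformed
    headers, duplicated IDs, dimension mismatches and unknown call tokens.
    """
    panel_path, snp_map_path = Path(panel_path), Path(snp_map_path)

    with open(snp_map_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != SNP_COLUMNS:
            raise PanelFormatError(
                f"{snp_map_path} line 1: expected header "
                f"{SNP_COLUMNS}, got {header}"
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise PanelFormatError(
                    f"{snp_map_path} line {lineno}: expected 5 fields, got {len(parts)}"
                )
            snp_id, chrom, pos, a, b = parts
            if pos == "":
                pos_val: object = pd.NA
            else:
                try:
                    pos_val = int(pos)
                except ValueError:
                    raise PanelFormatError(
                        f"{snp_map_path} line {lineno}: bad position {pos!r}"
                    ) from None
            rows.append((snp_id, chrom, pos_val, a, b))
    snps = pd.DataFrame(rows, columns=SNP_COLUMNS)
    snps["pos"] = snps["pos"].astype("Int64")

    with open(panel_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["sample_id", "ploidy", "population"]:
            raise PanelFormatError(
                f"{panel_path} line 1: header must start with "
                "sample_id<TAB>ploidy<TAB>population"
            )
        snp_ids = header[3:]
        if snp_ids != list(snps["snp_id"]):
            raise PanelFormatError(
                f"{panel_path} line 1: SNP columns do not match SNP map "
                f"({len(snp_ids)} vs {len(snps)} IDs or different order)"
            )
        sample_rows = []
        call_rows = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 + len(snp_ids):
                raise PanelFormatError(
                    f"{panel_path} line {lineno}: expected {3 + len(snp_ids)} "
                    f"fields, got {len(parts)}"
                )
            sid, ploidy, pop = parts[:3]
            try:
                ploidy_val = int(ploidy)
            except ValueError:
                raise PanelFormatError(
                    f"{panel_path} line {lineno}: bad ploidy {ploidy!r}"
                ) from None
            codes = []
            for tok in parts[3:]:
                if tok not in TOKEN_TO_CALL:
                    raise PanelFormatError(
                        f"{panel_path} line {lineno}: unknown call token {tok!r}"
                    )
                codes.append(TOKEN_TO_CALL[tok])
            sample_rows.append((sid, ploidy_val, pop))
            call_rows.append(codes)
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "ploidy", "population"])
    calls = np.asarray(call_rows, dtype=np.int8).reshape(len(samples), len(snps))
    return GenotypePanel(samples=samples, snps=snps, calls=calls)


def write_panel_tsv(
    panel: GenotypePanel, panel_path: str | Path, snp_map_path: str | Path
) -> None:
    """Write a panel in the canonical TSV dialect (round-trips bit-exactly)."""
    with open(snp_map_path, "w") as fh:
        fh.write("\t".join(SNP_COLUMNS) + "\n")
        for rec in panel.snps.itertuples(index=False):
            pos = "" if pd.isna(rec.pos) else str(int(rec.pos))
            fh.write(f"{rec.snp_id}\t{rec.chrom}\t{pos}\t{rec.allele_a}\t{rec.allele_b}\n")
    with open(panel_path, "w") as fh:
        fh.write("\t".join(["sample_id", "ploidy", "population"] + panel.snp_ids) + "\n")
        for i, rec in enumerate(panel.samples.itertuples(index=False)):
            tokens = [CALL_TO_TOKEN[c] for c in panel.calls[i]]
            fh.write(
                "\t".join([str(rec.sample_id), str(int(rec.ploidy)), str(rec.population)] + tokens)
                + "\n"
            )


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------


def read_panel_vcf(
    path: str | Path,
    populations: Mapping[str, str] | None = None,
) -> GenotypePanel:
    """Read a biallelic-SNP VCF into a collapsed three-class panel.

    Diploid GT 0/0 → AA, 0/1 → AB, 1/1 → BB, ./. → MISSING.  Tetraploid GT
    with any mix of 0 and 1 → AB (dosage collapse), all-0 → AA, all-1 → BB.
    Sample ploidy is inferred from the GT arity.  Multiallelic records and
    non-SNP alleles are skipped with a logged count; a VCF without a GT
    FORMAT field is an error.

    Parameters
    ----------
    populations
        Optional sample_id → population label map (default label ``"all"``).
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    if "GT" not in vf.header.formats:
        raise PanelFormatError(f"{path}: VCF has no GT FORMAT field")
    sample_ids = list(vf.header.samples)
    snp_rows = []
    call_cols: list[np.ndarray] = []
    ploidies: dict[str, int] = {}
    n_skipped = 0
    for rec in vf:
        alts = rec.alts or ()
        if len(alts) != 1 or rec.ref is None or len(rec.ref) != 1 or len(alts[0]) != 1:
            n_skipped += 1
            continue
        col = np.empty(len(sample_ids), dtype=np.int8)
        for j, sid in enumerate(sample_ids):
            gt = rec.samples[sid].get("GT")
            if gt is None:
                col[j] = MISSING
                continue
            alleles = [a for a in gt]
            if all(a is not None for a in alleles) and len(alleles) in (2, 4):
                ploidies.setdefault(sid, len(alleles))
            col[j] = collapse_gt(alleles)
        snp_id = rec.id if rec.id not in (None, ".") else f"{rec.chrom}:{rec.pos}"
        snp_rows.append((snp_id, rec.chrom, rec.pos, rec.ref, alts[0]))
        call_cols.append(col)
    if n_skipped:
        logger.warning("%s: skipped %d multiallelic/non-SNP records", path, n_skipped)
    snps = pd.DataFrame(snp_rows, columns=SNP_COLUMNS)
    snps["pos"] = snps["pos"].astype("Int64")
    populations = populations or {}
    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "ploidy": [ploidies.get(s, 2) for s in sample_ids],
            "population": [populations.get(s, "all") for s in sample_ids],
        }
    )
    calls = (
        np.stack(call_cols, axis=1)
        if call_cols
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    return GenotypePanel(samples=samples, snps=snps, calls=calls)


# ---------------------------------------------------------------------------
# Newick output
# ---------------------------------------------------------------------------


def write_newick(tree, path: str | Path | None = None) -> str:
    """Serialize a tree (``skbio.TreeNode``) to Newick with branch lengths.

    Returns the Newick string; additionally writes it to ``path`` if given.
    An empty tree (no tips) is an error.
    """
    from skbio import TreeNode

    if not isinstance(tree, TreeNode):
        raise TypeError(f"expected skbio.TreeNode, got {type(tree)}")
    if tree.count(tips=True) == 0:
        raise ValueError("cannot serialize an empty tree")
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue().strip()
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
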