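"""Synthetic genotype panels with known structure and known LD decay.

Two generators:

* :func:`simulate_wf` — a forward-in-time Wright–Fisher simulation of a pool
  of ``2·n_e`` haplotypes with per-interval recombination and an optional
  split into K independently drifting subpopulations.  Run long enough
  (≥ 4·n_e generations) from linkage equilibrium, the haplotype pool reaches
  drift–recombination equilibrium, where the expected r² between loci at
  recombination fraction c is approximately ``1/(1 + 4·n_e·c) + 1/(2·n_e)``.
  This is exactly the regime assumed by the LD-decay model fitted downstream,
  which makes the fitted decay curve testable against a known truth.
* :func:`balding_nichols_panel` — unlinked loci whose subpopulation allele
  frequencies are Beta-distributed around an ancestral frequency with
  variance ``p(1−p)·FST``; the standard structured-population generator used
  to test PCA/clustering recovery and the FST-ordering of Nei distances.

Genotypes are sampled from the haplotype pools at ploidy 2 or 4 and
immediately collapsed to the three-class AA/AB/BB coding, so tetraploid
dosage information is discarded exactly as it is on a three-cluster array.

Randomness: one global seed drives three documented, independently spawned
streams (simulation, genotype sampling, missingness), so fixtures are
byte-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import AA, AB, BB, MISSING, GenotypePanel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Parameters of the Wright–Fisher panel simulation.

    Defaults describe the standing study conditions: a population of
    ``n_e = 100`` diploids (200 haplotypes) evolved for ``4·n_e``
    generations — long enough to reach drift–recombination equilibrium —
    over 200 loci on a 1 Mbp chromosome at 1e-7 crossovers/bp/generation
    (pairwise recombination fractions span ~1e-5 … 0.1, and the
    equilibrium mean r² crosses 0.2 near 100 kbp), splitting
    halfway into two subpopulations sampled at tetraploid and diploid
    ploidy with 1% missing data.
    """

    n_e: int = 100
    n_loci: int = 200
    chrom_length: int = 1_000_000
    rec_rate: float = 1e-7
    n_generations: int = 400
    n_subpops: int = 2
    split_generation: int = 200
    founder_freq_low: float = 0.1
    founder_freq_high: float = 0.9
    samples_per_pop: int = 30
    ploidy_per_pop: tuple[int, ...] = (4, 2)
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_e < 2:
            raise ValueError("n_e must be ≥ 2")
        if self.n_loci < 2:
            raise ValueError("n_loci must be ≥ 2")
        if self.chrom_length < self.n_loci:
            raise ValueError("chrom_length must allow n_loci distinct positions")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")
        if self.rec_rate < 0 or self.rec_rate * self.chrom_length > 0.5:
            # per-interval crossover probability is Bernoulli; keep it ≤ 1/2
            raise ValueError("require 0 ≤ rec_rate · chrom_length ≤ 0.5")
        if self.n_subpops < 1:
            raise ValueError("n_subpops must be ≥ 1")
        if not 0 <= self.split_generation <= self.n_generations:
            raise ValueError("split_generation must lie in [0, n_generations]")
        if len(self.ploidy_per_pop) != self.n_subpops:
            raise ValueError("ploidy_per_pop must have one entry per subpopulation")
        if set(self.ploidy_per_pop) - {2, 4}:
            raise ValueError("ploidy must be 2 or 4")
        if not 0 < self.founder_freq_low <= self.founder_freq_high < 1:
            raise ValueError("founder frequency law must satisfy 0 < low ≤ high < 1")
        if self.samples_per_pop < 1:
            raise ValueError("samples_per_pop must be ≥ 1")

    def rng_streams(self) -> tuple[np.random.Generator, ...]:
        """(simulation, sampling, missingness) generators spawned from seed."""
        ss = np.random.SeedSequence(self.seed)
        return tuple(np.random.default_rng(s) for s in ss.spawn(3))


@dataclass
class SimTruth:
    """Ground truth of a Wright–Fisher run.

    ``haplotype_pools[k]`` is the final 0/1 haplotype matrix
    (2·n_e × n_loci) of subpopulation k (allele 1 = allele B);
    ``positions`` are the sorted locus coordinates in bp.
    """

    haplotype_pools: list[np.ndarray]
    positions: np.ndarray
    founder_freqs: np.ndarray
    config: SimulationConfig
    pop_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pop_names:
            self.pop_names = [f"pop{k + 1}" for k in range(len(self.haplotype_pools))]

    def interval_rec_fractions(self) -> np.ndarray:
        """Per-adjacent-interval crossover probabilities c_k."""
        return self.config.rec_rate * np.diff(self.positions).astype(float)

    def pairwise_rec_fraction(self, i: int, j: int) -> float:
        """Recombination fraction between loci i<j: 1 − Π(1 − c_k)."""
        c = self.interval_rec_fractions()
        lo, hi = min(i, j), max(i, j)
        return 1.0 - float(np.prod(1.0 - c[lo:hi]))


# ---------------------------------------------------------------------------
# Wright–Fisher core
# ---------------------------------------------------------------------------


def _evolve(
    pool: np.ndarray,
    c_intervals: np.ndarray,
    n_generations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve a haplotype pool for ``n_generations`` WF generations.

    Each offspring haplotype is a recombinant of two distinct random parent
    haplotypes; crossovers are independent Bernoulli(c_k) events per
    adjacent-locus interval (no interference).
    """
    n_hap, n_loci = pool.shape
    for _ in range(n_generations):
        p1 = rng.integers(n_hap, size=n_hap)
        p2 = (p1 + 1 + rng.integers(n_hap - 1, size=n_hap)) % n_hap
        start = rng.integers(2, size=n_hap)
        if n_loci > 1:
            xo = rng.random((n_hap, n_loci - 1)) < c_intervals
            switches = np.cumsum(xo, axis=1)
            which = np.empty((n_hap, n_loci), dtype=np.int64)
            which[:, 0] = start
            which[:, 1:] = (start[:, None] + switches) % 2
        else:
            which = start[:, None]
        pool = np.where(which == 0, pool[p1], pool[p2])
    return pool


def simulate_wf(config: SimulationConfig) -> SimTruth:
    """Run the Wright–Fisher simulation and return the final pools.

    A single ancestral pool of ``2·n_e`` haplotypes is initialised at
    linkage equilibrium (alleles i.i.d. Bernoulli per locus, founder
    frequencies drawn from the uniform founder law), evolved jointly for
    ``split_generation`` generations, then copied into ``n_subpops``
    independent pools that drift apart for the remaining generations.
    """
    rng_sim, _, _ = config.rng_streams()
    positions = np.sort(
        rng_sim.choice(config.chrom_length, size=config.n_loci, replace=False) + 1
    )
    founder_freqs = rng_sim.uniform(
        config.founder_freq_low, config.founder_freq_high, size=config.n_loci
    )
    n_hap = 2 * config.n_e
    pool = (rng_sim.random((n_hap, config.n_loci)) < founder_freqs).astype(np.int8)
    c_intervals = config.rec_rate * np.diff(positions).astype(float)

    pool = _evolve(pool, c_intervals, config.split_generation, rng_sim)
    post = config.n_generations - config.split_generation
    pools = [
        _evolve(pool.copy(), c_intervals, post, rng_sim)
        for _ in range(config.n_subpops)
    ]
    return SimTruth(
        haplotype_pools=pools,
        positions=positions,
        founder_freqs=founder_freqs,
        config=config,
    )


# ---------------------------------------------------------------------------
# Genotype sampling
# ---------------------------------------------------------------------------


def _dosage_to_call(dosage: np.ndarray, ploidy: int) -> np.ndarray:
    """Map per-locus allele-B dosage to collapsed three-class calls."""
    calls = np.full(dosage.shape, AB, dtype=np.int8)
    calls[dosage == 0] = AA
    calls[dosage == ploidy] = BB
    return calls


def sample_panel(truth: SimTruth, config: SimulationConfig | None = None) -> GenotypePanel:
    """Draw a genotype panel from the simulated haplotype pools.

    Each sample draws ``ploidy`` haplotypes with replacement from its
    subpopulation pool; the per-locus call is AA if all alleles are A,
    BB if all are B, otherwise AB (dosage collapse).  Missing calls are then
    injected i.i.d. at ``missing_rate``.
    """
    config = config or truth.config
    _, rng_sample, rng_missing = config.rng_streams()
    sample_rows = []
    call_rows = []
    for k, pool in enumerate(truth.haplotype_pools):
        ploidy = int(config.ploidy_per_pop[k])
        pop = truth.pop_names[k]
        for s in range(config.samples_per_pop):
            hap_idx = rng_sample.integers(pool.shape[0], size=ploidy)
            dosage = pool[hap_idx].sum(axis=0)
            call_rows.append(_dosage_to_call(dosage, ploidy))
            sample_rows.append((f"{pop}_s{s + 1:03d}", ploidy, pop))
    calls = np.vstack(call_rows)
    if config.missing_rate > 0:
        mask = rng_missing.random(calls.shape) < config.missing_rate
        calls = np.where(mask, np.int8(MISSING), calls)
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "ploidy", "population"])
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1:05d}" for i in range(config.n_loci)],
            "chrom": "chr1",
            "pos": truth.positions.astype(int),
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    snps["pos"] = snps["pos"].astype("Int64")
    return GenotypePanel(samples=samples, snps=snps, calls=calls)


def simulate_panel(config: SimulationConfig) -> tuple[GenotypePanel, SimTruth]:
    """Convenience wrapper: simulate pools and sample a panel from them."""
    truth = simulate_wf(config)
    return sample_panel(truth, config), truth


# ---------------------------------------------------------------------------
# Pool-level (phased) LD — the oracle side of decay tests
# ---------------------------------------------------------------------------


def pool_ld_pairs(
    truth: SimTruth, subpop: int = 0, maf: float = 0.05
) -> pd.DataFrame:
    """Phased r² and recombination fraction for all locus pairs in a pool.

    Computed directly on the 0/1 haplotype matrix (no genotype sampling, no
    EM), so it separates estimator error from sampling noise in downstream
    comparisons.  Loci with pool minor-allele frequency below ``maf`` are
    excluded.  Returns columns ``i, j, c, d, r2``.
    """
    pool = truth.haplotype_pools[subpop].astype(float)
    freqs = pool.mean(axis=0)
    keep = np.where(np.minimum(freqs, 1 - freqs) >= maf)[0]
    if len(keep) < 2:
        return pd.DataFrame(columns=["i", "j", "c", "d", "r2"])
    sub = pool[:, keep]
    corr = np.corrcoef(sub, rowvar=False)
    r2 = corr**2
    c_int = truth.interval_rec_fractions()
    # log-space cumulative product gives all pairwise 1 − Π(1 − c_k)
    log1mc = np.concatenate([[0.0], np.cumsum(np.log1p(-c_int))])
    ii, jj = np.triu_indices(len(keep), k=1)
    gi, gj = keep[ii], keep[jj]
    c = 1.0 - np.exp(log1mc[gj] - log1mc[gi])
    d = truth.positions[gj] - truth.positions[gi]
    return pd.DataFrame(
        {"i": gi, "j": gj, "c": c, "d": d.astype(int), "r2": r2[ii, jj]}
    )


# ---------------------------------------------------------------------------
# Balding–Nichols generator (unlinked loci, known FST)
# ---------------------------------------------------------------------------


def balding_nichols_panel(
    p_anc: Sequence[float] | np.ndarray,
    fst: float,
    n_subpops: int,
    samples_per_pop: int,
    ploidy: int | Sequence[int] = 2,
    seed: int = 0,
    missing_rate: float = 0.0,
) -> GenotypePanel:
    """Structured panel of unlinked loci under the Balding–Nichols model.

    For each subpopulation k and locus l with ancestral frequency p, the
    subpopulation allele-A frequency is drawn
    ``Beta(p·(1−F)/F, (1−p)·(1−F)/F)`` with ``F = fst`` (mean p, variance
    ``p(1−p)·F``); genotypes are binomial draws at the sample's ploidy, then
    collapsed to three classes.  Loci are placed on distinct chromosomes so
    they are unlinked by construction.
    """
    p_anc = np.asarray(p_anc, dtype=float)
    if not 0 < fst < 1:
        raise ValueError("fst must be in (0, 1)")
    if np.any((p_anc <= 0) | (p_anc >= 1)):
        raise ValueError("ancestral frequencies must be in (0, 1)")
    ploidies = (
        [int(ploidy)] * n_subpops if np.isscalar(ploidy) else [int(p) for p in ploidy]
    )
    if len(ploidies) != n_subpops or set(ploidies) - {2, 4}:
        raise ValueError("ploidy must be 2 or 4, one value or one per subpopulation")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_loci = len(p_anc)
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    sample_rows, call_rows = [], []
    for k in range(n_subpops):
        pk = rng.beta(a, b)  # per-locus subpop allele-A frequency
        pl = ploidies[k]
        for s in range(samples_per_pop):
            dosage_a = rng.binomial(pl, pk)
            dosage_b = pl - dosage_a
            call_rows.append(_dosage_to_call(dosage_b, pl))
            sample_rows.append((f"pop{k + 1}_s{s + 1:03d}", pl, f"pop{k + 1}"))
    calls = np.vstack(call_rows)
    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls = np.where(mask, np.int8(MISSING), calls)
    samples = pd.DataFrame(sample_rows, columns=["sample_id", "ploidy", "population"])
    snps = pd.DataFrame(
        {
            "snp_id": [f"bn{i + 1:05d}" for i in range(n_loci)],
            "chrom": [f"chr{i + 1}" for i in range(n_loci)],
            "pos": 1,
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    snps["pos"] = snps["pos"].astype("Int64")
    return GenotypePanel(samples=samples, snps=snps, calls=calls)


# ---------------------------------------------------------------------------
# Truth bundle I/O (TSV + key-value config echo)
# ---------------------------------------------------------------------------


def write_truth(truth: SimTruth, directory) -> None:
    """Write haplotype pools and a key=value config echo to ``directory``."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, pool in zip(truth.pop_names, truth.haplotype_pools):
        df = pd.DataFrame(pool, columns=[f"locus{i + 1}" for i in range(pool.shape[1])])
        df.to_csv(directory / f"haplotypes_{name}.tsv", sep="\t", index=False)
    lines = [f"{k} = {v}" for k, v in vars(truth.config).items()]
    lines.append("positions = " + ",".join(str(int(p)) for p in truth.positions))
    (directory / "truth_config.txt").write_text("\n".join(lines) + "\n")
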