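import numpy as np
import pandas as pd
import pytest

from mixploid import AA, AB, BB, MISSING, GenotypePanel

CALL_OF = {"AA": AA, "AB": AB, "BB": BB, "--": MISSING}


def panel_from_tokens(
    rows: list[str],
    ploidy: list[int] | int = 2,
    populations: list[str] | None = None,
    positions: list[int] | None = None,
    chroms: list[str] | None = None,
) -> GenotypePanel:
    """Build a panel from rows of space-separated call tokens."""
    calls = np.array(
        [[CALL_OF[tok] for tok in row.split()] for row in rows], dtype=np.int8
    )
    n, m = calls.shape
    if isinstance(ploidy, int):
        ploidy = [ploidy] * n
    populations = populations or ["pop1"] * n
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i + 1}" for i in range(n)],
            "ploidy": ploidy,
            "population": populations,
        }
    )
    snps = pd.DataFrame(
        {
            "snp_id": [f"m{j + 1}" for j in range(m)],
            "chrom": chroms or ["chr1"] * m,
            "pos": positions or list(range(1, m + 1)),
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    snps["pos"] = snps["pos"].astype("Int64")
    return GenotypePanel(samples=samples, snps=snps, calls=calls)


def random_panel(rng: np.random.Generator, n: int = 8, m: int = 12) -> GenotypePanel:
    """A random well-formed panel including missing calls and both ploidies."""
    calls = rng.choice([AA, AB, BB, MISSING], size=(n, m), p=[0.4, 0.3, 0.2, 0.1])
    samples = pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "ploidy": rng.choice([2, 4], size=n),
            "population": rng.choice(["p1", "p2"], size=n),
        }
    )
    bases = np.array(list("ACGT"))
    a_idx = rng.integers(4, size=m)
    b_idx = (a_idx + 1 + rng.integers(3, size=m)) % 4
    snps = pd.DataFrame(
        {
            "snp_id": [f"m{j}" for j in range(m)],
            "chrom": rng.choice(["chr1", "chr2"], size=m),
            "pos": rng.choice(10**6, size=m, replace=False) + 1,
            "allele_a": bases[a_idx],
            "allele_b": bases[b_idx],
        }
    )
    snps["pos"] = snps["pos"].astype("Int64")
    return GenotypePanel(samples=samples, snps=snps, calls=calls.astype(np.int8))


@pytest.fixture
def toy_panel() -> GenotypePanel:
    return panel_from_tokens(
        ["AA AB BB", "AB -- AA"],
        ploidy=[2, 4],
        populations=["p1", "p2"],
        positions=[100, 200, 5000],
    )


def bookkeeping_panel() -> GenotypePanel:
    """20 samples (clusters X, Y of 10) × 10 SNPs with hand-computed
    MAF-filter and polymorphism-sharing results.

    Expected (allele-B counts over 2·n_called chromosomes):
      m1  all AA                      → MAF 0      → excluded; polymorphic nowhere
      m2  one AB in X                 → 1/40=0.025 → excluded; polymorphic {X}
      m3  two AB in X                 → 2/40=0.05  → retained (boundary); {X}
      m4  one AB in X, one AB in Y    → 2/40=0.05  → retained; {X, Y}
      m5  three BB in Y               → 6/40=0.15  → retained; {Y}
      m6  X: 5 AA + 5 BB, Y all BB    → MAF 0.25   → retained; {X}
      m7  all AB                      → MAF 0.5    → retained; single call class → nowhere
      m8  one missing in X, one AB in Y → 1/38≈0.026 → excluded; {Y}
      m9  one AB in X, two BB in Y    → 5/40=0.125 → retained; {X, Y}
      m10 all BB                      → MAF 0      → excluded; nowhere
    Retained after MAF < 0.05 filter: m3, m4, m5, m6, m7, m9 (6 SNPs).
    Venn cells: {X} only = {m2, m3, m6} = 3; {Y} only = {m5, m8} = 2;
    {X, Y} = {m4, m9} = 2; total polymorphic = 7.
    """
    rows = []
    for i in range(10):  # cluster X
        m1 = "AA"
        m2 = "AB" if i == 0 else "AA"
        m3 = "AB" if i < 2 else "AA"
        m4 = "AB" if i == 0 else "AA"
        m5 = "AA"
        m6 = "BB" if i < 5 else "AA"
        m7 = "AB"
        m8 = "--" if i == 0 else "AA"
        m9 = "AB" if i == 0 else "AA"
        m10 = "BB"
        rows.append(" ".join([m1, m2, m3, m4, m5, m6, m7, m8, m9, m10]))
    for i in range(10):  # cluster Y
        m1 = "AA"
        m2 = "AA"
        m3 = "AA"
        m4 = "AB" if i == 0 else "AA"
        m5 = "BB" if i < 3 else "AA"
        m6 = "BB"
        m7 = "AB"
        m8 = "AB" if i == 0 else "AA"
        m9 = "BB" if i < 2 else "AA"
        m10 = "BB"
        rows.append(" ".join([m1, m2, m3, m4, m5, m6, m7, m8, m9, m10]))
    return panel_from_tokens(
        rows,
        ploidy=2,
        populations=["X"] * 10 + ["Y"] * 10,
        positions=list(range(100, 1100, 100)),
    )


@pytest.fixture(name="bookkeeping_panel")
def bookkeeping_panel_fixture() -> GenotypePanel:
    return bookkeeping_panel()
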