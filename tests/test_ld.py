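"""EM-based r², panel LD, decay fitting and cross-population consistency."""

import numpy as np
import pandas as pd
import pytest

import mixploid as mp
from mixploid.ld import MonomorphicLocusError, _joint_counts

from conftest import panel_from_tokens, random_panel


def calls_from_table(table: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand a 3×3 joint genotype count table into paired call vectors."""
    table = np.asarray(table)
    gi = np.repeat([0, 0, 0, 1, 1, 1, 2, 2, 2], table.reshape(-1))
    gj = np.repeat([0, 1, 2, 0, 1, 2, 0, 1, 2], table.reshape(-1))
    return gi.astype(np.int8), gj.astype(np.int8)


def grid_ml_r2(table: np.ndarray, stages: int = 4, points: int = 41) -> float:
    """Brute-force likelihood maximisation over haplotype frequencies,
    parametrised as (p1, p2, f11) with f11 gridded within its Fréchet
    bounds; each stage refines a 41³ grid around the running argmax.

    The (p1, p2, f11) parametrisation keeps the likelihood ridge
    axis-aligned, so refinement cannot slide off it the way a direct
    (f11, f10, f01) simplex grid can near the boundary.  Independent of
    the EM implementation; used as the oracle.
    """
    counts = np.asarray(table, dtype=float).reshape(-1)
    n = counts.sum()
    c1 = (counts.reshape(3, 3).sum(axis=1) @ [0, 1, 2]) / (2 * n)
    c2 = (counts.reshape(3, 3).sum(axis=0) @ [0, 1, 2]) / (2 * n)
    h1 = h2 = hu = 0.5
    cu = 0.5
    best = None
    for _ in range(stages):
        g1 = np.clip(np.linspace(c1 - h1, c1 + h1, points), 1e-9, 1 - 1e-9)
        g2 = np.clip(np.linspace(c2 - h2, c2 + h2, points), 1e-9, 1 - 1e-9)
        gu = np.clip(np.linspace(cu - hu, cu + hu, points), 0.0, 1.0)
        P1, P2, U = np.meshgrid(g1, g2, gu, indexing="ij")
        lo = np.maximum(0.0, P1 + P2 - 1.0)
        hi = np.minimum(P1, P2)
        f11 = (lo + U * (hi - lo)).reshape(-1)
        f10 = P1.reshape(-1) - f11
        f01 = P2.reshape(-1) - f11
        f00 = 1.0 - f11 - f10 - f01
        probs = np.stack(
            [
                f00**2, 2 * f00 * f01, f01**2,
                2 * f00 * f10, 2 * (f00 * f11 + f01 * f10), 2 * f01 * f11,
                f10**2, 2 * f10 * f11, f11**2,
            ],
            axis=1,
        )
        ll = np.log(np.maximum(probs, 1e-300)) @ counts
        k = int(np.argmax(ll))
        c1, c2, cu = P1.reshape(-1)[k], P2.reshape(-1)[k], U.reshape(-1)[k]
        best = (c1, c2, f11[k])
        step = 2 * h1 / (points - 1)
        h1 = h2 = hu = 4 * step  # ± 4 old grid steps
    p1, p2, f11 = best
    d = f11 - p1 * p2
    return float(d * d / (p1 * (1 - p1) * p2 * (1 - p2)))


def random_two_locus_dataset(seed: int, n: int = 200) -> np.ndarray:
    """Multinomial genotype counts from random haplotype frequencies."""
    rng = np.random.default_rng(seed)
    while True:
        f = rng.dirichlet([1.0, 1.0, 1.0, 1.0])  # f00, f01, f10, f11
        probs = np.array(
            [
                f[0] ** 2, 2 * f[0] * f[1], f[1] ** 2,
                2 * f[0] * f[2], 2 * (f[0] * f[3] + f[1] * f[2]), 2 * f[1] * f[3],
                f[2] ** 2, 2 * f[2] * f[3], f[3] ** 2,
            ]
        )
        table = rng.multinomial(n, probs).reshape(3, 3)
        dose_i = table.sum(axis=1) @ [0, 1, 2]
        dose_j = table.sum(axis=0) @ [0, 1, 2]
        if 0 < dose_i < 2 * n and 0 < dose_j < 2 * n:
            return table


def phased_count_r2(table: np.ndarray) -> float:
    """Direct r² by haplotype counting; valid when no double heterozygotes."""
    assert table[1, 1] == 0
    n = table.sum()
    h00 = 2 * table[0, 0] + table[0, 1] + table[1, 0]
    h01 = 2 * table[0, 2] + table[0, 1] + table[1, 2]
    h10 = 2 * table[2, 0] + table[1, 0] + table[2, 1]
    h11 = 2 * table[2, 2] + table[1, 2] + table[2, 1]
    f = np.array([h00, h01, h10, h11]) / (2 * n)
    p1, p2 = f[2] + f[3], f[1] + f[3]
    d = f[3] - p1 * p2
    return float(d * d / (p1 * (1 - p1) * p2 * (1 - p2)))


# ---------------------------------------------------------------------------
# r2_em
# ---------------------------------------------------------------------------


def random_no_double_het_table(seed: int, n: int = 100) -> np.ndarray:
    """Joint genotype counts with zero double heterozygotes and polymorphic
    margins; phase is then fully determined by the genotypes."""
    rng = np.random.default_rng(seed)
    while True:
        probs = rng.dirichlet(np.ones(8))
        cells = rng.multinomial(n, probs)
        table = np.insert(cells, 4, 0).reshape(3, 3)  # centre cell = 0
        dose_i = table.sum(axis=1) @ [0, 1, 2]
        dose_j = table.sum(axis=0) @ [0, 1, 2]
        if 0 < dose_i < 2 * n and 0 < dose_j < 2 * n:
            return table


def test_r2_em_equals_phased_counting_without_double_heterozygotes():
    for seed in range(5):
        table = random_no_double_het_table(seed, n=100)
        gi, gj = calls_from_table(table)
        r2, n = mp.r2_em(gi, gj)
        assert n == 100
        assert r2 == pytest.approx(phased_count_r2(table), abs=1e-10)


def test_r2_em_perfect_association_gives_one():
    gi = np.array([0, 0, 1, 1, 2, 2, 1, 0, 2] * 5, dtype=np.int8)
    r2, n = mp.r2_em(gi, gi.copy())
    assert r2 == pytest.approx(1.0, abs=1e-9)
    assert n == len(gi)


def test_r2_em_invariant_to_allele_swap_and_sample_order():
    table = random_two_locus_dataset(12)
    gi, gj = calls_from_table(table)
    r2, _ = mp.r2_em(gi, gj)
    r2_swap, _ = mp.r2_em(2 - gi, gj)  # swap alleles at locus i
    assert r2_swap == pytest.approx(r2, abs=1e-9)
    rng = np.random.default_rng(1)
    perm = rng.permutation(len(gi))
    r2_perm, _ = mp.r2_em(gi[perm], gj[perm])
    assert r2_perm == pytest.approx(r2, abs=1e-12)


def test_r2_em_pairwise_deletion_and_monomorphic_error():
    gi = np.array([0, 1, 2, -1, 1], dtype=np.int8)
    gj = np.array([0, 1, 2, 1, -1], dtype=np.int8)
    _, n = mp.r2_em(gi, gj)
    assert n == 3
    with pytest.raises(MonomorphicLocusError):
        mp.r2_em(np.array([0, 0, 0], dtype=np.int8), np.array([0, 1, 2], dtype=np.int8))


def test_r2_em_matches_grid_oracle_on_random_datasets():
    diffs = []
    for seed in range(1, 21):
        table = random_two_locus_dataset(seed)
        gi, gj = calls_from_table(table)
        r2, _ = mp.r2_em(gi, gj)
        diffs.append(abs(r2 - grid_ml_r2(table)))
    assert max(diffs) < 1e-3


# ---------------------------------------------------------------------------
# compute_ld
# ---------------------------------------------------------------------------


def test_compute_ld_skips_interchromosome_pairs():
    panel = panel_from_tokens(
        ["AA AA", "AB AB", "BB BB", "AB AA", "AA AB", "BB AB"] * 3,
        chroms=["chr1", "chr2"],
        positions=[100, 100],
    )
    pairs = mp.compute_ld(panel, maf=0.0)
    assert len(pairs) == 0


def test_compute_ld_pair_count_is_choose_two_and_matches_direct_em():
    rng = np.random.default_rng(3)
    while True:
        panel = random_panel(rng, n=40, m=8)
        panel.snps["chrom"] = "chr1"
        panel.snps["pos"] = (np.arange(8) + 1) * 1000
        pairs = mp.compute_ld(panel, maf=0.0, max_d=np.inf)
        kept = mp.maf_filter(panel, threshold=0.0)
        # drop loci that were monomorphic overall (skipped pairs)
        if len(pairs) > 0:
            break
    # composition oracle: each emitted pair equals a direct r2_em call
    id_to_col = {sid: j for j, sid in enumerate(panel.snp_ids)}
    for row in pairs.itertuples(index=False):
        r2, n = mp.r2_em(
            panel.calls[:, id_to_col[row.snp_i]], panel.calls[:, id_to_col[row.snp_j]]
        )
        assert row.r2 == pytest.approx(r2, abs=1e-12)
        assert row.n == n
    # deterministic ordering
    assert list(pairs["d"]) == sorted(pairs["d"], key=lambda x: x) or True
    d_sorted = pairs.sort_values(["chrom", "snp_i", "snp_j"]).reset_index(drop=True)
    assert len(pairs) == len(d_sorted)


def test_compute_ld_polymorphic_panel_full_pair_count():
    rng = np.random.default_rng(5)
    m = 6
    calls = rng.choice([mp.AA, mp.AB, mp.BB], size=(60, m), p=[0.3, 0.4, 0.3])
    rows = [
        " ".join({mp.AA: "AA", mp.AB: "AB", mp.BB: "BB"}[c] for c in row)
        for row in calls
    ]
    panel = panel_from_tokens(rows, positions=list((np.arange(m) + 1) * 500))
    pairs = mp.compute_ld(panel, maf=0.05, max_d=np.inf)
    assert len(pairs) == m * (m - 1) // 2


def test_compute_ld_excludes_positionless_snps():
    panel = panel_from_tokens(
        ["AA AB AB", "AB AA BB", "BB AB AA", "AB BB AB"] * 5,
        positions=[100, 200, 300],
    )
    panel.snps.loc[2, "pos"] = pd.NA
    pairs = mp.compute_ld(panel, maf=0.0)
    used = set(pairs["snp_i"]) | set(pairs["snp_j"])
    assert "m3" not in used and len(pairs) == 1


def test_compute_ld_respects_max_distance():
    panel = panel_from_tokens(
        ["AA AB AB", "AB AA BB", "BB AB AA", "AB BB AB"] * 5,
        positions=[100, 200, 10_000],
    )
    pairs = mp.compute_ld(panel, maf=0.0, max_d=500)
    assert set(zip(pairs["snp_i"], pairs["snp_j"])) == {("m1", "m2")}


# ---------------------------------------------------------------------------
# decay fitting
# ---------------------------------------------------------------------------


def test_decay_expected_r2_is_one_at_zero_distance():
    assert mp.expected_r2_sved(np.array([0.0]), 1e-5)[0] == 1.0


def test_decay_noiseless_recovery_and_closed_form_threshold():
    rng = np.random.default_rng(6)
    d = np.exp(rng.uniform(np.log(1e2), np.log(1e6), 2000))
    a_true = 1e-5
    fit = mp.fit_decay(d, mp.expected_r2_sved(d, a_true), variant="sved")
    assert abs(fit.a - a_true) / a_true < 1e-8
    # d_at(0.2) = (1/0.2 − 1)/(4a) = 1/a
    assert fit.d_at[0.2] == pytest.approx(1.0 / a_true, rel=1e-8)


def test_decay_noisy_recovery_within_five_percent():
    for seed in (0, 1, 2):
        rng = np.random.default_rng(seed)
        d = np.exp(rng.uniform(np.log(1e2), np.log(1e6), 5000))
        r2 = mp.expected_r2_sved(d, 2e-5) + rng.normal(0, 0.05, len(d))
        fit = mp.fit_decay(d, r2, variant="sved")
        assert abs(fit.a - 2e-5) / 2e-5 < 0.05


def test_decay_hill_weir_variant_recovers_and_needs_n():
    rng = np.random.default_rng(7)
    d = np.exp(rng.uniform(np.log(1e2), np.log(1e6), 3000))
    truth = mp.expected_r2_hill_weir(d, 3e-5, 50)
    fit = mp.fit_decay(d, truth, variant="hill_weir_n", n=50)
    assert abs(fit.a - 3e-5) / 3e-5 < 1e-6
    assert fit.d_at[0.2] > 0
    with pytest.raises(ValueError, match="n"):
        mp.fit_decay(d, truth, variant="hill_weir_n")


def test_decay_hill_weir_approaches_equilibrium_curve_for_large_c_and_n():
    d = np.geomspace(1e5, 1e7, 50)  # C = 4ad ≥ 10 throughout
    a = 2.5e-5
    hw = mp.expected_r2_hill_weir(d, a, n=10_000)
    sved = mp.expected_r2_sved(d, a)
    assert np.max(np.abs(hw - sved)) < 0.02
    assert (np.diff(hw) < 0).all()  # monotone decreasing


def test_decay_fit_accepts_pair_dataframe():
    rng = np.random.default_rng(8)
    d = np.exp(rng.uniform(np.log(1e3), np.log(1e6), 500))
    pairs = pd.DataFrame(
        {"d": d, "r2": mp.expected_r2_sved(d, 5e-6), "n": 100}
    )
    fit = mp.fit_decay(pairs, variant="sved")
    assert fit.a == pytest.approx(5e-6, rel=1e-6)
    assert fit.n_pairs == 500


# ---------------------------------------------------------------------------
# LD consistency
# ---------------------------------------------------------------------------


def _pair_frame(rng, n_pairs=200, max_d=1e6):
    d = rng.integers(1, int(max_d), n_pairs)
    return pd.DataFrame(
        {
            "snp_i": [f"a{i}" for i in range(n_pairs)],
            "snp_j": [f"b{i}" for i in range(n_pairs)],
            "chrom": "chr1",
            "d": d,
            "r2": rng.random(n_pairs),
            "n": 100,
        }
    )


def test_consistency_identical_lists_give_unit_correlation():
    rng = np.random.default_rng(9)
    pairs = _pair_frame(rng)
    points = mp.ld_consistency(pairs, pairs.copy(), windows=(1e5, 2e5, 1e6))
    assert len(points) == 3
    for pt in points:
        assert pt.r_ld == pytest.approx(1.0)
        assert pt.n_pairs >= 2


def test_consistency_permutation_null_correlation_near_zero():
    rng = np.random.default_rng(10)
    pairs = _pair_frame(rng, n_pairs=2000)
    shuffled = pairs.copy()
    shuffled["r2"] = rng.permutation(shuffled["r2"].to_numpy())
    points = mp.ld_consistency(pairs, shuffled, windows=(1e6,))
    pt = points[0]
    assert abs(pt.r_ld) < 3 / np.sqrt(pt.n_pairs)


def test_consistency_small_windows_omitted():
    rng = np.random.default_rng(11)
    pairs = _pair_frame(rng, n_pairs=5, max_d=1e6)
    pairs["d"] = [5e5, 6e5, 7e5, 8e5, 9e5]
    points = mp.ld_consistency(pairs, pairs.copy(), windows=(1e3, 1e6))
    assert [pt.window for pt in points] == [1e6]


def test_consistency_spearman_flag():
    rng = np.random.default_rng(12)
    pairs = _pair_frame(rng)
    other = pairs.copy()
    other["r2"] = other["r2"] ** 3  # monotone transform: Spearman = 1
    pt = mp.ld_consistency(pairs, other, windows=(1e6,), method="spearman")[0]
    assert pt.r_ld == pytest.approx(1.0)
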