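# Methods

This note records the statistical model behind each stage, the default
parameter choices and why they were made, and the known limits of the
synthetic-data generators. Notation: a biallelic SNP has alleles A and B;
`p` is the frequency of B unless stated otherwise; `n` is the number of
samples, `d` physical distance in bp, `c` the recombination fraction
between two loci.

## Collapsed genotype model

Tetraploid SNP-array clusters rarely separate the five dosage classes
(AAAA … BBBB) reliably, so every call is collapsed to three classes:

- `AA` — only allele A observed,
- `AB` — both alleles observed (covers AAAB, AABB, ABBB),
- `BB` — only allele B observed,
- `--` — missing.

Consequences used throughout the package:

- **Allele frequencies** are computed in diploid equivalents:
  `freq(B) = (2·n_BB + n_AB) / (2·n_called)` regardless of ploidy. For a
  tetraploid, `AB` contributes one copy of each allele even though the true
  dosage is unknown; this is the only unbiased-in-expectation choice
  available without dosage information, and it makes diploid and tetraploid
  samples commensurable.
- **Heterozygosity** under Hardy–Weinberg at frequency `p` is
  `H = 1 − p^k − (1−p)^k` for ploidy `k`: at `p = 0.5` this is 50% for
  diploids and 87.5% for tetraploids. The collapsed coding therefore
  *mechanically* produces much higher observed heterozygosity in
  tetraploids at equal allele frequencies — a pattern that should not be
  read as a diversity difference.

## Synthetic data

### Wright–Fisher forward simulator

A population is a pool of `2·n_e` haplotypes over `n_loci` biallelic loci
placed uniformly at random on a single chromosome of `chrom_length` bp.
Each generation, every offspring haplotype picks two distinct parent
haplotypes and recombines them: each inter-locus interval `k` crosses over
independently with probability `c_k = rec_rate · interval_bp` (at most one
crossover per interval per meiosis — accurate for the small per-interval
values used here). At `split_generation` the pool is copied into
`n_subpops` independent pools which then drift apart. Sampled individuals
draw `ploidy` haplotypes with replacement from their pool; dosage is
collapsed to the three-class code and calls are masked at `missing_rate`.

Default parameters and the reasoning behind them:

| parameter | default | why |
| --- | --- | --- |
| `n_e` | 100 | small enough that 400 generations ≈ 4·n_e reaches drift–recombination equilibrium in seconds; large enough that `1/(2·n_e)` background r² (0.005) stays well below the signal |
| `n_loci` | 200 | 19,900 locus pairs per run — enough to bin r² against `c` while keeping a full simulation under a second |
| `chrom_length` | 1 Mbp | one chromosome; pairs span the full `c` range of interest |
| `rec_rate` | 1e-7 /bp | with a 1 Mbp chromosome this puts pairwise `c` in ≈ 1e-5 … 0.1, so the equilibrium curve `E(r²) = 1/(1+4·n_e·c)` crosses 0.2 at ≈ 100 kbp — inside the simulated length. A rate of 1e-8 (a common genome-wide figure) would make the whole chromosome one linkage block at this length; we trade per-bp realism for a resolvable decay curve at desk scale. |
| `n_generations` | 400 | `4·n_e`, the standard burn-in for near-equilibrium LD |
| `founder_freq` | U(0.1, 0.9) | avoids loci that start nearly fixed and are lost immediately to drift |
| `samples_per_pop` / `ploidy_per_pop` | 30 / (4, 2) | a mixed-ploidy two-population design exercising every collapsed-code path |

Validation rejects `rec_rate · chrom_length > 0.5` (the per-interval
Bernoulli crossover model breaks down) and `split_generation >
n_generations`.

Known limits: no mutation (lost polymorphism is not replenished, so deep
splits leave few shared polymorphic loci); a single chromosome; no
selection; tetraploids are sampled as four independent haplotypes
(autopolyploid random chromosome segregation, no double reduction).

### Balding–Nichols panels

For clean structure benchmarks: subpopulation `k` draws its frequency for a
locus with ancestral frequency `p` from
`Beta(p(1−F)/F, (1−p)(1−F)/F)`, so `E(p_k) = p` and
`Var(p_k) = p(1−p)·F` with `F` the target FST. Loci are unlinked (each on
its own pseudo-chromosome), genotypes are Hardy–Weinberg draws. This
generator has structure but no LD — the complement of the Wright–Fisher
simulator, which has LD but only simple structure.

## Preprocessing

- **Presence/absence encoding.** Each SNP becomes two 0/1 columns
  (A present, B present): `AA → (1,0)`, `AB → (1,1)`, `BB → (0,1)`,
  missing → NaN. This is the natural codominant encoding for collapsed
  mixed-ploidy calls, since a dosage encoding (0/1/2) would assign
  tetraploid heterozygotes a fake dosage.
- **Imputation** replaces NaNs with the column mean (a column that is
  entirely missing is an error naming the SNP). Mean imputation is neutral
  for PCA: imputed entries sit at the centroid and contribute nothing to
  covariance.
- **MAF filter**: a SNP is retained when `min(f, 1−f) ≥ threshold`
  (default 0.05) among called samples — i.e. *strictly below* 5% is
  excluded, exactly 5% is kept. The filter is computed **within the
  analysis group** when one is given (e.g. per population for LD): a locus
  monomorphic in the analysed population is uninformative there even if
  polymorphic elsewhere, and near-monomorphic loci make r² estimates
  unstable.
- **Polymorphism sharing**: a SNP is polymorphic in a group when at least
  two distinct call classes occur among its called samples; the Venn cell
  counts partition the SNPs polymorphic anywhere.

## Structure

- **PCA** is computed by SVD of the column-centred presence/absence matrix
  (covariance PCA, no variance scaling). The two columns of a SNP are
  complementary and already on a common 0/1 scale; correlation-scaling
  would up-weight near-monomorphic SNPs, which is exactly what the MAF
  filter tries to avoid. Signs are fixed by making the largest-magnitude
  loading of each component positive. Default 5 components.
- **Clustering**: Gaussian mixtures fitted to the PC scores for each
  K in `K_range` (default 1…8) and each covariance model (spherical,
  diagonal, full), selected by BIC in the "maximize 2·logL − m·ln n"
  orientation.
- **Nei (1972) standard distance** between groups X and Y:
  `D = −ln( J_XY / sqrt(J_X · J_Y) )` with `J_XY = Σ_loci Σ_alleles x_i y_i`
  and the sums over loci taken *before* the ratio (the convention used by
  the common population-genetics spreadsheets). Loci with a frequency
  defined in both groups contribute; `D(X, X) = 0` exactly (a
  Cauchy–Schwarz equality that the implementation clamps against −0.0
  rounding), and disjoint fixation gives `+inf`.
- **Neighbor-joining** follows Saitou & Nei with the standard Q-criterion.
  Negative branch lengths (possible on non-additive inputs) are clamped to
  zero with the deficit transferred to the sibling branch, preserving path
  lengths between leaves as far as possible; on additive matrices the
  reconstruction is exact (tested to 1e-9, observed ~1e-15). The tree is
  returned as a `skbio.TreeNode` and written as Newick.

## Linkage disequilibrium

- **Two-locus r² from unphased genotypes.** For a pair of collapsed-call
  loci the 3×3 genotype table is a mixture over unobserved haplotype
  phase only in the double-heterozygote cell (AB/AB splits into coupling
  AB|ab vs repulsion Ab|aB). Haplotype frequencies are estimated by EM:
  the E-step splits the double-heterozygote count by the posterior odds
  `f00·f11 : f01·f10`; the M-step re-normalises haplotype counts.
  `r² = D² / (p_A p_a p_B p_b)` with `D = f11 − p1·p2`. Samples missing at
  either locus are dropped pairwise; a locus monomorphic among the
  analysed samples raises `MonomorphicLocusError`. The acceptance suite
  checks the EM against a brute-force likelihood grid over
  `(p1, p2, f11)` — agreement within 1e-3 on random datasets, and exact
  agreement with direct haplotype counting when no double heterozygotes
  occur. Tetraploid `AB` calls enter the same 3×3 table; this treats them
  as diploid-equivalent, consistent with the collapsed model.
- **Decay curves.** Two expectation functions of `C = 4·a·d` are
  available: the drift–recombination equilibrium (Sved) form
  `E(r²) = 1/(1+C)`, and the Hill & Weir finite-sample form
  `E(r²) = [(10+C)/((2+C)(11+C))] · [1 + ((3+C)(12+12C+C²))/(n(2+C)(11+C))]`,
  which adds the `O(1/n)` sampling inflation and is the standard choice
  for fitting observed panels (it needs `n`). The single coefficient `a`
  (per-bp) is fitted by Levenberg–Marquardt least squares on `log a` (the
  parameter spans orders of magnitude and must stay positive), initialised
  from the median data point. The decay distance at a target r² (default
  0.2) is closed-form for the Sved curve (`d = (1/t − 1)/(4a)`) and solved
  by Brent's method for Hill–Weir. Fits warn when the distance range spans
  fewer than two decades.
- **Cross-population consistency (r_LD)** is the Pearson correlation
  (Spearman available) of r² over the SNP pairs shared between two
  populations, within a maximum-distance window. Identical populations
  give r_LD = 1; independent phase gives r_LD ≈ 0. Caveat: because r²
  decays with distance in *both* populations, wide windows induce a
  positive correlation from the shared distance trend alone; short windows
  (≤ 100 kbp at the default simulation scale) isolate the phase signal,
  and that is where the statistic responds monotonically to divergence
  time.

## Reproducibility

All stochastic stages take explicit integer seeds. The simulator derives
three independent substreams (evolution, sampling, missingness) from one
`SeedSequence`, so enabling or disabling missingness does not perturb the
genotypes. The CLI echoes every effective configuration next to its
outputs; `scripts/acceptance.py --seed S --out report.json` regenerates the
headline quantities from scratch for any seed.
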