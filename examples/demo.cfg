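# End-to-end demo: simulate a two-subpopulation mixed-ploidy panel and
# analyse it.  Flat key = value format; unknown keys are an error.

# --- simulation ---
n_e = 100                 # Wright-Fisher population size (2*n_e haplotypes)
n_loci = 200
chrom_length = 1000000    # bp
rec_rate = 1e-7           # crossovers per bp per meiosis
n_generations = 400       # 4*n_e: drift-recombination equilibrium
n_subpops = 2
split_generation = 200
samples_per_pop = 30
ploidy_per_pop = 4,2      # one tetraploid and one diploid subpopulation
missing_rate = 0.01
seed = 7

# --- analysis ---
maf = 0.05                # SNPs with minor allele frequency < maf excluded from LD
r2_target = 0.2           # report distance at which fitted E(r^2) crosses this
n_pcs = 5
k_min = 1
k_max = 8
decay_variant = sved      # or hill_weir_n
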