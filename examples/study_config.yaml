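# fragpop pipeline configuration reproducing the bear-study settings.
#
# Run with:  fragpop run examples/study_config.yaml
# (after placing the converted supplementary data files under data/ —
#  see the README section on reproducing the published analysis).

# ---- inputs ---------------------------------------------------------------
# Delimited genotype table: individual_id, sex, period, then one
# "<allele1>/<allele2>" column per microsatellite locus (0/0 = missing).
genotypes: data/s1_genotypes.csv
# secr-style capture file: session, individual, occasion, trap_id [, sex]
captures: data/s2_captures.csv
# trap layout: session, trap_id, x, y   (planar km; one block per year
# because traps were moved between sessions)
traps: data/s2_traps.csv
# Binary natural-cover raster (ESRI ASCII); nodata = open water.
raster: data/cover.asc

output_dir: fragpop_out

# ---- stage toggles --------------------------------------------------------
do_popgen: true        # Table-1-style diversity summary
do_ne: true            # LD effective size + life-history adjustment
do_bottleneck: true    # SMM/TPM heterozygosity-excess tests
do_fca: true           # correspondence analysis + immigrant screen
do_scr: true           # sex-specific density models
do_frag: true          # fragmentation metrics

# ---- state space ----------------------------------------------------------
buffer: 12.0           # km around traps (the study's optimized buffer)
spacing: 1.0           # km between mask points
window_radius: 3.2     # km, moving-window percent-cover covariate
                       # (radius of the mean female home range)

# ---- population genetics --------------------------------------------------
maf: 0.05              # minimum allele frequency for the LD-Ne screen
alpha: 4.0             # age at sexual maturity (years, primiparity)
max_age: 24.0          # maximum age (years); adult life span = 24-4+1 = 21
tpm_p_multistep: 0.30  # two-phase model: 30% multi-step mutations
bottleneck_reps: 10000 # coalescent replicates per locus
n_boot: 1000           # locus bootstrap iterations for diversity CIs
hwe_permutations: 1000

# ---- SCR model set --------------------------------------------------------
# Fit per sex; density ~1 (homogeneous), ~session (year factor) or
# ~pnat (log-linear in percent natural cover); g0 terms: bk (trap-specific
# behavioural response) and/or h2 (2-class finite mixture); sigma fixed.
models:
  - {density: "~1",       g0: "~bk"}
  - {density: "~1",       g0: "~bk+h2"}
  - {density: "~session", g0: "~bk"}
  - {density: "~session", g0: "~bk+h2"}
  - {density: "~pnat",    g0: "~bk"}
  - {density: "~pnat",    g0: "~bk+h2"}
sexes: [F, M]

seed: 1
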