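# Methods

`fragpop` implements the three-legged analysis used in noninvasive
genetic capture-recapture studies of small, fragmented carnivore
populations: spatial capture-recapture (SCR) density estimation,
microsatellite population genetics, and landscape fragmentation
metrics, plus seeded generators that emulate the hair-trap sampling
design so the whole pipeline can be validated without field data.
This note records the models, the parameter choices that matter, and
the places where the design was genuinely open.

## Spatial capture-recapture

**Model.** Detections are binary per individual × trap × occasion
(proximity detectors: an animal can be detected at several traps in one
occasion).  Detection probability declines with distance from a latent
activity center `x` as a half-normal,

    p_jk(x) = g0 · exp(−d(x, trap_j)² / (2σ²)),

with `g0` on a logit link and `σ` (km) on a log link.  Supported
submodels:

* **bk** — trap-specific behavioural response: after an individual's
  first capture at a trap, `logit(g0)` at that trap shifts by a fitted
  amount for the rest of the session.  The response resets between
  sessions because traps are moved between years.
* **h2** — 2-class finite mixture on `g0` with a multinomial-logit
  mixing proportion, absorbing individual heterogeneity.
* **Density** — homogeneous (`~1`), session factor (`~session`), or
  log-linear in a habitat covariate (`~pnat`), all on a log link, in
  animals/km².

**Likelihood.** The full (Poisson-N) likelihood integrates activity
centers over a discretized habitat mask (lattice points within a
buffer of any trap; cell area = spacing²).  Per session,

    logL_s = Σ_i log Σ_x a·D(x)·P(y_i | x) − Λ_s − log n_s!,
    Λ_s    = Σ_x a·D(x)·p·(x),

where `P(y_i | x)` is the Bernoulli product over traps and occasions
(mixture-marginalized under h2; bk states reconstructed from the
observed history) and `p·(x)` is the probability of at least one
detection, computed from pre-first-capture probabilities.  Sessions
share detection parameters; the total is the sum of session
contributions.  The implementation reduces each individual's history
to four per-trap sufficient statistics (detections/non-detections in
the pre/post-capture state), making the evaluation a handful of
matrix products; it is verified to 1e-10 against exhaustive
enumeration on small problems (all submodel combinations).

**Fitting and inference.** Quasi-Newton (L-BFGS-B) maximization with
numeric gradients from data-driven starts (σ from mean recapture
displacement, D from detected individuals per unit mask area, g0 from
the raw detection rate), with up to 3 jittered restarts; the
coefficient covariance is the inverse finite-difference Hessian.  CIs
are Wald on the link scale and back-transformed, hence asymmetric
(lognormal for D and σ, logit-normal for g0).  Model selection uses
AICc with `n` equal to the number of detected individuals summed over
sessions — the convention that makes the criterion's small-sample
penalty reproducible from per-session capture counts alone.  Derived
abundance is `N = D × habitat area`, where the area is the
habitat-flagged portion of the mask (the full buffer is always used
for integration; the habitat flag only scales `N`).  Combined-sex
density and abundance add the sex-specific estimates with independent
SEs (`SE² = SE_F² + SE_M²`) and a symmetric normal CI; a sex-ratio
difference is flagged when the sex-specific 95% CIs do not overlap.

**Posterior activity centers.** For each detected individual,
`π(x | y_i) ∝ D̂(x)·P(y_i | x)` over mask points, normalized to 1;
the mode breaks ties toward the lowest mask index with a logged
warning.

## Population genetics

* **Diversity.** H_O is the heterozygote fraction; H_E is Nei's
  unbiased gene diversity `(2n/(2n−1))(1 − Σp²)` (plain form behind a
  flag); multilocus values are unweighted locus means.  Allelic
  richness uses hypergeometric rarefaction to `g` gene copies, with
  `g` defaulting to the minimum gene-copy count across periods and
  loci so that periods of unequal sample size are comparable.  F_IS is
  the Weir–Cockerham single-population estimator (ratio of summed
  variance components over loci and alleles).  CIs for all four come
  from a percentile bootstrap over loci (default 1,000 iterations,
  seeded).
* **Identity.** Per locus `PI = Σp⁴ + Σ_{i<j}(2p_ip_j)²` and
  `PI_sibs = 0.25 + 0.5Σp² + 0.5(Σp²)² − 0.25Σp⁴`, multiplied across
  loci.
* **Equilibrium tests.** Hardy–Weinberg: per-locus Monte-Carlo
  permutation of gene copies with a |H_O − H_E| statistic, combined
  across loci by Fisher's method (χ² on 2L df), with Bonferroni
  flags.  Linkage disequilibrium: per locus pair, the G
  (log-likelihood-ratio) statistic of the joint genotype table against
  a permutation null (one locus shuffled across individuals); pairs
  with fewer than 5 complete individuals are flagged untestable.
* **Null alleles.** A one-tailed homozygote-excess permutation test
  per locus plus the Brookfield-1 estimate `r̂ = (H_E − H_O)/(1+H_E)`.

## Effective size

The LD method computes Burrows' composite disequilibrium Δ̂ (with the
S/(S−1) correction) for every allele pair across every locus pair,
squares it against the `p(1−p)q(1−q)` denominator, and averages with
weights = allele comparisons × pair sample size (configurable).
Alleles below the MAF cutoff (default 0.05) are dropped; a diallelic
locus contributes one allele (the second is algebraically redundant).
The expected sampling component — `1/S + 3.19/S²` for S ≥ 30, else
`0.0018 + 0.907/S + 4.44/S²` (random mating) — is subtracted and the
drift relation inverted; a non-positive drift signal reports an
infinite estimate.  CIs come from a delete-one jackknife over locus
pairs, transformed through the same inversion (bounds therefore
swap).  Validation: recovery of a known N_e = 50 from forward
Wright–Fisher simulation (median within 20% over 200 replicates).

**Overlapping generations.** Bears are iteroparous; the raw LD
estimate of the effective number of breeders N_B is corrected with the
two-trait regressions in `fragpop/data/waples_adjustment.json`
(functions of `log₁₀(AL/α)`, with α = age at maturity, default 4 y,
and adult life span AL = max_age − α + 1, default 21 y), then mapped
to N_E.  The chain raw N_B → adjusted N_B → N_E is exposed at every
step because the two printed quantities a user may want to compare
against can sit in a very different ratio than these regressions
produce at AL/α ≈ 5: keeping the chain inspectable localizes any such
discrepancy instead of absorbing it.  The coefficients live in a data
file so a correction never touches code.

## Bottleneck tests

After a recent crash, rare alleles disappear faster than gene
diversity, so observed H_E exceeds the equilibrium expectation for the
observed allele count.  `heq_distribution` simulates a single-locus
Kingman coalescent with stepwise mutations (SMM) or a two-phase model
(TPM: default 30% multi-step mutations with geometric step sizes of
variance 12), calibrates θ by bisection so the expected allele count
matches the observed k, and retains replicates with exactly k alleles.
Both the observed and the simulated heterozygosity use plain gene
diversity `1 − Σp²` so the two sides of the comparison are on the same
footing (and the 2-allele bound H ≤ 0.5 holds exactly).  The
across-locus test is a one-tailed Wilcoxon signed-rank for excess
(two-tailed available).  Calibration is verified on data generated by
the same coalescent at constant size (p roughly uniform), and power on
a forward-simulated 90% crash; the SMM variant is conservative
relative to TPM on post-crash data, as expected.

## Factorial correspondence analysis

Individuals are embedded by correspondence analysis of the
individuals × allele-count matrix (0/1/2 copies per allele column):
SVD of the doubly standardized frequency matrix, eigenvalues = squared
singular values, total inertia their sum, row principal coordinates
reported.  Candidate immigrants are flagged by Mahalanobis distance on
the first two axes (threshold 3, with one re-weighting pass excluding
initial flags) — a reproducible replacement for reading outliers off a
plot.  Because "percent inertia among individuals" is ambiguous, both
the total inertia and the first-two-axes share are reported and
neither is asserted in tests.

## Landscape metrics

Patches are connected components of natural cells (8-neighbour rule by
default).  Percent habitat is relative to *land* area (nodata = open
water excluded); patch density is patches/km²; contagion uses the
standard formula from class proportions and double-counted 8-neighbour
adjacencies (boundary and nodata pairs excluded), verified against a
brute-force adjacency counter.  A property worth remembering when
reading contagion values: with two classes at equal proportions the
metric cannot exceed 50, so a ~48%-habitat landscape reading ~30–40 is
"aggregated" only relative to that cap.  The `pnat` covariate is the
fraction of natural cover among cells whose centers fall within a
circular window (default radius 3.2 km, the mean female home-range
radius); edge cells use the within-raster part of the window.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the study design: a ~48%-natural fragmented
landscape (thresholded smoothed Gaussian noise; autocorrelation scale
controls contagion; ~5.6% of the extent masked as lakes), a 4-km
sampling grid with traps only in cells ≥ 20% natural cover, 3 sessions
× 8 occasions of Bernoulli half-normal detections with bk and h2
options, ~35% per-detection genotyping failure, and HWE multilocus
genotypes with optional inbreeding, forward Wright–Fisher bottleneck,
and drifted-source immigrants.  Known divergences from the real data:

* Activity centers are redrawn independently per session (the
  multi-session model's own assumption); real bears persist across
  years, so between-year dependence is not emulated.
* Genotyping failure is independent binary thinning of detections; the
  real subsampling operated on physical hair samples per trap-occasion.
* The generated landscapes qualify a larger share of grid cells
  (~50–70%) for trapping than the real 36.5%, because the real grid
  was also constrained by citrus groves and survey practicality that
  the generator does not model.
* Genotypes have no scoring error or allelic dropout.

Passing tests therefore demonstrate correctness of the estimators
under the stated models at the study's scale — not robustness to the
unmodeled features above.

**Parameter-recovery study.** 100 replicates at the study scale
(threshold-placed 4-km grid of ~80 traps on a 48×42-km landscape, 3 × 8
occasions, D_F = 0.039 / D_M = 0.015, σ_F = 2.626 / σ_M = 8.098 km,
g0_F = 0.126 / g0_M = 0.025), fitting the generating homogeneous model
per sex on a 2-km-spacing, 10-km-buffer mask.  The coarser-than-field
mask spacing is a deliberate discretization choice validated by a
separate likelihood-stability check (halving the spacing moves the
log-likelihood by < 0.01).  Median relative bias of combined D̂ is
< 5% and Wald CI coverage ≈ 95%.

**Detector-placement experiment.** The experiment quantifies the
caveat that placing detectors only in quality habitat hampers
estimation of density–habitat relationships.  Its default conditions
are chosen to represent the caveat's mechanism: fragmentation at
block scale (6-km landscape autocorrelation, structure larger than a
sampling cell) and detection more local than the trap spacing
(σ = 1.5 km on a 4-km grid), so that threshold placement truncates the
covariate range actually sampled.  Under these conditions the RMSE of
the estimated slope under threshold placement is consistently about
twice that under uniform placement (direction asserted, magnitude
not).  With fine-grained landscapes or σ comparable to the grid
spacing the effect largely dissolves, because the buffer around any
trap then samples the full covariate range — itself an instructive
boundary on the caveat.

## Numerical choices and degenerate inputs

* All Monte-Carlo procedures take explicit integer seeds; generators
  are bit-reproducible for a fixed seed.
* Likelihood evaluations clip detection probabilities to
  [1e-300, 1−1e-12]; non-finite objective values return a large
  penalty and are logged.
* Optimizer tolerances: ftol 1e-10, gtol 1e-7, ≤ 500 iterations, 3
  jittered restarts; non-converged fits are flagged and excluded from
  model tables.
* Monomorphic loci are excluded (with a log entry) from HWE, LD,
  bottleneck, and richness-comparison computations; an all-monomorphic
  table yields F_IS = NaN, zero FCA inertia, and an error from the LD
  N_e estimator.
* A non-positive LD drift signal reports N̂ = ∞ with an infinite upper
  bound rather than a negative estimate.
* Contagion is NaN with fewer than two classes present; an all-nodata
  raster is an error.
* Posterior-mode ties break to the lowest mask index with a warning.

## Known limitations

* Euclidean distances on a planar metric CRS only; no reprojection,
  no least-cost distance.
* Poisson-N likelihood only (no binomial-N, no Bayesian/MCMC fits, no
  open-population or telemetry-integrated models).
* No between-population statistics (single population by design) and
  no model-based clustering for the immigrant screen.
* Raster I/O is ESRI ASCII text only.
* The bottleneck θ-calibration caches by (k, n, model) with an
  internal deterministic seed; extremely high allele counts relative
  to n_genes can make the exact-k rejection step slow (a warning
  reports the realized acceptance).
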