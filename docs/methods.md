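# Methods

This note documents the models, estimators and numerical choices behind
`yewoffset`, and what the synthetic-landscape experiments do and do not
demonstrate.

## Population-level design

All association and offset models operate on the populations x SNPs
alternate-allele frequency matrix `F`, not on individual genotypes. With a
few dozen populations and thousands of SNPs this trades individual-level
power for robustness and speed, and matches the resolution at which
climate data exist (one climate normal per population). Pre-processing:

* **Filtering** — SNPs with more than 30% missing calls, then individuals
  with more than 30% missing calls, then SNPs with minor-allele count
  below 20 counted over the retained individuals. The order matters
  because the MAC depends on which individuals survive; it is fixed and
  logged. With 475 diploids, MAC 20 corresponds to a MAF of 2.11%.
  A separate "structure" preset (15% missingness, no MAC filter) feeds the
  PCA, because rare variants carry structure information and missingness
  biases it.
* **Imputation** — missing calls take the modal genotype of the
  individual's gene pool (k-means on the leading genotype PCs, K = 2) at
  that SNP; ties break toward the lower code, and a pool with no calls
  falls back to the global mode. Modal imputation is crude but the
  downstream models consume population frequencies, where its bias is
  second-order.
* **LD pruning** — greedy left-to-right scan within each contig, dropping
  any SNP whose squared Pearson correlation of genotype codes
  (pairwise-complete) with an already-kept SNP reaches the threshold
  (default r² < 0.7). Deterministic and order-stable; SNPs on different
  contigs are never compared.

## Climate predictor selection

Forward selection against the constrained ordination: at each step the
candidate variable maximizing the Ezekiel-adjusted R² is proposed and
admitted only if the permutation p-value of its marginal pseudo-F
(candidate rows permuted; 999 permutations, alpha 0.05) passes, and the
growing model's adjusted R² does not exceed the full preselected model's
(the classic double stopping rule; the second stop is skipped at
alpha >= 1, where the caller asks for exhaustive admission). Pairs with
|Pearson r| strictly above 0.75 then lose their lower-priority member, and
variables are dropped by largest VIF until all VIFs are below 10. Columns
are standardized internally, so selection is invariant to affine
rescaling. Geography covariates are dbMEMs: great-circle distances
truncated at the longest minimum-spanning-tree edge (beyond: 4x the
truncation), double-centered and eigendecomposed, keeping eigenvectors
with positive eigenvalues whose Moran's I (under the within-truncation
neighbour graph) exceeds the null expectation -1/(n-1).

## Constrained ordination and variance partitioning

`RDA` centers `F`, standardizes predictors, optionally residualizes both
on a conditioning block (pRDA), and eigendecomposes the fitted values via
SVD. `R²` is the constrained inertia over the *total* centered inertia
(before conditioning), so the partial R² of the three pRDA models plus the
confounded remainder reproduce the full model's R² exactly (identity
asserted to 1e-10). Permutation p-values permute rows of the residualized
predictor block against the fixed response. The confounded fraction can
be negative when blocks act as suppressors.

## Candidate scans and their calibration

The calibration of each scan was measured on null landscapes (no adaptive
loci, 30 populations x 2000 SNPs, structured drift and climate-geography
correlation) by the any-false-discovery rate at q <= 0.10, which BH should
hold near 0.10 under the global null.

* **RDA/pRDA outliers** — squared Mahalanobis distance of per-SNP loading
  vectors on the first K = 2 constrained axes. Loadings are projections of
  *unit-variance* centered SNP columns; on raw frequency columns the
  loading cloud is a scale mixture across loci and its tails are far
  heavier than chi-square (measured null any-rate 0.63). Center and
  scatter come from a minimum covariance determinant (MCD) fit, because
  the classical covariance is stretched by the very outliers being sought
  and masks them at a few percent of adaptive loci. D² is rescaled by the
  median-based genomic inflation factor, referred to chi²_K, and
  BH-adjusted. Measured null any-rate: 0.00-0.03.
* **LFMM (ridge / truncated-SVD variant)** — one-shot estimation: ridge
  regression of `F` on climate, leading K = 2 left singular vectors of the
  residual as latent factors, then per-SNP OLS on [climate, factors].
  t statistics are mapped through their Student null to z-scores before
  GIF calibration (at ~20 residual dof, treating t² as chi²₁ is badly
  anticonservative: measured null any-rate 1.0 without the mapping).
  Candidate calls Bonferroni-correct across climate variables within each
  SNP and run a single BH family across SNPs; unioning per-variable BH
  families multiplies the error rate by the variable count (measured 0.33
  vs 0.07 after the fix). With K = 0 the estimator reduces exactly to
  per-SNP OLS t-tests.
* **Gradient-forest-lite** — one bagged regression forest per SNP
  (default 50 trees, max_features = p/3, min_samples_leaf 2) of allele
  frequency on climate; importance is the out-of-bag R², truncated at 0.
  Candidates are the intersection of top-5% importance sets across
  independently seeded runs (default 5). The structure-corrected variant
  first removes the LFMM latent-factor fit from `F`. In-forest
  split-impurity decreases, rescaled so each SNP contributes its OOB R²,
  accumulate into per-variable cumulative-importance (turnover) step
  functions, clamped to the training climate range.

Consensus candidates (>= 2 methods) are LD-pruned into the *outlier set*;
*random sets* are drawn from never-flagged SNPs, matched to the outlier
set's minor-allele-frequency profile in 10 equal-width bins over [0, 0.5]
(nearest-MAF fill-in when a bin runs short, logged).

## Offsets, GDI, robustness

The RDA offset projects standardized reference and future climates through
the fitted coefficients onto the first K axes and takes the Euclidean
distance with each axis coordinate multiplied by its eigenvalue share
w_k = λ_k/Σλ (the "axis importance" weight; a config switch could use
√λ, but the variance fraction is the default and the tests pin it). The
GF offset transforms each climate variable through its turnover function
and measures the distance between transformed vectors. Offsets are
averaged across GCMs, min-max normalized across populations (an all-equal
vector maps to zeros with a warning), and cut into five equal-occupancy
classes (sizes differ by at most one; ties break by population order).
Two methods are "congruent" for a population when their classes differ by
less than two; |Δclass| >= 2 flags non-robustness.

The GDI compares each population's observed scores (centered frequency
vector projected on the axes) with its climate-predicted scores, same
weighting, min-max normalized. It is exactly zero everywhere when `F` is
exactly linear in climate.

Garden (transplant) offsets replace the future climate with a common
garden's climate vector and otherwise reuse the same machinery.

## Trait models and validation

Each trait is modeled as `Y_ijk = μ + pop_i + geno_j(i) + ε_ijk` with
Gaussian random intercepts, after averaging repeated measures per
individual; growth-type traits can absorb fixed covariates (e.g. stem
length, centered). REML (statsmodels linear mixed models) is the default —
deterministic, and its BLUPs match the closed-form shrinkage estimator on
balanced designs; a Gibbs sampler with weak inverse-gamma priors (0.001,
0.001) is available and its posterior means of pop_i agree with the REML
BLUPs to r > 0.98 in tests. If the full fit fails, the genotype term is
dropped with a warning. Populations with fewer than 3 measured plants are
excluded. The composite trait index min-max standardizes each trait's
BLUPs across the shared populations and averages with equal weights (a
constant trait contributes 0.5 for everyone; a single trait reproduces its
standardized BLUPs). Validation reports, per (method x SNP set x trait),
Pearson's r with its two-sided p and the OLS slope of fitness on offset;
negative r is the direction consistent with maladaptation. BLUP
uncertainty is reported but not propagated into the validation models.

## The synthetic landscape

`simulate_landscape` emulates: two gene pools mixing linearly along an
east-west (longitude) gradient; neutral loci from Balding-Nichols beta
draws (pool differentiation at `drift_fst`, within-pool drift at
`drift_fst`/3); a fraction `frac_adaptive` of loci whose population
frequencies are logistic clines (slope in logit units per climate SD) in
one designated driver variable; six climate variables sharing one spatial
factor (loadings <= 0.7, pairwise |r| <= ~0.6) plus independent variation;
genotypes as two Bernoulli draws per individual (HWE within population)
through a Gaussian copula whose AR(1) dependence within contigs creates
LD while preserving every locus's Binomial(2, p) marginal; missing calls
at a uniform rate. Future climates add the per-variable mean shift
`future_shift` modulated by a per-population latitude factor (0.6-1.4,
mimicking polar amplification — a spatially uniform shift would displace
every population identically and make the linear offset degenerate across
populations), plus per-GCM jitter of 5% of the shift. Phenotypes decline
with the Gaussian-kernel climate distance between a population's origin
and the garden along the driver variables, with genotype-level (sd
noise/2) and residual (sd noise) Gaussian noise across clones and ramets.

Defaults (29 populations, 16 trees each, 2000 SNPs, 5% adaptive loci, six
climate variables, five GCMs, drift FST 0.15, seed 17) mirror a
range-wide conifer sampling design at desk scale. What the generator does
*not* emulate: coalescent/recombination realism, selection over time,
ascertainment bias of SNP panels, non-Gaussian climate errors, G×E in the
garden. Passing tests therefore demonstrate statistical behaviour of the
estimators under a controlled architecture, not performance guarantees on
real data.

## Problem sizes and known limitations

The test and acceptance experiments run at 18-30 populations, 150-2000
SNPs, 10-100 replicate seeds — sizes chosen so the full suite exercises
every stage at meaningful power. Known limitations:

* RDA and GF offsets rank populations by different functionals — the
  linear offset by projected displacement magnitude, the turnover offset
  by how much cumulative importance lies between the reference and future
  climate (and by clamping at the training range). Their cross-method rank
  agreement on synthetic landscapes is moderate (Spearman ~0.3-0.45), a
  genuine property of the two methods rather than an estimation artifact:
  substituting a forced-linear turnover raises agreement to ~0.9.
  Within-method agreement across SNP sets is high, and both offsets
  correlate negatively with simulated fitness proxies.
* The pRDA conditioned on ancestry PCs removes climate-collinear adaptive
  signal along with structure; under a strong climate-structure
  correlation it is conservative (few candidates), which is why the
  consensus rule works from the union of several scans.
* The forward-selection significance test permutes the candidate's rows
  (not residuals); with very few populations its null distribution is
  coarse (p resolution 1/(n_perm+1)).
* GF-lite turnover functions are step functions supported on observed
  split points; outside the training climate range they are clamped, so
  large extrapolations saturate.
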