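# yewoffset

Genomic-offset analysis for range-wide tree population genomics: detect
climate-associated loci, predict per-population maladaptation under future
or transplant climates, and validate the predictions against common-garden
fitness proxies. The package targets the study design of a range-wide
*Taxus baccata* (English yew) sample — a few dozen populations genotyped at
thousands of SNPs, per-population climate normals for a reference period
and several future GCM projections, and a clonal common-garden trial — but
all components are generic population-level tools.

## What it computes

**Genotype–environment association (GEA).** Population allele frequencies
`F` (populations x SNPs) are regressed on climate by redundancy analysis
(RDA): `F ~ climate`, optionally conditioned on ancestry PCs (pRDA). The
constrained axes come from the eigendecomposition of the fitted values;
per-SNP outlier statistics are squared Mahalanobis distances `D²` of SNP
loadings on the leading `K = 2` axes, calibrated by a genomic inflation
factor and converted to Benjamini–Hochberg q-values (FDR 10%). Two further
scans run alongside: a latent-factor mixed model (LFMM; ridge estimation
with truncated-SVD latent factors, 2 factors) and a gradient-forest-style
scan (per-SNP regression forests; importance = out-of-bag R²; candidates =
top 5% intersected across runs), each raw and structure-corrected. Loci
flagged by ≥ 2 methods, LD-pruned within contigs at r² < 0.7, form the
*outlier set*; frequency-matched *random sets* serve as controls.

**Variance partitioning.** Full and partial RDA models decompose the
genetic variance into pure climate, pure population structure (ancestry
PCs), pure geography (dbMEM spatial eigenvectors) and a confounded
fraction, with permutation p-values.

**Genomic offset.** For RDA: populations' climate-predicted ordination
scores at reference vs. future climate; offset = eigenvalue-weighted
Euclidean distance over the first `K` axes. For GF: climates are mapped
through per-variable cumulative-importance (turnover) functions first.
Offsets are averaged over GCMs, min–max normalized, cut into five
equal-occupancy classes, and flagged non-robust where the two methods
disagree by ≥ 2 classes.

**GDI (genomic discrepancy index).** Min–max-normalized distance between a
population's *observed* ordination scores and its climate-*predicted*
scores — large values mark populations off the species-wide gene–climate
cline.

**Validation.** Common-garden traits are modeled as
`Y_ijk = μ + pop_i + geno_j(i) + ε_ijk` (REML, Gibbs option); population
BLUPs and an equal-weight composite trait index are correlated with
transplant offsets (origin climate vs. garden climate). Under a garden
harsher than most origins, offsets should correlate *negatively* with the
fitness proxies.

A synthetic-landscape generator (`simulate_landscape`) provides ground
truth for every stage: two admixing gene pools, Balding–Nichols drift,
logistic allele-frequency clines on a designated climate variable,
within-contig LD, missing calls, per-GCM future climates and common-garden
phenotypes.

## Worked example

```python
import yewoffset as yo

ds = yo.simulate_landscape(yo.LandscapeConfig(n_pops=29, n_snps=800, seed=17))
g = yo.filter_genotypes(ds.genotypes, 0.30, 0.30, 20)   # missingness + MAC
freqs = yo.population_allele_freqs(g)

res = yo.RDA(freqs.freqs, ds.reference_climate.values).fit()
print(res.summary())
```

```
Redundancy analysis (RDA)
  populations: 29   SNPs: 767
  predictors:  clim1, clim2, clim3, clim4, clim5, clim6
  constrained axes retained: 6
  R2 = 0.4203   adjusted R2 = 0.2622
  eigenvalues: 4.954, 0.5475, 0.4223, 0.375, 0.3652, 0.33
```

The six climate predictors explain ~42% of the among-population allele
frequency variance; the first constrained axis dominates, reflecting the
simulated cline. Candidate scans and offsets then hang off the same
objects:

```python
outliers = yo.rda_outliers(res, K=2, fdr=0.10)     # D2, q, candidate flags
fut = ds.future_climates()[0]
off = yo.rda_offset(res, ds.reference_climate, fut, K=2)
print(off.sort_values().tail(3).round(3))
```

```
P23    4.254
P14    4.381
P02    4.526
Name: offset, dtype: float64
```

Populations with the largest projected displacement along the fitted
gene–climate axes receive the largest offsets — the candidates for
climate maladaptation. The full orchestration (filtering → climate
selection → five GEA scans → consensus/random sets → offsets/GDI →
popgen statistics → BLUP validation) is one call:

```bash
yewoffset run --seed 17 --out run_dir
yewoffset report run_dir
```

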