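"""Synthetic landscapes with known adaptive architecture.

Emulates the structure of a range-wide conifer SNP dataset: two admixing
gene pools along an east-west gradient, drift-dominated neutral loci
(Balding-Nichols differentiation), a minority of adaptive loci whose
population allele frequencies follow logistic clines in a designated
climate variable, within-contig linkage, missing genotypes, per-GCM future
climates, and common-garden phenotypes that decline with the climate
distance between a population's origin and the garden.

Every downstream stage of the pipeline can therefore be scored against
ground truth. Defaults mirror the study conditions of a 29-population
range-wide sample with a handful of climate predictors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climsel import ClimateTable
from .genio import MISSING, GenotypeMatrix

#: default per-variable future climate displacement, in reference-period SD
#: units: warming-dominated shift with drier conditions, the signature of
#: the severe-forcing scenarios used for mid-century projections.
DEFAULT_FUTURE_SHIFT = (1.5, 0.5, 1.0, 1.5, -1.0, 0.5)


@dataclass
class LandscapeConfig:
    """Parameters of the synthetic landscape.

    Counts default to a desk-scale version of a range-wide study: 29
    populations, ~16 trees each, a few thousand SNPs of which 5% sit on
    climate clines, six candidate climate variables, five GCMs.
    ``cline_slope`` is in logit units per climate SD; ``drift_fst`` sets
    neutral differentiation between the two gene pools.
    """

    n_pops: int = 29
    n_ind_per_pop: int = 16
    n_snps: int = 2000
    frac_adaptive: float = 0.05
    n_climate_vars: int = 6
    cline_slope: float = 1.5
    drift_fst: float = 0.15
    admixture_gradient: bool = True
    missing_rate: float = 0.05
    contig_size: int = 10
    future_shift: tuple = DEFAULT_FUTURE_SHIFT
    n_gcms: int = 5
    n_driver_vars: int = 1
    polygenic: bool = False
    ld_rho: float = 0.5
    seed: int = 17

    def __post_init__(self) -> None:
        for name in ("n_pops", "n_ind_per_pop", "n_snps", "n_climate_vars",
                     "contig_size", "n_gcms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 <= self.frac_adaptive <= 1 and 0 <= self.missing_rate <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if not (0 < self.drift_fst < 1):
            raise ValueError("drift_fst must be in (0, 1)")
        shift = np.asarray(self.future_shift, float)
        if shift.size == 1:
            shift = np.repeat(shift, self.n_climate_vars)
        if shift.size < self.n_climate_vars:
            shift = np.resize(shift, self.n_climate_vars)
        self.future_shift = tuple(shift[: self.n_climate_vars])


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated landscape."""

    adaptive_loci: np.ndarray
    cline_intercepts: np.ndarray
    cline_slopes: np.ndarray
    driver_vars: np.ndarray
    ancestral_freqs: np.ndarray
    gene_pool_labels: np.ndarray  # per population: "west"/"east"/"admixed"
    admixture_weights: np.ndarray  # per population west-pool weight
    expected_freqs: pd.DataFrame  # pops x SNPs noise-free frequencies
    pool_freqs: pd.DataFrame | None = None  # gene-pool (west/east) x SNPs
    fitness_scale: float = 2.0

    def fitness_fn(self, climate_distance) -> np.ndarray:
        """Expected relative fitness, Gaussian-decreasing in climate distance."""
        d = np.asarray(climate_distance, float)
        return np.exp(-0.5 * (d / self.fitness_scale) ** 2)

    def to_json(self) -> str:
        return json.dumps(
            {
                "adaptive_loci": self.adaptive_loci.tolist(),
                "cline_intercepts": self.cline_intercepts.tolist(),
                "cline_slopes": self.cline_slopes.tolist(),
                "driver_vars": self.driver_vars.tolist(),
                "ancestral_freqs": self.ancestral_freqs.tolist(),
                "gene_pool_labels": self.gene_pool_labels.tolist(),
                "admixture_weights": self.admixture_weights.tolist(),
                "fitness_scale": self.fitness_scale,
            },
            indent=1,
        )


@dataclass
class SyntheticDataset:
    """Bundle returned by :func:`simulate_landscape`."""

    genotypes: GenotypeMatrix
    climates: dict  # key "" for reference, gcm label for future tables
    coords: pd.DataFrame
    truth: SyntheticTruth

    @property
    def reference_climate(self) -> ClimateTable:
        return self.climates[""]

    def future_climates(self) -> list[ClimateTable]:
        return [t for k, t in self.climates.items() if k]


def logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, float)))


def adaptive_cline_freq(env_value, intercept, slope):
    """Allele frequency on a logistic climate cline.

    logistic(intercept + slope * env_value); strictly inside (0, 1) and
    monotone in the environment whenever the slope is non-zero.
    """
    vals = [np.asarray(v, float) for v in (env_value, intercept, slope)]
    if any(not np.all(np.isfinite(v)) for v in vals):
        raise ValueError("cline inputs must be finite")
    f = logistic(vals[1] + vals[2] * vals[0])
    # keep strictly inside (0,1) even where the logistic saturates in floats
    return np.clip(f, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))


def _balding_nichols(rng, p_anc, fst, size):
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    return np.clip(rng.beta(a, b, size=size), 1e-4, 1 - 1e-4)


def simulate_landscape(config: LandscapeConfig) -> SyntheticDataset:
    """Simulate genotypes, climates, coordinates and ground truth.

    Neutral loci: ancestral frequency in (0.05, 0.95), two gene-pool
    frequencies by Balding-Nichols draws at ``drift_fst``, then mixed per
    population by its admixture weight with extra within-pool drift at
    ``drift_fst / 3``. Adaptive loci: logistic cline on one designated
    (standardized) climate variable. Genotypes are two Bernoulli draws per
    individual (Hardy-Weinberg within population). Future climates are the
    reference plus ``future_shift`` plus a per-GCM jitter of 5% of the
    shift. Fully reproducible from ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    pops = [f"P{i + 1:02d}" for i in range(cfg.n_pops)]
    var_names = [f"clim{v + 1}" for v in range(cfg.n_climate_vars)]

    # geography: east-west gradient in longitude
    lon = np.linspace(-10, 30, cfg.n_pops) + rng.normal(0, 1.0, cfg.n_pops)
    lat = rng.uniform(36, 60, cfg.n_pops)
    coords = pd.DataFrame({"lon": lon, "lat": lat}, index=pops)

    # admixture weight of the western pool declines eastward
    if cfg.admixture_gradient:
        w = 1.0 - (lon - lon.min()) / (lon.max() - lon.min())
    else:
        w = (np.arange(cfg.n_pops) < cfg.n_pops / 2).astype(float)
    labels = np.where(w > 0.75, "west", np.where(w < 0.25, "east", "admixed"))

    # climate: single spatial factor plus independent variation, so the
    # variables are correlated (|r| <= ~0.6) but not degenerate
    loadings = np.resize([0.7, 0.3, 0.45, 0.55, 0.25, 0.35], cfg.n_climate_vars)
    f_spatial = (lon - lon.mean()) / lon.std(ddof=1)
    clim = loadings * f_spatial[:, None] + np.sqrt(1 - loadings**2) * rng.normal(
        0, 1, (cfg.n_pops, cfg.n_climate_vars)
    )
    clim = (clim - clim.mean(axis=0)) / clim.std(axis=0, ddof=1)
    ref = ClimateTable(pd.DataFrame(clim, index=pops, columns=var_names), "reference", "")

    # adaptive architecture
    n_adapt = int(round(cfg.frac_adaptive * cfg.n_snps))
    if cfg.frac_adaptive > 0 and n_adapt < 1:
        warnings.warn("frac_adaptive * n_snps < 1: zero adaptive loci")
    adaptive = rng.choice(cfg.n_snps, size=n_adapt, replace=False)
    adaptive.sort()
    p_anc = rng.uniform(0.05, 0.95, cfg.n_snps)
    slope_mag = cfg.cline_slope / 3.0 if cfg.polygenic else cfg.cline_slope
    slopes = rng.choice([-1.0, 1.0], n_adapt) * slope_mag
    intercepts = np.log(p_anc[adaptive] / (1 - p_anc[adaptive]))
    drivers = rng.integers(0, max(cfg.n_driver_vars, 1), n_adapt)

    # population allele frequencies
    freqs = np.empty((cfg.n_pops, cfg.n_snps))
    pool_w = _balding_nichols(rng, p_anc, cfg.drift_fst, cfg.n_snps)
    pool_e = _balding_nichols(rng, p_anc, cfg.drift_fst, cfg.n_snps)
    base = w[:, None] * pool_w[None, :] + (1 - w[:, None]) * pool_e[None, :]
    fst_within = cfg.drift_fst / 3.0
    for i in range(cfg.n_pops):
        freqs[i] = _balding_nichols(rng, base[i], fst_within, cfg.n_snps)
    for a, j in enumerate(adaptive):
        env = clim[:, drivers[a]]
        freqs[:, j] = adaptive_cline_freq(env, intercepts[a], slopes[a])

    # genotypes: two Bernoulli allele draws per individual (HWE within
    # population); within-contig linkage from an AR(1) Gaussian copula over
    # loci, which keeps the Binomial(2, p) marginal at every locus
    n_ind = cfg.n_pops * cfg.n_ind_per_pop
    contig = np.arange(cfg.n_snps) // cfg.contig_size
    new_contig = np.r_[True, np.diff(contig) != 0]
    phi = cfg.ld_rho
    from scipy.stats import norm

    pop_of_row = np.repeat(np.arange(cfg.n_pops), cfg.n_ind_per_pop)
    thresh = norm.ppf(freqs)[pop_of_row]  # n_ind x n_snps
    alleles = np.zeros((n_ind, cfg.n_snps), dtype=np.int8)
    innov = np.sqrt(1 - phi**2)
    for _copy in range(2):
        eps = rng.normal(0, 1, (n_ind, cfg.n_snps))
        z = eps.copy()
        for j in range(1, cfg.n_snps):
            if not new_contig[j]:
                z[:, j] = phi * z[:, j - 1] + innov * eps[:, j]
        alleles += (z < thresh).astype(np.int8)
    calls = alleles
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = MISSING

    snp_meta = pd.DataFrame(
        {
            "id": [f"snp{j + 1}" for j in range(cfg.n_snps)],
            "contig": [f"contig{c + 1}" for c in contig],
            "pos": (np.arange(cfg.n_snps) % cfg.contig_size) * 100 + 1,
        }
    )
    ind_meta = pd.DataFrame(
        {
            "id": [f"{pops[i // cfg.n_ind_per_pop]}_i{i % cfg.n_ind_per_pop + 1}" for i in range(n_ind)],
            "population": [pops[i // cfg.n_ind_per_pop] for i in range(n_ind)],
        }
    )
    genotypes = GenotypeMatrix(calls, snp_meta, ind_meta)

    # future climates: mean shift modulated by latitude (stronger change at
    # high latitude, mimicking polar amplification, so displacement varies
    # across populations) plus small per-GCM jitter
    shift = np.asarray(cfg.future_shift, float)
    lat01 = (lat - lat.min()) / max(lat.max() - lat.min(), 1e-9)
    modulation = 0.6 + 0.8 * lat01  # population-specific factor in [0.6, 1.4]
    climates = {"": ref}
    jitter_sd = 0.05 * np.abs(shift)
    for g in range(cfg.n_gcms):
        fut = clim + modulation[:, None] * shift + rng.normal(0, 1, clim.shape) * jitter_sd
        label = f"GCM{g + 1}"
        climates[label] = ClimateTable(
            pd.DataFrame(fut, index=pops, columns=var_names), "future", label
        )

    truth = SyntheticTruth(
        adaptive_loci=adaptive,
        cline_intercepts=intercepts,
        cline_slopes=slopes,
        driver_vars=drivers,
        ancestral_freqs=p_anc,
        gene_pool_labels=labels,
        admixture_weights=w,
        expected_freqs=pd.DataFrame(freqs, index=pops, columns=snp_meta["id"]),
        pool_freqs=pd.DataFrame(
            np.vstack([pool_w, pool_e]), index=["west", "east"],
            columns=snp_meta["id"]),
    )
    return SyntheticDataset(genotypes, climates, coords, truth)


DEFAULT_TRAITS = ("growth", "shoot_elongation", "repro_phenology", "leaf_thickness")


def garden_climate_distance(
    truth: SyntheticTruth, reference: ClimateTable, climate_of_garden
) -> pd.Series:
    """Per-population distance between origin climate and garden climate.

    Only the designated driver variables enter the distance: they are the
    axes along which the simulated populations are adapted.
    """
    garden = np.asarray(climate_of_garden, float)
    drivers = np.unique(truth.driver_vars) if len(truth.driver_vars) else np.array([0])
    vals = reference.values.to_numpy(float)
    d = np.sqrt(((vals[:, drivers] - garden[drivers]) ** 2).sum(axis=1))
    return pd.Series(d, index=reference.populations)


def simulate_phenotypes(
    truth: SyntheticTruth,
    reference: ClimateTable,
    climate_of_garden,
    pops=None,
    n_clones: int = 5,
    n_ramets: int = 3,
    noise_sd: float = 0.5,
    traits=DEFAULT_TRAITS,
    seed: int = 17,
) -> pd.DataFrame:
    """Common-garden trait observations in long format.

    Each population's expected trait value decreases with the climate
    distance between its origin and the garden (through the Gaussian
    fitness function of the truth object). ``n_clones`` genotypes per
    population each contribute ``n_ramets`` observations; genotype effects
    (sd ``noise_sd/2``) and residuals (sd ``noise_sd``) are Gaussian.
    Traits share the same fitness signal with trait-specific scaling, so
    they are positively correlated but not identical.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    rng = np.random.default_rng(seed)
    if pops is None:
        pops = reference.populations
    dist = garden_climate_distance(truth, reference, climate_of_garden)
    fitness = truth.fitness_fn(dist.loc[list(pops)].to_numpy())

    rows = []
    for m, trait in enumerate(traits):
        scale = 1.0 + 0.25 * m
        base = 0.5 * m
        for i, pop in enumerate(pops):
            mu = base + scale * fitness[i]
            geno_fx = rng.normal(0, noise_sd / 2.0, n_clones)
            for c in range(n_clones):
                gid = f"{pop}_g{c + 1}"
                for r in range(n_ramets):
                    rows.append(
                        {
                            "individual": f"{gid}_r{r + 1}",
                            "genotype_id": gid,
                            "population": pop,
                            "trait": trait,
                            "year": 2009 + r,
                            "value": mu + geno_fx[c] + rng.normal(0, noise_sd),
                        }
                    )
    return pd.DataFrame(rows)


def write_fixtures(dataset: SyntheticDataset, outdir, phenotypes: pd.DataFrame | None = None) -> dict:
    """Write the dataset as plain-text fixtures (VCF v4.2 + TSV/CSV + JSON)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    g = dataset.genotypes
    if g.n_individuals == 0 or not g.populations:
        raise ValueError("empty population set")

    vcf_path = outdir / "genotypes.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for contig in pd.unique(g.snp_meta["contig"]):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.ind_meta["id"])
            + "\n"
        )
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(g.n_snps):
            meta = g.snp_meta.iloc[j]
            gts = "\t".join(gt_str[int(c)] for c in g.calls[:, j])
            fh.write(
                f"{meta['contig']}\t{meta['pos']}\t{meta['id']}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n"
            )

    popmap_path = outdir / "popmap.tsv"
    g.ind_meta[["id", "population"]].to_csv(popmap_path, sep="\t", header=False, index=False)

    climate_path = outdir / "climate.csv"
    pd.concat([t.to_long() for t in dataset.climates.values()]).to_csv(
        climate_path, index=False
    )

    coords_path = outdir / "coords.csv"
    dataset.coords.to_csv(coords_path, index_label="population")

    truth_path = outdir / "truth.json"
    truth_path.write_text(dataset.truth.to_json())

    paths = {
        "vcf": vcf_path,
        "popmap": popmap_path,
        "climate": climate_path,
        "coords": coords_path,
        "truth": truth_path,
    }
    if phenotypes is not None:
        pheno_path = outdir / "phenotypes.csv"
        phenotypes.to_csv(pheno_path, index=False)
        paths["phenotypes"] = pheno_path
    return paths


def read_climate_tables(path) -> dict:
    """Inverse of the long-format climate CSV written by :func:`write_fixtures`."""
    df = pd.read_csv(path, dtype={"gcm": str})
    df["gcm"] = df["gcm"].fillna("")
    tables = {}
    for (period, gcm), grp in df.groupby(["period", "gcm"], sort=False):
        wide = grp.pivot(index="population", columns="variable", values="value")
        wide = wide[sorted(wide.columns, key=lambda c: grp["variable"].tolist().index(c))]
        tables[gcm] = ClimateTable(wide, period, gcm)
    return tables
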