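"""End-to-end pipeline: data -> filtering -> climate selection -> GEA ->
offsets/GDI -> population genetics -> common-garden validation.

A single :class:`PipelineConfig` drives the run; every numeric default is
the standard threshold of the analysis protocol (30% missingness, MAC 20,
|r| > 0.75 correlation pruning, VIF < 10, FDR 10%, top 5% importance,
consensus of >= 2 methods, within-contig r2 < 0.7, K = 2 ordination axes,
5 offset classes, >= 3 plants per population). Outputs are CSV/JSON stage
artifacts plus a manifest with input hashes and the seed, so reruns with
the same config and seed are bit-identical for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import climsel, gea, genio, landscape, offsets, pheno, popgen
from .ordination import RDA, variance_partition

logger = logging.getLogger(__name__)

SNP_SETS = ("all", "outlier", "random", "random_2", "all_outlier")


@dataclass
class PipelineConfig:
    """Configuration of a full run; defaults follow the analysis protocol."""

    # data: either a synthetic landscape or explicit input paths
    synthetic: landscape.LandscapeConfig | None = None
    vcf: str | None = None
    popmap: str | None = None
    climate_csv: str | None = None
    coords_csv: str | None = None
    phenotypes_csv: str | None = None

    # filtering (analysis preset) and the structure preset used for PCA
    max_missing_snp: float = 0.30
    max_missing_ind: float = 0.30
    min_mac: int = 20
    structure_max_missing: float = 0.15
    structure_min_mac: int = 0

    # climate selection
    alpha: float = 0.05
    forward_n_perm: int = 999
    r_max: float = 0.75
    vif_max: float = 10.0

    # GEA
    fdr: float = 0.10
    top_frac: float = 0.05
    gf_n_runs: int = 5
    gf_n_trees: int = 50
    min_methods: int = 2
    r2_prune: float = 0.7
    K_latent: int = 2

    # offsets / GDI
    K: int = 2
    n_classes: int = 5
    gdi_snp_set: str = "random"

    # validation
    min_plants: int = 3
    garden_noise_sd: float = 0.5
    garden_shift: float = 2.0  # garden driver climate, in SD units beyond origin mean

    n_perm: int = 99  # variance-partition permutations
    seed: int = 17
    outdir: str = "yewoffset_run"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineResult:
    """Handle over the artifacts of a completed run."""

    outdir: Path
    manifest: dict
    freqs: genio.AlleleFreqMatrix
    selection: climsel.SelectionReport
    partition: object
    candidates: gea.CandidateReport
    offset_results: dict
    gdi: offsets.GDIResult
    validation: pd.DataFrame | None


def _load_inputs(cfg: PipelineConfig, outdir: Path):
    if cfg.synthetic is not None:
        ds = landscape.simulate_landscape(cfg.synthetic)
        return ds.genotypes, ds.climates, ds.coords, ds
    for name in ("vcf", "popmap", "climate_csv", "coords_csv"):
        p = getattr(cfg, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"required input {name!r} missing: {p}")
    g = genio.read_inputs(cfg.vcf, cfg.popmap)
    climates = landscape.read_climate_tables(cfg.climate_csv)
    coords = pd.read_csv(cfg.coords_csv, index_col="population")
    return g, climates, coords, None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    cfg = config
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    manifest: dict = {"seed": cfg.seed, "stages": [], "files": {}}

    def _save(df: pd.DataFrame, name: str, **kw):
        path = outdir / name
        df.to_csv(path, **kw)
        manifest["files"][name] = _sha256(path)

    def _stage(name):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        _stage("inputs")
        g_raw, climates, coords, ds = _load_inputs(cfg, outdir)
        ref_clim = climates[""]
        fut_clims = [t for k, t in climates.items() if k]

        _stage("structure")
        g_struct = genio.filter_genotypes(
            g_raw, cfg.structure_max_missing, cfg.structure_max_missing,
            cfg.structure_min_mac,
        )
        pc_scores, pc_var = popgen.genotype_pca(g_struct, n_components=2)
        pools = popgen.assign_gene_pools(pc_scores, K=2, seed=int(rng.integers(2**31)))
        struct_pcs = pc_scores.copy()
        struct_pcs["population"] = g_struct.ind_meta["population"].to_numpy()
        pop_pcs = struct_pcs.groupby("population", sort=False).mean()

        _stage("filter_impute")
        drop_report: list = []
        g_filt = genio.filter_genotypes(
            g_raw, cfg.max_missing_snp, cfg.max_missing_ind, cfg.min_mac,
            report=drop_report,
        )
        pool_of_ind = pools.reindex(g_filt.ind_meta["id"]).fillna(0).to_numpy()
        g_imp = genio.impute_modal_by_pool(g_filt, pool_of_ind)
        freqs = genio.population_allele_freqs(g_imp)
        _save(pd.DataFrame(drop_report, columns=["item", "rule"]), "dropped.tsv",
              sep="\t", index=False)
        _save(freqs.freqs, "allele_freqs.csv", index_label="population")

        pops = freqs.populations
        ref_clim = climsel.ClimateTable(
            ref_clim.values.loc[pops], ref_clim.period, ref_clim.gcm)
        fut_clims = [
            climsel.ClimateTable(t.values.loc[pops], t.period, t.gcm)
            for t in fut_clims
        ]
        coords = coords.loc[pops]
        pop_pcs = pop_pcs.loc[pops]

        _stage("climate_selection")
        fwd = climsel.forward_select(
            freqs.freqs, ref_clim, alpha=cfg.alpha, n_perm=cfg.forward_n_perm,
            seed=int(rng.integers(2**31)),
        )
        # keep forward-selected variables first, then survivors of the
        # correlation and VIF prunes over the full candidate table
        corr = climsel.prune_correlated(ref_clim, cfg.r_max, priority=fwd.kept)
        vif = climsel.prune_vif(ref_clim.subset(corr.kept), cfg.vif_max)
        selected = [v for v in ref_clim.variables if v in vif.kept]
        selection = climsel.SelectionReport(
            selected, fwd.dropped + corr.dropped + vif.dropped, fwd.pvalues, vif.vifs)
        (outdir / "climate_selection.json").write_text(
            json.dumps(selection.to_dict(), indent=1, default=str))
        clim_sel = ref_clim.subset(selected)
        fut_sel = [t.subset(selected) for t in fut_clims]

        _stage("geography")
        mems = climsel.dbmem(coords)

        _stage("variance_partition")
        part = variance_partition(
            freqs.freqs, clim_sel, pop_pcs, mems, n_perm=cfg.n_perm,
            seed=int(rng.integers(2**31)),
        )
        (outdir / "variance_partition.json").write_text(
            json.dumps(part.to_dict(), indent=1))

        _stage("gea")
        rda_res = RDA(freqs.freqs, clim_sel.values).fit()
        prda_res = RDA(freqs.freqs, clim_sel.values, condition=pop_pcs).fit()
        rda_tab = gea.rda_outliers(rda_res, K=cfg.K, fdr=cfg.fdr)
        prda_tab = gea.rda_outliers(prda_res, K=cfg.K, fdr=cfg.fdr)
        lfmm_res = gea.LFMM(freqs.freqs, clim_sel.values, K_latent=cfg.K_latent).fit()
        lfmm_cands = lfmm_res.candidates(cfg.fdr)
        gf_imp, gf_cands, gf_res = gea.gf_importance(
            freqs.freqs, clim_sel.values, n_trees=cfg.gf_n_trees,
            n_runs=cfg.gf_n_runs, top_frac=cfg.top_frac, correct=False,
            seed=int(rng.integers(2**31)),
        )
        _, gfc_cands, _ = gea.gf_importance(
            freqs.freqs, clim_sel.values, n_trees=cfg.gf_n_trees,
            n_runs=cfg.gf_n_runs, top_frac=cfg.top_frac, correct=True,
            K_latent=cfg.K_latent, seed=int(rng.integers(2**31)),
        )
        method_sets = {
            "rda": list(rda_tab.index[rda_tab["candidate"]]),
            "prda": list(prda_tab.index[prda_tab["candidate"]]),
            "lfmm": lfmm_cands,
            "gf_raw": gf_cands,
            "gf_corrected": gfc_cands,
        }
        consensus = gea.consensus_candidates(method_sets, cfg.min_methods)
        outlier_set = genio.ld_prune_within_contigs(g_imp, consensus, cfg.r2_prune)
        all_outlier = gea.consensus_candidates(method_sets, 1)
        maf = gea.snp_maf(freqs.freqs)
        rs_seed = int(rng.integers(2**31))
        random_set = gea.matched_random_set(
            freqs.snp_ids, maf, all_outlier, outlier_set, seed=rs_seed)
        random_set_2 = gea.matched_random_set(
            freqs.snp_ids, maf, all_outlier + random_set, outlier_set,
            seed=rs_seed + 1)
        stats_tab = pd.DataFrame(
            {"D2_rda": rda_tab["D2"], "q_rda": rda_tab["q"],
             "q_prda": prda_tab["q"], "q_lfmm": lfmm_res.snp_qvalues(),
             "gf_importance": gf_imp})
        candidates = gea.CandidateReport(
            method_sets, stats_tab, outlier_set, all_outlier, random_set,
            random_set_2)
        _save(candidates.to_table(), "candidates.tsv", sep="\t",
              index_label="snp")

        _stage("offsets")
        offset_results: dict = {}
        snp_sets = {
            "all": freqs.snp_ids, "outlier": outlier_set, "random": random_set,
            "random_2": random_set_2, "all_outlier": all_outlier,
        }
        models: dict = {}
        for set_name, ids in snp_sets.items():
            if len(ids) < 2:
                logger.warning("snp set %r too small; skipped", set_name)
                continue
            Ysub = freqs.freqs[ids]
            res = RDA(Ysub, clim_sel.values).fit()
            models[set_name] = res
            raw = pd.DataFrame(
                {t.gcm: offsets.rda_offset(res, clim_sel, t, K=min(cfg.K, res.K_retained))
                 for t in fut_sel})
            offset_results[("rda", set_name)] = offsets.aggregate_offsets(
                raw, "rda", set_name, cfg.n_classes)
            if set_name == "all" and gf_res is not None:
                turnover = gf_res.turnover_functions()
            else:
                turnover = gea.GradientForest(
                    Ysub, clim_sel.values, n_trees=cfg.gf_n_trees,
                    seed=int(rng.integers(2**31))).fit().turnover_functions()
            raw_gf = pd.DataFrame(
                {t.gcm: offsets.gf_offset(turnover, clim_sel, t) for t in fut_sel})
            offset_results[("gf", set_name)] = offsets.aggregate_offsets(
                raw_gf, "gf", set_name, cfg.n_classes)
        off_tab = pd.concat([r.to_frame() for r in offset_results.values()])
        robust = offsets.robustness_flags(
            offset_results[("rda", cfg.gdi_snp_set)],
            offset_results[("gf", cfg.gdi_snp_set)])
        off_tab["non_robust"] = off_tab.index.map(robust).astype("boolean")
        _save(off_tab, "offsets.csv", index_label="population")

        _stage("gdi")
        gdi_model = models.get(cfg.gdi_snp_set, models["all"])
        gdi = offsets.gdi_rda(gdi_model, K=min(cfg.K, gdi_model.K_retained))
        _save(gdi.to_frame(), "gdi.csv", index_label="population")

        _stage("popgen")
        stats = popgen.popgen_stats(g_struct, K=2, seed=int(rng.integers(2**31)))
        _save(stats.pop_fst.to_frame(), "pop_fst.csv", index_label="population")
        _save(stats.josts_d_pairwise, "josts_d.csv", index_label="population")

        _stage("validation")
        validation = None
        if ds is not None or cfg.phenotypes_csv is not None:
            if cfg.phenotypes_csv is not None:
                obs = pd.read_csv(cfg.phenotypes_csv)
                garden_clim_sel = None
            else:
                drivers = np.unique(ds.truth.driver_vars) if len(ds.truth.driver_vars) else [0]
                garden = np.zeros(len(ref_clim.variables))
                garden[drivers] = cfg.garden_shift
                obs = landscape.simulate_phenotypes(
                    ds.truth, ref_clim, garden, noise_sd=cfg.garden_noise_sd,
                    seed=int(rng.integers(2**31)))
                garden_clim_sel = pd.Series(garden, index=ref_clim.variables)[selected].to_numpy()
            blups = pheno.fit_trait_blups(obs, min_plants=cfg.min_plants)
            comp = pheno.composite_trait_index(blups)
            fitness = {t: b.blups for t, b in blups.items()}
            fitness["composite_index"] = comp
            if garden_clim_sel is not None:
                garden_offs = {
                    (m, s): offsets.garden_offset(
                        models[s], clim_sel, garden_clim_sel,
                        K=min(cfg.K, models[s].K_retained))
                    for (m, s) in offset_results if m == "rda" and s in models
                }
            else:
                garden_offs = {k: v.mean_raw for k, v in offset_results.items()}
            validation = pheno.validate_offsets(garden_offs, fitness)
            _save(validation, "validation.csv", index=False)
            blup_tab = pd.DataFrame({t: b.blups for t, b in blups.items()})
            blup_tab["composite_index"] = comp
            _save(blup_tab, "trait_blups.csv", index_label="population")

        manifest["config"] = json.loads(json.dumps(
            dataclasses.asdict(cfg), default=str))
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return PipelineResult(outdir, manifest, freqs, selection, part,
                              candidates, offset_results, gdi, validation)
    except Exception as err:
        manifest["error"] = {"stage": manifest["stages"][-1], "message": str(err)}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise


def report(run_dir) -> dict:
    """Summarize a completed (or partial) run directory."""
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    out: dict = {"stages": manifest["stages"], "partial": "error" in manifest}
    if "error" in manifest:
        out["error"] = manifest["error"]
    vp = run_dir / "variance_partition.json"
    if vp.exists():
        out["variance_partition"] = json.loads(vp.read_text())
    cand = run_dir / "candidates.tsv"
    if cand.exists():
        tab = pd.read_csv(cand, sep="\t", index_col="snp")
        flags = [c for c in tab.columns if c.startswith("is_") and c != "is_outlier_set"]
        counts = {c.removeprefix("is_"): int(tab[c].sum()) for c in flags}
        counts["union"] = int(tab[flags].any(axis=1).sum())
        counts["outlier_set"] = int(tab["is_outlier_set"].sum())
        out["candidate_counts"] = counts
    for name in ("offsets.csv", "gdi.csv", "validation.csv"):
        p = run_dir / name
        if p.exists():
            out[name.removesuffix(".csv")] = pd.read_csv(p).to_dict("records")
    return out
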