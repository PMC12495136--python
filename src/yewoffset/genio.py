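"""Genotype, climate and phenotype input handling.

Containers for diploid SNP genotype matrices and population allele-frequency
matrices, plus the standard pre-processing steps of a landscape-genomics
pipeline: missingness/MAC filtering, modal-genotype imputation within gene
pools, population allele frequencies, and within-contig LD pruning.

Genotypes are coded 0/1/2 as the count of the alternate allele; missing
calls use the sentinel ``MISSING`` (-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs diploid genotype calls with metadata.

    Parameters
    ----------
    calls : ndarray of int8, shape (n_individuals, n_snps)
        Alternate-allele counts in {0, 1, 2}; missing calls are ``MISSING``.
    snp_meta : DataFrame with columns ``id``, ``contig``, ``pos``
        One row per SNP, ``pos`` 1-based. SNP ids must be unique.
    ind_meta : DataFrame with columns ``id``, ``population``
        One row per individual; each individual belongs to one population.
    """

    calls: np.ndarray
    snp_meta: pd.DataFrame
    ind_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (individuals x SNPs)")
        n_ind, n_snp = self.calls.shape
        if len(self.ind_meta) != n_ind or len(self.snp_meta) != n_snp:
            raise ValueError("metadata shape does not match calls")
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype codes must be in {0,1,2,missing}")
        if self.snp_meta["id"].duplicated().any():
            raise ValueError("SNP ids must be unique")
        self.snp_meta = self.snp_meta.reset_index(drop=True)
        self.ind_meta = self.ind_meta.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    @property
    def n_snps(self) -> int:
        return self.calls.shape[1]

    @property
    def populations(self) -> list[str]:
        return list(pd.unique(self.ind_meta["population"]))

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls[:, index],
            self.snp_meta.iloc[index].reset_index(drop=True),
            self.ind_meta.copy(),
        )

    def take_individuals(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.calls[index],
            self.snp_meta.copy(),
            self.ind_meta.iloc[index].reset_index(drop=True),
        )


@dataclass
class AlleleFreqMatrix:
    """Populations x SNPs alternate-allele frequencies.

    ``freqs`` is a DataFrame indexed by population with one column per SNP
    id; ``n_obs`` holds the number of non-missing allele copies (2 x called
    genotypes) behind each frequency. Cells with ``n_obs == 0`` are NaN.
    """

    freqs: pd.DataFrame
    n_obs: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        vals = self.freqs.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0.0) & (vals <= 1.0))
        if not ok.all():
            raise ValueError("allele frequencies must lie in [0, 1]")
        if self.n_obs is None:
            self.n_obs = pd.DataFrame(
                np.full(self.freqs.shape, np.nan),
                index=self.freqs.index,
                columns=self.freqs.columns,
            )

    @property
    def populations(self) -> list[str]:
        return list(self.freqs.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.freqs.columns)

    def values(self) -> np.ndarray:
        return self.freqs.to_numpy(dtype=float)


def read_inputs(vcf_path, popmap_path) -> GenotypeMatrix:
    """Read a VCF and a two-column popmap TSV into a :class:`GenotypeMatrix`.

    Only biallelic SNP records are kept; multiallelic records are dropped
    and their count logged. Heterozygotes code 1 regardless of phasing.

    Raises
    ------
    ValueError
        If a VCF sample is absent from the popmap (the sample is named).
    """
    from cyvcf2 import VCF

    popmap = pd.read_csv(
        popmap_path, sep="\t", header=None, names=["id", "population"], dtype=str
    )
    pop_of = dict(zip(popmap["id"], popmap["population"]))

    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    for s in samples:
        if s not in pop_of:
            raise ValueError(f"sample {s!r} in VCF is missing from the popmap")

    rows, ids, contigs, poss = [], [], [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = var.gt_types
        codes = np.where(
            gt == 0, 0, np.where(gt == 1, 1, np.where(gt == 3, 2, MISSING))
        ).astype(np.int8)
        rows.append(codes)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        contigs.append(var.CHROM)
        poss.append(var.POS)
    vcf.close()
    if n_multi:
        logger.info("dropped %d multiallelic records", n_multi)
    if not rows:
        raise ValueError("no biallelic SNP records in VCF")

    calls = np.vstack(rows).T  # individuals x SNPs
    snp_meta = pd.DataFrame({"id": ids, "contig": contigs, "pos": poss})
    ind_meta = pd.DataFrame(
        {"id": samples, "population": [pop_of[s] for s in samples]}
    )
    return GenotypeMatrix(calls, snp_meta, ind_meta)


def filter_genotypes(
    g: GenotypeMatrix,
    max_missing_snp: float = 0.30,
    max_missing_ind: float = 0.30,
    min_mac: int = 20,
    report: list | None = None,
) -> GenotypeMatrix:
    """Missingness and minor-allele-count filtering.

    Order: SNPs by missingness, then individuals by missingness, then the
    MAC filter counted over the retained individuals' non-missing calls
    (the MAC of a SNP depends on which individuals survive). With ``min_mac``
    of 20 over 475 diploids the implied minor-allele-frequency threshold is
    20/950 = 2.105%.

    ``report``, if given, collects ``(snp_id_or_ind_id, rule)`` tuples for
    every dropped item.
    """
    if not (0 <= max_missing_snp <= 1 and 0 <= max_missing_ind <= 1):
        raise ValueError("missingness thresholds must be fractions in [0,1]")
    if min_mac < 0:
        raise ValueError("min_mac must be >= 0")

    miss = g.missing_mask()
    snp_miss = miss.mean(axis=0)
    keep_snp = snp_miss <= max_missing_snp
    if report is not None:
        for sid in g.snp_meta.loc[~keep_snp, "id"]:
            report.append((sid, "snp_missingness"))
    g = g.take_snps(np.flatnonzero(keep_snp))

    miss = g.missing_mask()
    ind_miss = miss.mean(axis=1) if g.n_snps else np.zeros(g.n_individuals)
    keep_ind = ind_miss <= max_missing_ind
    if report is not None:
        for iid in g.ind_meta.loc[~keep_ind, "id"]:
            report.append((iid, "individual_missingness"))
    g = g.take_individuals(np.flatnonzero(keep_ind))

    calls = g.calls
    obs = calls != MISSING
    alt = np.where(obs, calls, 0).sum(axis=0)
    total = 2 * obs.sum(axis=0)
    mac = np.minimum(alt, total - alt)
    keep_mac = mac >= min_mac
    if report is not None:
        for sid in g.snp_meta.loc[~keep_mac, "id"]:
            report.append((sid, "mac"))
    g = g.take_snps(np.flatnonzero(keep_mac))

    if g.n_snps == 0:
        raise ValueError("all SNPs removed by filtering")
    logger.info(
        "filter order snp_missingness -> ind_missingness -> mac; kept %d SNPs, %d individuals",
        g.n_snps,
        g.n_individuals,
    )
    return g


def impute_modal_by_pool(g: GenotypeMatrix, pool_labels) -> GenotypeMatrix:
    """Replace missing calls by the modal genotype within each gene pool.

    Ties break toward the lowest genotype code. A pool with no calls at a
    SNP falls back to the global mode; a SNP missing in everyone is an
    error (it should have been filtered).
    """
    pool_labels = np.asarray(pool_labels)
    if len(pool_labels) != g.n_individuals:
        raise ValueError("one pool label per individual required")

    calls = g.calls.copy()
    miss = calls == MISSING
    if not miss.any():
        return GenotypeMatrix(calls, g.snp_meta.copy(), g.ind_meta.copy())

    def _mode(column: np.ndarray) -> int:
        # lowest code wins ties; column holds non-missing codes only
        counts = np.bincount(column, minlength=3)
        return int(np.argmax(counts))

    for j in np.flatnonzero(miss.any(axis=0)):
        col = calls[:, j]
        obs_all = col[col != MISSING]
        if obs_all.size == 0:
            raise ValueError(
                f"SNP {g.snp_meta['id'].iloc[j]!r} missing in all individuals"
            )
        global_mode = _mode(obs_all)
        for pool in np.unique(pool_labels):
            in_pool = pool_labels == pool
            hole = in_pool & miss[:, j]
            if not hole.any():
                continue
            obs = col[in_pool & ~miss[:, j]]
            calls[hole, j] = _mode(obs) if obs.size else global_mode
    return GenotypeMatrix(calls, g.snp_meta.copy(), g.ind_meta.copy())


def population_allele_freqs(g: GenotypeMatrix) -> AlleleFreqMatrix:
    """Per-population alternate-allele frequencies with observed allele counts."""
    pops = g.populations
    freqs = np.empty((len(pops), g.n_snps))
    n_obs = np.empty_like(freqs)
    for i, pop in enumerate(pops):
        sel = (g.ind_meta["population"] == pop).to_numpy()
        if not sel.any():
            raise ValueError(f"population {pop!r} has no individuals")
        sub = g.calls[sel]
        obs = sub != MISSING
        alt = np.where(obs, sub, 0).sum(axis=0)
        tot = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[i] = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        n_obs[i] = tot
    snp_ids = list(g.snp_meta["id"])
    return AlleleFreqMatrix(
        pd.DataFrame(freqs, index=pops, columns=snp_ids),
        pd.DataFrame(n_obs, index=pops, columns=snp_ids),
    )


def genotype_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of 0/1/2 codes over pairwise-complete calls.

    Composite LD on unphased diploids; returns 0.0 when either SNP is
    constant over the shared calls.
    """
    ok = (a != MISSING) & (b != MISSING)
    if ok.sum() < 2:
        return 0.0
    x, y = a[ok].astype(float), b[ok].astype(float)
    if x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_prune_within_contigs(
    g: GenotypeMatrix, snp_subset=None, r2_max: float = 0.7
) -> list[str]:
    """Greedy positional LD pruning within contigs.

    Scanning each contig left to right by position, a SNP is dropped when
    its genotype-code r-squared with any already-kept SNP on the same
    contig reaches ``r2_max``. SNPs on different contigs are never
    compared. Returns the kept SNP ids in scan order.
    """
    if not (0 < r2_max <= 1):
        raise ValueError("r2_max must be in (0, 1]")
    ids = list(g.snp_meta["id"])
    col_of = {sid: j for j, sid in enumerate(ids)}
    if snp_subset is None:
        snp_subset = ids
    for sid in snp_subset:
        if sid not in col_of:
            raise ValueError(f"SNP id {sid!r} not in genotype matrix")
    sub = g.snp_meta.set_index("id").loc[list(snp_subset)]
    kept: list[str] = []
    for contig, block in sub.groupby("contig", sort=False):
        block = block.sort_values("pos", kind="stable")
        kept_cols: list[int] = []
        for sid in block.index:
            j = col_of[sid]
            if all(
                genotype_r2(g.calls[:, j], g.calls[:, k]) < r2_max for k in kept_cols
            ):
                kept.append(sid)
                kept_cols.append(j)
    return kept


def write_freqs_csv(freqs: AlleleFreqMatrix, path) -> None:
    freqs.freqs.to_csv(path, index_label="population")


def read_climate_csv(path) -> pd.DataFrame:
    """Long-format climate CSV (population, variable, value, period, gcm)."""
    df = pd.read_csv(path, dtype={"gcm": str})
    df["gcm"] = df["gcm"].fillna("")
    return df
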