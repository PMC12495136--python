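"""Genotype-environment association (GEA) scans and candidate SNP sets.

Five detection routes over population allele frequencies:

* RDA / pRDA — Mahalanobis outliers in constrained-ordination loading space,
  calibrated by a genomic inflation factor, FDR-controlled (BH).
* LFMM — per-locus climate regression with truncated-SVD latent factors
  absorbing unobserved structure, one-shot ridge estimation.
* Gradient-forest (raw and structure-corrected) — per-locus regression
  forests whose out-of-bag R2 measures nonlinear climate association;
  candidates are top-fraction sets intersected across independent runs.

Plus consensus candidates (loci flagged by at least ``min_methods``
methods) and allele-frequency-matched random control sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ordination import RDAResults, _as_matrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# RDA Mahalanobis outliers


def genomic_inflation_factor(stat: np.ndarray, df: int) -> float:
    """Median-based genomic inflation factor of chi-square statistics."""
    return float(np.median(stat) / stats.chi2.ppf(0.5, df))


def rda_outliers(results: RDAResults, K: int = 2, fdr: float = 0.10) -> pd.DataFrame:
    """Mahalanobis outliers of SNP loadings on the first K constrained axes.

    Loadings are the projections of *per-locus standardized* (unit-variance)
    centered SNP columns onto the axes; without this standardization the
    loading cloud is a scale mixture across loci of unequal variance and its
    tails run far heavier than chi-square, which destroys FDR calibration.
    Each SNP's squared Mahalanobis distance from the cloud is rescaled by
    the genomic inflation factor (median D2 over the chi2_K median),
    converted to an upper-tail chi2_K p-value and BH-adjusted; candidates
    satisfy q <= ``fdr``. The distance itself is invariant to per-axis
    rescaling, so the axis-score convention is immaterial here.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > results.K_retained:
        raise ValueError(f"K={K} exceeds {results.K_retained} retained axes")
    if not (0 < fdr < 1):
        raise ValueError("fdr must be in (0, 1)")
    Yc = results.model.Y - results.y_mean
    sd = Yc.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    L = (Yc / sd).T @ results.site_scores[:, :K]
    # robust center/scatter: the classical covariance is stretched by the very
    # outliers being sought (masking), killing power at a few percent of
    # adaptive loci
    from sklearn.covariance import MinCovDet

    mcd = MinCovDet(random_state=0).fit(L)
    mu, cov = mcd.location_, np.atleast_2d(mcd.covariance_)
    d2 = np.einsum("ij,jk,ik->i", L - mu, np.linalg.inv(cov), L - mu)
    gif = genomic_inflation_factor(d2, K)
    p = stats.chi2.sf(d2 / gif, K)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"snp": results.model.snp_ids, "D2": d2, "gif": gif, "p": p, "q": q,
         "candidate": q <= fdr}
    ).set_index("snp")


# ---------------------------------------------------------------------------
# Latent factor mixed model (ridge / truncated-SVD variant)


class LFMM:
    """Latent-factor climate regression on allele frequencies.

    One-shot estimation: ridge-regress Y on climate, take the leading
    ``K_latent`` left singular vectors of the residual as latent factors,
    then refit every SNP by OLS on [climate, factors]. With ``K_latent=0``
    this reduces exactly to per-SNP OLS t-tests.
    """

    def __init__(self, Y, X, K_latent: int = 2, ridge: float = 1e-6):
        self.Y, self.pop_names, self.snp_ids = _as_matrix(Y)
        self.X, _, self.var_names = _as_matrix(X)
        n = self.Y.shape[0]
        if K_latent < 0:
            raise ValueError("K_latent must be >= 0")
        if K_latent >= min(n, self.Y.shape[1]):
            raise ValueError("K_latent must be smaller than both Y dimensions")
        self.K_latent = K_latent
        self.ridge = ridge

    def fit(self) -> "LFMMResults":
        n = self.Y.shape[0]
        Yc = self.Y - self.Y.mean(axis=0)
        sd = self.X.std(axis=0, ddof=1)
        Z = (self.X - self.X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

        if self.K_latent > 0:
            A = Z.T @ Z + self.ridge * np.eye(Z.shape[1])
            B1 = np.linalg.solve(A, Z.T @ Yc)
            R = Yc - Z @ B1
            U, s, _ = np.linalg.svd(R, full_matrices=False)
            factors = U[:, : self.K_latent] * s[: self.K_latent]
        else:
            factors = np.empty((n, 0))

        D = np.column_stack([np.ones(n), Z, factors])
        coef, *_ = np.linalg.lstsq(D, Yc, rcond=None)
        resid = Yc - D @ coef
        dof = n - D.shape[1]
        if dof < 1:
            raise ValueError("not enough populations for the requested model")
        sigma2 = (resid**2).sum(axis=0) / dof
        XtX_inv = np.linalg.pinv(D.T @ D)
        p_clim = Z.shape[1]
        se = np.sqrt(np.outer(np.diag(XtX_inv)[1 : 1 + p_clim], sigma2))
        eff = coef[1 : 1 + p_clim]
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(se > 0, eff / se, 0.0)
        return LFMMResults(self, eff, tstat, factors, dof)


@dataclass
class LFMMResults:
    model: LFMM
    effects: np.ndarray  # climate vars x SNPs
    tstats: np.ndarray
    factors: np.ndarray  # populations x K_latent
    dof: int
    _cache: dict = field(default_factory=dict)

    def calibrated_pvalues(self) -> pd.DataFrame:
        """Per-variable GIF-recalibrated p-values.

        t statistics are first mapped through their Student null to normal
        z-scores (at the small residual dof of population-level fits, t^2
        tails are far heavier than chi2_1, which would wreck calibration),
        then z^2 is rescaled by the median-based genomic inflation factor
        and referred to chi2_1.
        """
        if "p" in self._cache:
            return self._cache["p"]
        p_t = 2.0 * stats.t.sf(np.abs(self.tstats), self.dof)
        z2 = stats.norm.isf(np.clip(p_t / 2.0, 1e-300, 1.0)) ** 2
        rows = {}
        for v, name in enumerate(self.model.var_names):
            gif = genomic_inflation_factor(z2[v], 1)
            rows[name] = stats.chi2.sf(z2[v] / max(gif, 1e-12), 1)
        out = pd.DataFrame(rows, index=self.model.snp_ids)
        self._cache["p"] = out
        return out

    def qvalues(self) -> pd.DataFrame:
        """Per-variable BH q-values (one family per climate variable)."""
        p = self.calibrated_pvalues()
        return p.apply(lambda col: multipletests(col, method="fdr_bh")[1], axis=0)

    def snp_qvalues(self) -> pd.Series:
        """One q-value per SNP: Bonferroni across climate variables on the
        calibrated p-values, then a single BH family across SNPs.

        Unioning per-variable BH calls would multiply the false-discovery
        rate by the number of variables; collapsing to one test per SNP
        keeps the SNP-level FDR at its nominal level.
        """
        p = self.calibrated_pvalues()
        p_snp = np.minimum(p.min(axis=1) * p.shape[1], 1.0)
        return pd.Series(multipletests(p_snp, method="fdr_bh")[1],
                         index=p.index, name="q")

    def candidates(self, fdr: float = 0.10) -> list[str]:
        """SNPs whose SNP-level q-value reaches the FDR level."""
        q = self.snp_qvalues()
        return list(q.index[q <= fdr])

    def corrected_frequencies(self) -> np.ndarray:
        """Y with the latent-factor contribution removed (structure-corrected)."""
        Yc = self.model.Y - self.model.Y.mean(axis=0)
        if self.factors.shape[1] == 0:
            return Yc
        gamma, *_ = np.linalg.lstsq(self.factors, Yc, rcond=None)
        return Yc - self.factors @ gamma

    def summary(self) -> str:
        n_cand = len(self.candidates(0.10))
        return (
            f"LFMM (ridge, truncated-SVD factors)\n"
            f"  SNPs: {len(self.model.snp_ids)}   populations: {len(self.model.pop_names)}\n"
            f"  latent factors: {self.model.K_latent}   residual dof: {self.dof}\n"
            f"  candidates at q<=0.10: {n_cand}"
        )


# ---------------------------------------------------------------------------
# Gradient-forest-lite


@dataclass
class TurnoverFunction:
    """Monotone step function of cumulative split importance along a gradient.

    Evaluation is clamped to the training range: 0 below the smallest
    threshold, the total importance above the largest.
    """

    thresholds: np.ndarray
    cum_importance: np.ndarray

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        if self.thresholds.size == 0:
            return np.zeros_like(x)
        idx = np.searchsorted(self.thresholds, x, side="right")
        padded = np.concatenate([[0.0], self.cum_importance])
        return padded[idx]

    @property
    def total(self) -> float:
        return float(self.cum_importance[-1]) if self.cum_importance.size else 0.0


def _tree_split_importances(tree):
    """(variables, thresholds, impurity-decrease weights) arrays of one tree."""
    t = tree.tree_
    internal = t.children_left != -1
    if not internal.any():
        return None
    wn = t.weighted_n_node_samples
    imp = (
        wn[internal] * t.impurity[internal]
        - wn[t.children_left[internal]] * t.impurity[t.children_left[internal]]
        - wn[t.children_right[internal]] * t.impurity[t.children_right[internal]]
    ) / wn[0]
    return t.feature[internal], t.threshold[internal], np.maximum(imp, 0.0)


class GradientForest:
    """Per-SNP regression forests of allele frequency on climate.

    A forest is fitted for every SNP; its out-of-bag R2 (truncated at 0)
    is the SNP's climate importance, and in-forest split-impurity
    decreases, scaled to the SNP's OOB R2, accumulate into per-variable
    cumulative-importance (turnover) functions.
    """

    def __init__(self, Y, X, n_trees: int = 50, seed: int = 0,
                 collect_splits: bool = True):
        self.Y, self.pop_names, self.snp_ids = _as_matrix(Y)
        self.Xdf = pd.DataFrame(_as_matrix(X)[0], columns=_as_matrix(X)[2])
        self.n_trees = n_trees
        self.seed = seed
        self.collect_splits = collect_splits

    def fit(self) -> "GradientForestResults":
        from sklearn.tree import DecisionTreeRegressor

        X = np.ascontiguousarray(self.Xdf.to_numpy(float))
        X32 = X.astype(np.float32)
        n, n_vars = X.shape
        n_snps = self.Y.shape[1]
        importance = np.zeros(n_snps)
        splits: dict[int, list] = {v: [] for v in range(n_vars)}
        rng = np.random.default_rng(self.seed)
        max_feat = max(1, n_vars // 3)
        for j in range(n_snps):
            y = np.ascontiguousarray(self.Y[:, j])
            if np.ptp(y) == 0:
                continue  # constant SNP: importance 0, never a candidate
            # bagged trees with out-of-bag prediction
            oob_sum = np.zeros(n)
            oob_cnt = np.zeros(n)
            raw: list[tuple] = []
            for _ in range(self.n_trees):
                idx = rng.integers(0, n, n)
                tree = DecisionTreeRegressor(
                    max_features=max_feat,
                    min_samples_leaf=2,
                    random_state=int(rng.integers(2**31)),
                )
                tree.fit(X[idx], y[idx], check_input=False)
                oob = np.ones(n, bool)
                oob[idx] = False
                if oob.any():
                    pred_all = tree.tree_.predict(X32).ravel()
                    oob_sum[oob] += pred_all[oob]
                    oob_cnt[oob] += 1
                if self.collect_splits:
                    triple = _tree_split_importances(tree)
                    if triple is not None:
                        raw.append(triple)
            seen = oob_cnt > 0
            if seen.sum() < 2 or np.ptp(y[seen]) == 0:
                continue
            pred = oob_sum[seen] / oob_cnt[seen]
            ss_res = float(((y[seen] - pred) ** 2).sum())
            ss_tot = float(((y[seen] - y[seen].mean()) ** 2).sum())
            r2 = max(1.0 - ss_res / ss_tot, 0.0)
            importance[j] = r2
            if r2 == 0 or not raw:
                continue
            feats = np.concatenate([r[0] for r in raw])
            thrs = np.concatenate([r[1] for r in raw])
            ws = np.concatenate([r[2] for r in raw])
            tot = ws.sum()
            if tot <= 0:
                continue
            # split weights re-expressed so a SNP contributes its OOB R2 in total
            ws = ws * (r2 / tot)
            for v in range(n_vars):
                sel = feats == v
                if sel.any():
                    splits[v].append((thrs[sel], ws[sel]))
        return GradientForestResults(self, importance, splits)


@dataclass
class GradientForestResults:
    model: GradientForest
    importance_: np.ndarray
    _splits: dict

    @property
    def importance(self) -> pd.Series:
        return pd.Series(self.importance_, index=self.model.snp_ids, name="importance")

    def top_candidates(self, top_frac: float = 0.05) -> list[str]:
        imp = self.importance
        n_top = max(1, int(round(top_frac * len(imp))))
        ranked = imp.sort_values(ascending=False, kind="stable")
        top = ranked.iloc[:n_top]
        return list(top.index[top > 0])

    def turnover_functions(self) -> dict[str, TurnoverFunction]:
        out = {}
        for v, name in enumerate(self.model.Xdf.columns):
            pairs = self._splits.get(v, [])
            if not pairs:
                out[name] = TurnoverFunction(np.array([]), np.array([]))
                continue
            thr = np.concatenate([p[0] for p in pairs])
            w = np.concatenate([p[1] for p in pairs])
            order = np.argsort(thr, kind="stable")
            out[name] = TurnoverFunction(thr[order], np.cumsum(w[order]))
        return out

    def summary(self) -> str:
        return (
            f"Gradient-forest-lite\n"
            f"  SNPs: {len(self.model.snp_ids)}   trees per SNP: {self.model.n_trees}\n"
            f"  mean importance (OOB R2): {self.importance_.mean():.4f}"
        )


def gf_importance(
    Y,
    X,
    n_trees: int = 50,
    n_runs: int = 5,
    top_frac: float = 0.05,
    correct: bool = False,
    K_latent: int = 2,
    seed: int = 0,
) -> tuple[pd.Series, list[str], GradientForestResults]:
    """Gradient-forest candidate detection across independently seeded runs.

    Candidates are the intersection of the top-``top_frac`` importance sets
    over ``n_runs`` runs. With ``correct=True`` the frequencies are first
    residualized on LFMM latent factors (structure-corrected variant).
    Returns (mean importance, candidate ids, last run's results).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    Ymat, pops, snp_ids = _as_matrix(Y)
    if correct:
        lf = LFMM(Ymat, X, K_latent=K_latent).fit()
        Ymat = lf.corrected_frequencies()
    Ydf = pd.DataFrame(Ymat, index=pops, columns=snp_ids)
    rng = np.random.default_rng(seed)
    imps, cand_sets, res = [], [], None
    for i in range(n_runs):
        res = GradientForest(Ydf, X, n_trees=n_trees, seed=int(rng.integers(2**31)),
                             collect_splits=(i == n_runs - 1)).fit()
        imps.append(res.importance)
        cand_sets.append(set(res.top_candidates(top_frac)))
    mean_imp = pd.concat(imps, axis=1).mean(axis=1)
    cands = set.intersection(*cand_sets) if cand_sets else set()
    ordered = [s for s in snp_ids if s in cands]
    return mean_imp, ordered, res


# ---------------------------------------------------------------------------
# Consensus and matched random sets


def consensus_candidates(per_method_sets: dict, min_methods: int = 2) -> list[str]:
    """SNPs flagged by at least ``min_methods`` of the per-method sets."""
    if len(per_method_sets) < 2:
        raise ValueError("need at least two method sets")
    counts: dict[str, int] = {}
    order: list[str] = []
    for s in per_method_sets.values():
        for sid in s:
            if sid not in counts:
                counts[sid] = 0
                order.append(sid)
            counts[sid] += 1
    return [sid for sid in order if counts[sid] >= min_methods]


def matched_random_set(
    all_snps,
    maf: pd.Series,
    exclude,
    target: list[str],
    n_bins: int = 10,
    seed: int = 0,
) -> list[str]:
    """Frequency-matched random control set.

    Bins the target (outlier) SNPs by minor-allele frequency into
    ``n_bins`` equal-width bins over [0, 0.5] and samples, without
    replacement, the same number of non-candidate SNPs per bin. When a bin
    runs short, the nearest-MAF non-candidates fill in (logged).
    """
    rng = np.random.default_rng(seed)
    if not target:
        return []
    pool = [s for s in all_snps if s not in set(exclude)]
    if len(pool) < len(target):
        raise ValueError("not enough non-candidate SNPs to match the target set")
    edges = np.linspace(0, 0.5, n_bins + 1)
    pool_maf = maf.loc[pool].to_numpy()
    tgt_maf = maf.loc[list(target)].to_numpy()
    pool_bin = np.clip(np.digitize(pool_maf, edges) - 1, 0, n_bins - 1)
    tgt_bin = np.clip(np.digitize(tgt_maf, edges) - 1, 0, n_bins - 1)
    chosen: list[str] = []
    available = {b: [pool[i] for i in np.flatnonzero(pool_bin == b)] for b in range(n_bins)}
    shortfall: list[tuple[int, int]] = []
    for b in range(n_bins):
        need = int((tgt_bin == b).sum())
        if need == 0:
            continue
        have = available[b]
        take = min(need, len(have))
        if take:
            chosen.extend(rng.choice(have, size=take, replace=False).tolist())
        if take < need:
            shortfall.append((b, need - take))
    if shortfall:
        logger.info("widening MAF bins for %s", shortfall)
        remaining = [s for s in pool if s not in set(chosen)]
        for b, deficit in shortfall:
            center = (edges[b] + edges[b + 1]) / 2
            remaining.sort(key=lambda s: abs(maf.loc[s] - center))
            if len(remaining) < deficit:
                raise ValueError("cannot frequency-match the random set")
            chosen.extend(remaining[:deficit])
            remaining = remaining[deficit:]
    return chosen


def snp_maf(freqs) -> pd.Series:
    """Mean-across-populations minor-allele frequency per SNP."""
    vals, pops, snp_ids = _as_matrix(freqs)
    mean_p = np.nanmean(vals, axis=0)
    return pd.Series(np.minimum(mean_p, 1 - mean_p), index=snp_ids, name="maf")


@dataclass
class CandidateReport:
    """Per-method candidates plus consensus and matched control sets."""

    method_sets: dict[str, list[str]]
    stats: pd.DataFrame  # per-SNP D2/p/q/importance columns where available
    outlier_set: list[str] = field(default_factory=list)
    all_outlier: list[str] = field(default_factory=list)
    random_set: list[str] = field(default_factory=list)
    random_set_2: list[str] = field(default_factory=list)

    def counts(self) -> pd.Series:
        c = {m: len(s) for m, s in self.method_sets.items()}
        c.update(
            outlier_set=len(self.outlier_set),
            all_outlier=len(self.all_outlier),
            random_set=len(self.random_set),
            random_set_2=len(self.random_set_2),
        )
        return pd.Series(c, name="n_candidates")

    def to_table(self) -> pd.DataFrame:
        t = self.stats.copy()
        for m, s in self.method_sets.items():
            t[f"is_{m}"] = t.index.isin(s)
        t["is_outlier_set"] = t.index.isin(self.outlier_set)
        return t
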