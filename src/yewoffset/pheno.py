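"""Common-garden trait BLUPs, the composite trait index, and offset validation.

Traits measured on clonally replicated material in a common garden are
modeled as  Y_ijk = mu + pop_i + geno_j(i) + eps_ijk  with Gaussian random
intercepts for population and for genotype nested in population. The
population intercept predictions (BLUPs) are the fitness proxies that
genomic offsets are validated against: under a garden climate harsher than
most origins, offsets are expected to correlate *negatively* with fitness
proxies.

Estimation is REML by default (via statsmodels' linear mixed models); a
Gibbs sampler with weakly informative inverse-gamma priors is available as
an option, whose posterior means of pop_i converge to the REML BLUPs for
these weak priors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class TraitBLUPs:
    """Population intercept predictions for one trait."""

    trait: str
    blups: pd.Series  # per-population intercept prediction
    se: pd.Series
    var_pop: float
    var_geno: float
    var_resid: float
    n_plants: pd.Series
    mu: float = 0.0

    def summary(self) -> str:
        return (
            f"Trait {self.trait!r}: {len(self.blups)} populations\n"
            f"  variance components: pop {self.var_pop:.4g}, "
            f"geno {self.var_geno:.4g}, residual {self.var_resid:.4g}\n"
            f"  BLUP range: {self.blups.min():.3f} to {self.blups.max():.3f}"
        )


class TraitModel:
    """Mixed model for one common-garden trait.

    Parameters
    ----------
    obs : long-format DataFrame with columns ``individual``, ``genotype_id``,
        ``population``, ``trait``, ``value`` (and optionally covariates).
        Repeated measures per individual (e.g. years) are averaged first.
    trait : trait name to model
    covariates : fixed-effect covariate column names (e.g. stem length for
        growth, to absorb age differences)
    min_plants : smallest number of measured plants for a population to be
        retained (default 3)
    """

    def __init__(self, obs: pd.DataFrame, trait: str, covariates=(), min_plants: int = 3):
        df = obs[obs["trait"] == trait].copy()
        if df.empty:
            raise ValueError(f"no observations for trait {trait!r}")
        keys = ["individual", "genotype_id", "population"]
        agg = {c: "mean" for c in ["value", *covariates]}
        df = df.groupby(keys, as_index=False, sort=False).agg(agg)
        counts = df.groupby("population", sort=False)["individual"].nunique()
        keep = counts[counts >= min_plants].index
        dropped = sorted(set(counts.index) - set(keep))
        if dropped:
            logger.info("dropping populations with <%d plants: %s", min_plants, dropped)
        df = df[df["population"].isin(keep)]
        if df["population"].nunique() < 2:
            raise ValueError("need at least 2 populations after the min-plants filter")
        self.data = df.reset_index(drop=True)
        self.trait = trait
        self.covariates = list(covariates)
        self.n_plants = df.groupby("population", sort=False)["individual"].nunique()

    def _design(self):
        y = self.data["value"].to_numpy(float)
        X = np.ones((len(y), 1))
        if self.covariates:
            C = self.data[self.covariates].to_numpy(float)
            X = np.column_stack([X, C - C.mean(axis=0)])
        return y, X

    def fit(self, method: str = "reml", **kwargs) -> TraitBLUPs:
        if method == "reml":
            return self._fit_reml()
        if method == "gibbs":
            return self._fit_gibbs(**kwargs)
        raise ValueError("method must be 'reml' or 'gibbs'")

    def _fit_reml(self) -> TraitBLUPs:
        import statsmodels.formula.api as smf

        df = self.data.copy()
        fixed = "value ~ 1" + "".join(
            f" + center({c})" for c in self.covariates
        )
        vc = {"geno": "0 + C(genotype_id)"}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                md = smf.mixedlm(fixed, df, groups=df["population"], re_formula="1",
                                 vc_formula=vc)
                fit = md.fit(reml=True, method="lbfgs")
                # vcomp is on the response scale in statsmodels results
                var_geno = float(fit.vcomp[0])
            except Exception:
                fit = None
            if fit is None or not np.isfinite(fit.llf):
                logger.warning("full model failed; refitting without genotype term")
                md = smf.mixedlm(fixed, df, groups=df["population"], re_formula="1")
                fit = md.fit(reml=True, method="lbfgs")
                var_geno = 0.0
        var_pop = float(fit.cov_re.iloc[0, 0])
        var_resid = float(fit.scale)
        re = fit.random_effects
        pops = list(self.n_plants.index)
        blups = pd.Series({p: float(re[p].iloc[0]) for p in pops}, name=self.trait)
        se_map = {}
        for p in pops:
            try:
                cond_var = fit.random_effects_cov[p]["Group"]
                se_map[p] = float(np.sqrt(np.atleast_2d(cond_var)[0, 0]))
            except Exception:
                se_map[p] = np.nan
        return TraitBLUPs(
            self.trait, blups.loc[pops], pd.Series(se_map).loc[pops],
            var_pop, var_geno, var_resid, self.n_plants,
            mu=float(fit.fe_params.iloc[0]),
        )

    def _fit_gibbs(self, n_iter: int = 4000, burn: int = 1000, thin: int = 5,
                   seed: int = 0) -> TraitBLUPs:
        """Gibbs sampler with weak inverse-gamma priors on all variances.

        Conjugate normal-inverse-gamma updates for (mu, covariate betas),
        population effects, genotype effects and the three variances; the
        returned BLUPs are posterior means of pop_i.
        """
        rng = np.random.default_rng(seed)
        y, X = self._design()
        pops = pd.Categorical(self.data["population"])
        genos = pd.Categorical(self.data["genotype_id"])
        ip, ig = pops.codes, genos.codes
        n_pop, n_geno = len(pops.categories), len(genos.categories)
        n = len(y)

        beta = np.zeros(X.shape[1])
        u = np.zeros(n_pop)
        v = np.zeros(n_geno)
        s2_pop = s2_geno = s2_res = float(np.var(y)) or 1.0
        a0, b0 = 0.001, 0.001  # weak inverse-gamma

        keep_u = []
        keep_s2 = []
        XtX = X.T @ X
        for it in range(n_iter):
            # fixed effects
            resid = y - u[ip] - v[ig]
            prec = XtX / s2_res + 1e-8 * np.eye(X.shape[1])
            mean = np.linalg.solve(prec, X.T @ resid / s2_res)
            beta = rng.multivariate_normal(mean, np.linalg.inv(prec))
            xb = X @ beta
            # population effects
            r = y - xb - v[ig]
            for p in range(n_pop):
                sel = ip == p
                nn = sel.sum()
                var = 1.0 / (nn / s2_res + 1.0 / s2_pop)
                u[p] = rng.normal(var * r[sel].sum() / s2_res, np.sqrt(var))
            # genotype effects
            r = y - xb - u[ip]
            for gidx in range(n_geno):
                sel = ig == gidx
                nn = sel.sum()
                var = 1.0 / (nn / s2_res + 1.0 / s2_geno)
                v[gidx] = rng.normal(var * r[sel].sum() / s2_res, np.sqrt(var))
            # variances
            s2_pop = 1.0 / rng.gamma(a0 + n_pop / 2, 1.0 / (b0 + (u**2).sum() / 2))
            s2_geno = 1.0 / rng.gamma(a0 + n_geno / 2, 1.0 / (b0 + (v**2).sum() / 2))
            e = y - xb - u[ip] - v[ig]
            s2_res = 1.0 / rng.gamma(a0 + n / 2, 1.0 / (b0 + (e**2).sum() / 2))
            if it >= burn and (it - burn) % thin == 0:
                keep_u.append(u.copy())
                keep_s2.append((s2_pop, s2_geno, s2_res))
        U = np.array(keep_u)
        S = np.array(keep_s2).mean(axis=0)
        blups = pd.Series(U.mean(axis=0), index=pops.categories, name=self.trait)
        se = pd.Series(U.std(axis=0, ddof=1), index=pops.categories)
        order = list(self.n_plants.index)
        return TraitBLUPs(self.trait, blups.loc[order], se.loc[order],
                          float(S[0]), float(S[1]), float(S[2]), self.n_plants)


def fit_trait_blups(
    obs: pd.DataFrame, covariates_by_trait: dict | None = None,
    min_plants: int = 3, method: str = "reml", **kwargs,
) -> dict[str, TraitBLUPs]:
    """Fit one mixed model per trait present in the long-format table."""
    covariates_by_trait = covariates_by_trait or {}
    out = {}
    for trait in pd.unique(obs["trait"]):
        cov = covariates_by_trait.get(trait, ())
        out[trait] = TraitModel(obs, trait, covariates=cov,
                                min_plants=min_plants).fit(method=method, **kwargs)
    return out


def composite_trait_index(blups_by_trait: dict[str, TraitBLUPs | pd.Series]) -> pd.Series:
    """Equal-weight mean of min-max-standardized per-trait BLUPs.

    Populations are intersected across traits. A trait constant across
    populations carries no ranking information and contributes 0.5 for
    every population (logged). With a single trait the index equals its
    min-max-standardized BLUPs.
    """
    if not blups_by_trait:
        raise ValueError("need at least one trait")
    series = {
        t: (b.blups if isinstance(b, TraitBLUPs) else b)
        for t, b in blups_by_trait.items()
    }
    common = None
    for s in series.values():
        common = set(s.index) if common is None else common & set(s.index)
    common = sorted(common)
    parts = []
    for t, s in series.items():
        v = s.loc[common].to_numpy(float)
        rng_ = v.max() - v.min()
        if rng_ <= 0:
            logger.info("trait %s constant across populations; contributes 0.5", t)
            parts.append(np.full(len(common), 0.5))
        else:
            parts.append((v - v.min()) / rng_)
    return pd.Series(np.mean(parts, axis=0), index=common, name="composite_index")


def validate_offsets(offsets: dict, fitness: dict, min_pops: int = 5) -> pd.DataFrame:
    """Correlate genomic offsets with fitness proxies.

    ``offsets``: {(method, snp_set): per-population offset Series};
    ``fitness``: {trait: per-population Series} (include the composite
    index as one entry). Each cell reports Pearson's r with its two-sided
    p-value and the OLS slope of fitness on offset with its standard error
    and p-value. Negative r is the direction consistent with maladaptation
    (higher offset, lower fitness). Cells with fewer than ``min_pops``
    shared populations are reported as NA with a reason.
    """
    rows = []
    for (method, snp_set), off in offsets.items():
        off = off if isinstance(off, pd.Series) else pd.Series(off)
        for trait, fit in fitness.items():
            fit = fit if isinstance(fit, pd.Series) else pd.Series(fit)
            common = off.index.intersection(fit.index)
            row = {"method": method, "snp_set": snp_set, "trait": trait,
                   "n_pops": len(common)}
            if len(common) < min_pops:
                row.update(pearson_r=np.nan, pearson_p=np.nan, slope=np.nan,
                           slope_se=np.nan, slope_p=np.nan,
                           note=f"<{min_pops} shared populations")
            else:
                x = off.loc[common].to_numpy(float)
                y = fit.loc[common].to_numpy(float)
                r, p = stats.pearsonr(x, y)
                ols = stats.linregress(x, y)
                row.update(pearson_r=r, pearson_p=p, slope=ols.slope,
                           slope_se=ols.stderr, slope_p=ols.pvalue, note="")
            rows.append(row)
    return pd.DataFrame(rows)
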