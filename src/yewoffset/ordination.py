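"""Redundancy analysis (RDA) and genetic variance partitioning.

RDA is the constrained ordination at the heart of population-level
genotype-environment association: a multivariate linear regression of the
population allele-frequency matrix on climate (and optionally other)
predictors, followed by an eigendecomposition of the fitted values. Partial
RDA (pRDA) residualizes both response and predictors on a conditioning
block first, isolating the variance attributable to one predictor set.

The interface follows the model/results convention: :class:`RDA` is built
from data, ``fit()`` returns an :class:`RDAResults` carrying coefficients,
site scores, SNP loadings, eigenvalues and R-squared statistics, with
``summary()``, ``predict_scores()`` and permutation tests hanging off the
results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climsel import ClimateTable
from .genio import AlleleFreqMatrix


def _as_matrix(obj) -> tuple[np.ndarray, list[str], list[str]]:
    """Coerce AlleleFreqMatrix / ClimateTable / DataFrame / ndarray to array."""
    if isinstance(obj, AlleleFreqMatrix):
        return obj.values(), obj.populations, obj.snp_ids
    if isinstance(obj, ClimateTable):
        return obj.values.to_numpy(float), obj.populations, obj.variables
    if isinstance(obj, pd.DataFrame):
        return obj.to_numpy(float), list(obj.index), list(obj.columns)
    arr = np.atleast_2d(np.asarray(obj, float))
    return (arr, None, [str(j) for j in range(arr.shape[1])])


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of M on [1, C] (column-wise OLS)."""
    X = np.column_stack([np.ones(len(M)), C])
    beta, *_ = np.linalg.lstsq(X, M, rcond=None)
    return M - X @ beta


class RDA:
    """Constrained ordination of allele frequencies on predictors.

    Parameters
    ----------
    Y : AlleleFreqMatrix, DataFrame or ndarray (populations x SNPs)
    X : ClimateTable, DataFrame or ndarray (populations x predictors)
        Predictor columns are standardized internally (mean 0, unit sd);
        the standardization is stored so new climates can be projected.
    condition : optional predictor block to partial out (pRDA)
    scale_X : standardize predictors (default True)
    """

    def __init__(self, Y, X, condition=None, scale_X: bool = True):
        self.Y, self.pop_names, self.snp_ids = _as_matrix(Y)
        self.X, x_pops, self.var_names = _as_matrix(X)
        if self.Y.shape[0] != self.X.shape[0]:
            raise ValueError("Y and X must have the same number of populations")
        if self.pop_names is not None and x_pops is not None and self.pop_names != x_pops:
            raise ValueError("population order of Y and X differs")
        if self.pop_names is None:
            self.pop_names = x_pops or [str(i) for i in range(self.Y.shape[0])]
        self.condition = None
        self.cond_names: list[str] = []
        if condition is not None:
            self.condition, c_pops, self.cond_names = _as_matrix(condition)
            if self.condition.shape[0] != self.Y.shape[0]:
                raise ValueError("condition rows must match Y")
        n_par = self.X.shape[1] + (0 if self.condition is None else self.condition.shape[1])
        if self.Y.shape[0] <= n_par + 1:
            raise ValueError("need n_pops > n_predictors + n_condition + 1")
        self.scale_X = scale_X

    @classmethod
    def from_tables(cls, freqs: AlleleFreqMatrix, climate: ClimateTable, condition=None):
        if freqs.populations != climate.populations:
            raise ValueError("population sets of freqs and climate differ")
        return cls(freqs, climate, condition=condition)

    def fit(self) -> "RDAResults":
        n = self.Y.shape[0]
        y_mean = self.Y.mean(axis=0)
        Yc = self.Y - y_mean
        total_inertia = float((Yc**2).sum())

        x_mean = self.X.mean(axis=0)
        x_sd = self.X.std(axis=0, ddof=1)
        x_sd = np.where(x_sd > 0, x_sd, 1.0)
        Z = (self.X - x_mean) / x_sd if self.scale_X else self.X - x_mean

        if self.condition is not None:
            Yw = _residualize(Yc, self.condition)
            Zw = _residualize(Z, self.condition)
        else:
            Yw, Zw = Yc, Z

        B, *_ = np.linalg.lstsq(Zw, Yw, rcond=None)
        if not np.all(np.isfinite(B)):
            raise np.linalg.LinAlgError(
                "singular predictor cross-product; prune collinear variables (VIF)"
            )
        Yhat = Zw @ B
        U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
        tol = max(s[0], 1.0) * 1e-10 if s.size else 0.0
        K = int((s > tol).sum())
        U, s, Vt = U[:, :K], s[:K], Vt[:K]
        eigvals = s**2 / (n - 1)
        site_scores = U * s
        snp_loadings = Vt.T  # SNPs x K, orthonormal axis directions

        r2 = float((Yhat**2).sum()) / total_inertia if total_inertia > 0 else 0.0
        p = self.X.shape[1]
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1) if n - p - 1 > 0 else np.nan
        res = RDAResults(
            model=self,
            coefficients=B,
            site_scores=site_scores,
            snp_loadings=snp_loadings,
            eigenvalues=eigvals,
            K_retained=K,
            total_R2=r2,
            adjusted_R2=adj,
            total_inertia=total_inertia,
            x_mean=x_mean,
            x_sd=x_sd if self.scale_X else np.ones_like(x_sd),
            y_mean=y_mean,
        )
        res._Yw, res._Zw = Yw, Zw
        return res


@dataclass
class RDAResults:
    """Fitted constrained ordination.

    ``coefficients``: predictors x SNPs regression coefficients (on the
    standardized predictor scale). ``site_scores``: populations x K linear
    combination scores (centered per axis). ``snp_loadings``: SNPs x K
    orthonormal axis directions. ``eigenvalues``: constrained-axis
    variances, descending. ``total_R2``: constrained inertia as a fraction
    of the centered response inertia (before conditioning).
    """

    model: RDA
    coefficients: np.ndarray
    site_scores: np.ndarray
    snp_loadings: np.ndarray
    eigenvalues: np.ndarray
    K_retained: int
    total_R2: float
    adjusted_R2: float
    total_inertia: float
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: np.ndarray

    def axis_weights(self, K: int) -> np.ndarray:
        """Axis-importance weights w_k = lambda_k / sum(lambda_1..K)."""
        lam = self.eigenvalues[:K]
        return lam / lam.sum()

    def standardize_climate(self, climate) -> np.ndarray:
        vals, _, names = _as_matrix(climate)
        if names != self.model.var_names:
            raise ValueError(
                f"climate variables {names} do not match model variables "
                f"{self.model.var_names}"
            )
        return (vals - self.x_mean) / self.x_sd

    def predict_scores(self, climate, K: int | None = None) -> np.ndarray:
        """Climate-only population scores: Z_new B V over the first K axes."""
        K = self.K_retained if K is None else K
        if K > self.K_retained:
            raise ValueError(f"K={K} exceeds the {self.K_retained} retained axes")
        Z = self.standardize_climate(climate)
        return Z @ self.coefficients @ self.snp_loadings[:, :K]

    def observed_scores(self, Y=None, K: int | None = None) -> np.ndarray:
        """Projection of centered allele-frequency rows onto the axes."""
        K = self.K_retained if K is None else K
        Ymat = self.model.Y if Y is None else _as_matrix(Y)[0]
        return (Ymat - self.y_mean) @ self.snp_loadings[:, :K]

    def anova_permutation(self, n_perm: int = 999, seed: int = 0) -> float:
        """Permutation p-value of the constrained fraction.

        Rows of the (residualized) predictor block are permuted against
        the fixed response, which is the correct exchangeable unit for a
        partial model.
        """
        rng = np.random.default_rng(seed)
        Yw, Zw = self._Yw, self._Zw
        fit0 = Zw @ np.linalg.lstsq(Zw, Yw, rcond=None)[0]
        stat = float((fit0**2).sum())
        exceed = 0
        for _ in range(n_perm):
            Zp = Zw[rng.permutation(len(Zw))]
            fit = Zp @ np.linalg.lstsq(Zp, Yw, rcond=None)[0]
            if float((fit**2).sum()) >= stat:
                exceed += 1
        return (exceed + 1) / (n_perm + 1)

    def summary(self) -> str:
        lines = [
            "Redundancy analysis (RDA)" + (" — partial" if self.model.condition is not None else ""),
            f"  populations: {len(self.model.pop_names)}   SNPs: {len(self.model.snp_ids)}",
            f"  predictors:  {', '.join(self.model.var_names)}",
        ]
        if self.model.cond_names:
            lines.append(f"  conditioned on: {', '.join(self.model.cond_names)}")
        lines += [
            f"  constrained axes retained: {self.K_retained}",
            f"  R2 = {self.total_R2:.4f}   adjusted R2 = {self.adjusted_R2:.4f}",
            "  eigenvalues: "
            + ", ".join(f"{v:.4g}" for v in self.eigenvalues[: min(6, self.K_retained)]),
        ]
        return "\n".join(lines)


def partition_table(r2_full: float, pure: dict[str, float]) -> pd.DataFrame:
    """Arithmetic of a variance-partition table.

    Given the full-model R-squared and the pure (conditioned) R-squared of
    each predictor block, derive the confounded fraction, the unexplained
    fraction and each row's share of the explained variance.
    """
    rows = [("full", r2_full, 1.0)]
    confounded = r2_full - sum(pure.values())
    for name, r2 in pure.items():
        rows.append((f"pure_{name}", r2, r2 / r2_full))
    rows.append(("confounded", confounded, confounded / r2_full))
    rows.append(("unexplained", 1.0 - r2_full, np.nan))
    return pd.DataFrame(rows, columns=["component", "R2", "relative"]).set_index(
        "component"
    )


@dataclass
class VariancePartition:
    """Decomposition of genetic variance into climate, structure, geography."""

    R2_full: float
    R2_pure: dict[str, float]
    pvalues: dict[str, float] = field(default_factory=dict)

    @property
    def R2_confounded(self) -> float:
        return self.R2_full - sum(self.R2_pure.values())

    @property
    def R2_unexplained(self) -> float:
        return 1.0 - self.R2_full

    def table(self) -> pd.DataFrame:
        t = partition_table(self.R2_full, self.R2_pure)
        t["p"] = [
            self.pvalues.get(c, self.pvalues.get(c.removeprefix("pure_"), np.nan))
            for c in t.index
        ]
        return t

    def to_dict(self) -> dict:
        return {
            "R2_full": self.R2_full,
            **{f"R2_pure_{k}": v for k, v in self.R2_pure.items()},
            "R2_confounded": self.R2_confounded,
            "R2_unexplained": self.R2_unexplained,
            "pvalues": self.pvalues,
        }


def variance_partition(
    Y,
    climate,
    structure_pcs=None,
    geography=None,
    n_perm: int = 99,
    seed: int = 0,
) -> VariancePartition:
    """Full-model and pure-block R-squared via RDA and pRDA.

    Fits the full model on all blocks, then one pRDA per block conditioned
    on the union of the others. The confounded fraction is the full R2
    minus the sum of pure fractions (it can be negative when blocks act as
    suppressors). Permutation p-values permute response rows against the
    residualized tested block.
    """
    Ymat, _, _ = _as_matrix(Y)
    blocks: dict[str, np.ndarray] = {}
    blocks["climate"] = _as_matrix(climate)[0]
    if structure_pcs is not None:
        blocks["structure"] = _as_matrix(structure_pcs)[0]
    if geography is not None:
        blocks["geography"] = _as_matrix(geography)[0]
    n = Ymat.shape[0]
    p_all = sum(b.shape[1] for b in blocks.values())
    if p_all >= n - 1:
        raise ValueError("combined predictor count must be < n_pops - 1")

    X_all = np.column_stack([_std_cols(b) for b in blocks.values()])
    full = RDA(Ymat, X_all, scale_X=False).fit()

    rng = np.random.default_rng(seed)
    pure: dict[str, float] = {}
    pvalues: dict[str, float] = {"full": full.anova_permutation(n_perm, seed=int(rng.integers(2**31)))}
    for name, b in blocks.items():
        others = [v for k, v in blocks.items() if k != name]
        cond = np.column_stack([_std_cols(o) for o in others]) if others else None
        res = RDA(Ymat, _std_cols(b), condition=cond, scale_X=False).fit()
        pure[name] = res.total_R2
        pvalues[name] = res.anova_permutation(n_perm, seed=int(rng.integers(2**31)))
    return VariancePartition(full.total_R2, pure, pvalues)


def _std_cols(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, float)
    sd = M.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (M - M.mean(axis=0)) / sd
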