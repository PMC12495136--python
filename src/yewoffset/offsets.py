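"""Genomic offsets and the genomic discrepancy index (GDI).

A genomic offset is the distance between a population's modeled genomic
composition under its reference climate and under a future (or transplant)
climate — a proxy for expected climate maladaptation. Two prediction
engines are supported: the linear constrained-ordination route (climate
projected through fitted RDA axes) and the nonlinear gradient-forest route
(climates transformed by cumulative-importance turnover functions).

The GDI measures how far a population's *observed* genomic composition
sits from its climate-*predicted* composition on the leading constrained
axes — large values flag populations deviating from the species-wide
gene-climate relationship.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climsel import ClimateTable
from .gea import TurnoverFunction
from .ordination import RDAResults


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Scale to [0, 1] across entries; all-equal input maps to all zeros."""
    x = np.asarray(x, float)
    lo, hi = np.min(x), np.max(x)
    if hi - lo <= 0:
        warnings.warn("all values equal; min-max normalization returns zeros")
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def quantile_classes(x: np.ndarray, n_classes: int = 5) -> np.ndarray:
    """Equal-occupancy classes 1..n (class 1 = lowest), sizes differing by <= 1.

    Ties in ``x`` break by position order, which is population label order
    in every caller.
    """
    x = np.asarray(x, float)
    n = len(x)
    order = np.argsort(x, kind="stable")
    classes = np.empty(n, dtype=int)
    # first (n % n_classes) classes get the extra member
    sizes = np.full(n_classes, n // n_classes)
    sizes[: n % n_classes] += 1
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    for c in range(n_classes):
        classes[order[bounds[c] : bounds[c + 1]]] = c + 1
    return classes


@dataclass
class OffsetResult:
    """Per-population offsets for one method and one SNP set."""

    raw: pd.DataFrame  # populations x GCMs
    method: str  # "rda" | "gf"
    snp_set: str  # "all" | "outlier" | "random" | "random_2" | "all_outlier"
    n_classes: int = 5

    def __post_init__(self) -> None:
        self.mean_raw = self.raw.mean(axis=1)
        self.normalized = pd.Series(
            minmax_normalize(self.mean_raw.to_numpy()), index=self.raw.index
        )
        self.classes = pd.Series(
            quantile_classes(self.mean_raw.to_numpy(), self.n_classes),
            index=self.raw.index,
        )

    @property
    def populations(self) -> list[str]:
        return list(self.raw.index)

    def to_frame(self) -> pd.DataFrame:
        out = self.raw.copy()
        out["mean"] = self.mean_raw
        out["normalized"] = self.normalized
        out["class"] = self.classes
        out.insert(0, "snp_set", self.snp_set)
        out.insert(0, "method", self.method)
        return out


def aggregate_offsets(
    raw: pd.DataFrame, method: str = "rda", snp_set: str = "all", n_classes: int = 5
) -> OffsetResult:
    """Mean across GCM columns, min-max normalize, classify into quantile classes."""
    if raw.shape[1] < 1:
        raise ValueError("need at least one GCM column")
    return OffsetResult(raw, method, snp_set, n_classes)


def robustness_flags(result_a: OffsetResult, result_b: OffsetResult) -> pd.Series:
    """Non-robust populations: the two methods' classes differ by 2 or more."""
    if result_a.populations != result_b.populations:
        raise ValueError("population sets of the two results differ")
    diff = (result_a.classes - result_b.classes).abs()
    return (diff >= 2).rename("non_robust")


def rda_offset(
    results: RDAResults,
    clim_ref: ClimateTable,
    clim_fut: ClimateTable,
    K: int = 2,
) -> pd.Series:
    """Linear genomic offset on the constrained axes.

    Population scores are predicted from climate alone at the reference and
    future climates; the offset is the Euclidean distance over the first K
    axes after weighting each axis by its share of the retained eigenvalue
    mass, w_k = lambda_k / sum(lambda_1..K).
    """
    s_ref = results.predict_scores(clim_ref, K=K)
    s_fut = results.predict_scores(clim_fut, K=K)
    w = results.axis_weights(K)
    d = np.sqrt((((s_ref - s_fut) * w) ** 2).sum(axis=1))
    return pd.Series(d, index=clim_ref.populations, name="offset")


def gf_offset(
    turnover: dict[str, TurnoverFunction],
    clim_ref: ClimateTable,
    clim_fut: ClimateTable,
) -> pd.Series:
    """Nonlinear genomic offset through turnover functions.

    Each climate variable is mapped through its cumulative-importance
    function (clamped outside the training range); the offset is the
    Euclidean distance between the transformed reference and future
    climate vectors. A flat turnover contributes nothing however large the
    climatic shift.
    """
    missing = [v for v in clim_ref.variables if v not in turnover]
    if missing:
        raise ValueError(f"variables absent from turnover set: {missing}")
    parts = []
    for v in clim_ref.variables:
        f = turnover[v]
        parts.append(f(clim_ref.values[v].to_numpy()) - f(clim_fut.values[v].to_numpy()))
    d = np.sqrt(np.sum(np.array(parts) ** 2, axis=0))
    return pd.Series(d, index=clim_ref.populations, name="offset")


def garden_offset(
    results_or_turnover,
    clim_origin_ref: ClimateTable,
    clim_garden,
    K: int = 2,
    method: str = "rda",
) -> pd.Series:
    """Offset between each population's origin climate and a common garden.

    The garden climate (one vector per evaluation window) replaces the
    future climate of :func:`rda_offset` / :func:`gf_offset`; it must be
    expressed in the model's variables (same units as the origin table).
    """
    garden = np.asarray(clim_garden, float).reshape(1, -1)
    garden_table = ClimateTable(
        pd.DataFrame(
            np.repeat(garden, len(clim_origin_ref.populations), axis=0),
            index=clim_origin_ref.populations,
            columns=clim_origin_ref.variables,
        ),
        period="garden",
    )
    if method == "rda":
        return rda_offset(results_or_turnover, clim_origin_ref, garden_table, K=K)
    if method == "gf":
        return gf_offset(results_or_turnover, clim_origin_ref, garden_table)
    raise ValueError("method must be 'rda' or 'gf'")


@dataclass
class GDIResult:
    """Observed-vs-predicted score discrepancy per population."""

    observed_scores: pd.DataFrame
    predicted_scores: pd.DataFrame
    weights: np.ndarray
    raw: pd.Series
    normalized: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"raw_distance": self.raw, "gdi": self.normalized}
        )


def gdi_rda(
    results: RDAResults,
    Y=None,
    clim_ref: ClimateTable | None = None,
    K: int = 2,
) -> GDIResult:
    """Genomic discrepancy index on the first K constrained axes.

    Observed scores project each population's centered allele-frequency
    vector onto the axes; predicted scores come from the linear combination
    of the climate variables. Both are weighted per axis by
    w_k = lambda_k / sum(lambda_1..K); the Euclidean distance between them
    is min-max normalized across populations. The raw distance is exactly
    zero everywhere when the response is exactly linear in climate.
    """
    if K > results.K_retained:
        raise ValueError(f"K={K} exceeds {results.K_retained} retained axes")
    clim = clim_ref if clim_ref is not None else ClimateTable(
        pd.DataFrame(results.model.X, index=results.model.pop_names,
                     columns=results.model.var_names)
    )
    obs = results.observed_scores(Y, K=K)
    pred = results.predict_scores(clim, K=K)
    w = results.axis_weights(K)
    d = np.sqrt((((obs - pred) * w) ** 2).sum(axis=1))
    pops = results.model.pop_names
    cols = [f"RDA{k + 1}" for k in range(K)]
    return GDIResult(
        observed_scores=pd.DataFrame(obs, index=pops, columns=cols),
        predicted_scores=pd.DataFrame(pred, index=pops, columns=cols),
        weights=w,
        raw=pd.Series(d, index=pops, name="raw_distance"),
        normalized=pd.Series(minmax_normalize(d), index=pops, name="gdi"),
    )
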