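"""Climate predictor selection and spatial covariates.

Implements the predictor-screening ladder used in landscape-genomics GEA
studies: permutation-based forward selection against a constrained
ordination, pairwise Pearson-correlation pruning, variance-inflation-factor
pruning, and distance-based Moran's eigenvector maps (dbMEMs) as geography
covariates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass
class ClimateTable:
    """Populations x climate variables for one period and one GCM.

    ``values``: DataFrame indexed by population, one column per variable.
    ``period``: label such as ``"reference"`` or ``"2041-2070"``.
    ``gcm``: climate-model label; empty string for the reference period.
    """

    values: pd.DataFrame
    period: str = "reference"
    gcm: str = ""

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("climate table contains missing values")

    @property
    def populations(self) -> list[str]:
        return list(self.values.index)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, variables) -> "ClimateTable":
        return ClimateTable(self.values[list(variables)], self.period, self.gcm)

    def to_long(self) -> pd.DataFrame:
        long = self.values.reset_index(names="population").melt(
            id_vars="population", var_name="variable", value_name="value"
        )
        long["period"] = self.period
        long["gcm"] = self.gcm
        return long


@dataclass
class SelectionReport:
    """Outcome of a predictor-selection step."""

    kept: list[str]
    dropped: list[tuple[str, str, float]] = field(default_factory=list)
    pvalues: dict[str, float] = field(default_factory=dict)
    vifs: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "kept": self.kept,
            "dropped": [list(d) for d in self.dropped],
            "pvalues": self.pvalues,
            "vifs": self.vifs,
        }


def _standardize(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - X.mean(axis=0)) / sd


def _multivariate_r2(Y: np.ndarray, X: np.ndarray) -> float:
    """Fraction of the centered response inertia captured by OLS on X."""
    Yc = Y - Y.mean(axis=0)
    tot = float((Yc**2).sum())
    if tot == 0:
        return 0.0
    Xc = X - X.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fit = Xc @ beta
    return float(np.clip((fit**2).sum() / tot, 0.0, 1.0))


def _adjusted_r2(r2: float, n: int, p: int) -> float:
    # Ezekiel correction
    if n - p - 1 <= 0:
        return -np.inf
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def forward_select(
    Y,
    X: ClimateTable,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
) -> SelectionReport:
    """Permutation-based forward selection of climate predictors.

    Starting from the empty model, the candidate maximizing the adjusted
    R-squared of the constrained ordination of ``Y`` is proposed at each
    step; it is admitted only if the permutation p-value of its marginal
    pseudo-F (candidate rows permuted, ``n_perm`` permutations) is at most
    ``alpha`` and the adjusted R-squared does not exceed that of the full
    model containing all preselected variables. Climate columns are
    standardized internally, so selection is invariant to affine rescaling
    of any variable.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    Ymat = Y.values() if hasattr(Y, "values") and not isinstance(Y, pd.DataFrame) else np.asarray(Y, float)
    if isinstance(Y, pd.DataFrame):
        Ymat = Y.to_numpy(dtype=float)
    names = X.variables
    Z = _standardize(X.values.to_numpy(dtype=float))
    n = Ymat.shape[0]

    full_adj = _adjusted_r2(_multivariate_r2(Ymat, Z), n, Z.shape[1])
    kept: list[int] = []
    pvalues: dict[str, float] = {}
    dropped: list[tuple[str, str, float]] = []

    while True:
        remaining = [j for j in range(len(names)) if j not in kept]
        if not remaining:
            break
        if n < len(kept) + 3:
            logger.warning("too few populations to extend the model; stopping")
            break
        r2_base = _multivariate_r2(Ymat, Z[:, kept]) if kept else 0.0
        best_j, best_adj, best_r2 = None, -np.inf, 0.0
        for j in remaining:
            cols = kept + [j]
            r2 = _multivariate_r2(Ymat, Z[:, cols])
            adj = _adjusted_r2(r2, n, len(cols))
            if adj > best_adj:
                best_j, best_adj, best_r2 = j, adj, r2
        # global stop: the growing model may not beat the full model's
        # adjusted fit (skipped at alpha >= 1, where the caller asks for
        # exhaustive admission rather than a significance-guided search)
        if alpha < 1 and best_adj > full_adj + 1e-12:
            break
        df_resid = n - len(kept) - 2
        if df_resid <= 0:
            break
        denom = max(1.0 - best_r2, 1e-12) / df_resid
        f_obs = (best_r2 - r2_base) / denom
        exceed = 0
        zj = Z[:, best_j].copy()
        for _ in range(n_perm):
            zp = rng.permutation(zj)
            cols = np.column_stack([Z[:, kept], zp]) if kept else zp[:, None]
            r2p = _multivariate_r2(Ymat, cols)
            fp = (r2p - r2_base) / (max(1.0 - r2p, 1e-12) / df_resid)
            if fp >= f_obs:
                exceed += 1
        p = (exceed + 1) / (n_perm + 1)
        pvalues[names[best_j]] = p
        if p <= alpha:
            kept.append(best_j)
        else:
            dropped.append((names[best_j], "forward_ns", p))
            break

    kept_names = [names[j] for j in kept]
    for nm in names:
        if nm not in kept_names and all(d[0] != nm for d in dropped):
            dropped.append((nm, "never_entered", np.nan))
    return SelectionReport(kept_names, dropped, pvalues)


def prune_correlated(
    X: ClimateTable, r_max: float = 0.75, priority: list[str] | None = None
) -> SelectionReport:
    """Drop one variable of every pair with |Pearson r| strictly above ``r_max``.

    The variable ranked lower in ``priority`` (e.g. forward-selection order)
    is dropped; variables absent from ``priority`` rank below all listed
    ones, later columns below earlier ones. Pairs at exactly ``r_max`` are
    kept (strict inequality).
    """
    if not (0 < r_max < 1):
        raise ValueError("r_max must be in (0, 1)")
    names = X.variables
    rank = {nm: i for i, nm in enumerate(priority or [])}
    order = {nm: (rank.get(nm, len(rank)), i) for i, nm in enumerate(names)}
    keep = list(names)
    dropped: list[tuple[str, str, float]] = []
    while True:
        if len(keep) < 2:
            break
        corr = X.values[keep].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        if corr[i, j] <= r_max:
            break
        a, b = keep[i], keep[j]
        loser = b if order[a] <= order[b] else a
        dropped.append((loser, "correlation", float(corr[i, j])))
        keep.remove(loser)
    return SelectionReport(keep, dropped)


def compute_vifs(values: pd.DataFrame) -> dict[str, float]:
    """VIF_j = 1 / (1 - R2_j) from regressing variable j on the others."""
    names = list(values.columns)
    Z = _standardize(values.to_numpy(dtype=float))
    vifs = {}
    for j, nm in enumerate(names):
        others = np.delete(Z, j, axis=1)
        if others.shape[1] == 0:
            vifs[nm] = 1.0
            continue
        Xd = np.column_stack([np.ones(len(Z)), others])
        beta, *_ = np.linalg.lstsq(Xd, Z[:, j], rcond=None)
        resid = Z[:, j] - Xd @ beta
        sst = float((Z[:, j] ** 2).sum())
        r2 = 1.0 - float((resid**2).sum()) / sst if sst > 0 else 0.0
        vifs[nm] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def prune_vif(X: ClimateTable, vif_max: float = 10.0) -> SelectionReport:
    """Iteratively drop the largest-VIF variable until all VIFs < ``vif_max``.

    Perfectly collinear variables have infinite VIF and are dropped first.
    """
    names = list(X.variables)
    if len(names) < 2:
        return SelectionReport(names, vifs={nm: 1.0 for nm in names})
    keep = list(names)
    dropped: list[tuple[str, str, float]] = []
    while len(keep) >= 2:
        vifs = compute_vifs(X.values[keep])
        worst = max(keep, key=lambda nm: vifs[nm])
        if vifs[worst] < vif_max:
            break
        dropped.append((worst, "vif", float(vifs[worst])))
        keep.remove(worst)
    final_vifs = compute_vifs(X.values[keep]) if len(keep) >= 2 else {nm: 1.0 for nm in keep}
    return SelectionReport(keep, dropped, vifs=final_vifs)


def haversine_matrix(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Great-circle distance matrix in kilometres."""
    lon = np.radians(np.asarray(lon, float))
    lat = np.radians(np.asarray(lat, float))
    dlon = lon[:, None] - lon[None, :]
    dlat = lat[:, None] - lat[None, :]
    a = (
        np.sin(dlat / 2) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def morans_i(u: np.ndarray, W: np.ndarray) -> float:
    """Moran's I of vector ``u`` under spatial weights ``W``."""
    u = np.asarray(u, float)
    z = u - u.mean()
    s0 = W.sum()
    denom = float((z**2).sum())
    if s0 == 0 or denom == 0:
        return 0.0
    return float(len(u) / s0 * (z @ W @ z) / denom)


def dbmem(coords: pd.DataFrame, return_eigvals: bool = False):
    """Distance-based Moran's eigenvector maps from lon/lat coordinates.

    Great-circle distances are truncated at the longest edge of their
    minimum spanning tree (larger distances replaced by four times the
    truncation distance), the truncated matrix is double-centered and
    eigendecomposed, and eigenvectors showing positive spatial
    autocorrelation (Moran's I above its null expectation -1/(n-1) under
    the within-truncation neighbour graph) are returned, ordered by
    decreasing eigenvalue.
    """
    lon = coords["lon"].to_numpy(float)
    lat = coords["lat"].to_numpy(float)
    n = len(lon)
    if n < 3:
        raise ValueError("need at least 3 locations")
    D = haversine_matrix(lon, lat)
    if np.allclose(squareform(D, checks=False), 0):
        raise ValueError("all coordinates are identical")
    mst = minimum_spanning_tree(D).toarray()
    trunc = mst.max()
    Dt = np.where(D > trunc, 4.0 * trunc, D)
    np.fill_diagonal(Dt, 0.0)
    # PCoA (Gower double centering) of the truncated distance matrix
    A = -0.5 * Dt**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigvals, eigvecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-9 * max(abs(eigvals[0]), 1.0)
    eigvals, eigvecs = eigvals[pos], eigvecs[:, pos]
    W = ((D <= trunc) & (D > 0)).astype(float)
    expect = -1.0 / (n - 1)
    keep = [k for k in range(eigvecs.shape[1]) if morans_i(eigvecs[:, k], W) > expect]
    V = eigvecs[:, keep]
    out = pd.DataFrame(
        V, index=coords.index, columns=[f"MEM{k + 1}" for k in range(V.shape[1])]
    )
    if return_eigvals:
        return out, eigvals[keep]
    return out
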