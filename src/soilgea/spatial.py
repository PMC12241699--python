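"""Spatial PCA of candidate loci and cline regressions.

Spatial PCA maximises the product of score variance and Moran's I over
a connection network, so its positive eigenvalues pick out global,
cline-like multilocus structures and its negative eigenvalues local
(neighbour-contrast) ones.  The lagged score — the row-standardised
network average of a score — is the smoothed multilocus cline that gets
regressed on soil predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SoilGEAError, GenotypeMatrix
from .sim import haversine_km


# ----------------------------------------------------------------------
# connection network
# ----------------------------------------------------------------------

@dataclass
class ConnectionNetwork:
    coords: np.ndarray          # nodes x 2 (lon, lat) or planar
    W: np.ndarray               # symmetric non-negative weights, zero diagonal
    W_row: np.ndarray           # row-standardised copy
    method: str = "knn"
    params: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


def build_connection_network(
    coords, method: str = "knn", k: int = 3, planar: bool = False
) -> ConnectionNetwork:
    """Symmetrised k-nearest-neighbour graph with inverse-distance weights.

    Coordinates are decimal-degree (lon, lat) pairs by default, with
    great-circle distances in km; set ``planar=True`` for Euclidean
    coordinates.  Duplicate coordinates are refused (aggregate samples
    to sites first).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < k + 1:
        raise SoilGEAError(f"need at least k+1={k + 1} nodes")
    uniq, counts = np.unique(coords, axis=0, return_counts=True)
    if (counts > 1).any():
        dups = uniq[counts > 1]
        raise SoilGEAError(f"duplicate coordinates (aggregate to sites first): {dups.tolist()}")
    if planar:
        diff = coords[:, None, :] - coords[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
    else:
        d = haversine_km(coords)
    np.fill_diagonal(d, np.inf)
    W = np.zeros((n, n))
    for i in range(n):
        nbrs = np.argsort(d[i])[:k]
        W[i, nbrs] = 1.0 / d[i, nbrs]
    W = np.maximum(W, W.T)       # symmetrise
    np.fill_diagonal(W, 0.0)
    reach = _connected(W)
    if not reach:
        warnings.warn("connection network is not connected")
    W_row = W / W.sum(axis=1, keepdims=True)
    return ConnectionNetwork(coords, W, W_row, method, {"k": k, "planar": planar})


def _connected(W: np.ndarray) -> bool:
    n = W.shape[0]
    seen = {0}
    stack = [0]
    adj = [np.flatnonzero(W[i] > 0) for i in range(n)]
    while stack:
        i = stack.pop()
        for j in adj[i]:
            if j not in seen:
                seen.add(int(j))
                stack.append(int(j))
    return len(seen) == n


def morans_i(values: np.ndarray, W_row: np.ndarray) -> float:
    """Moran's I with row-standardised weights (S0 = n)."""
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return 0.0
    return float(x @ (W_row @ x) / denom)


# ----------------------------------------------------------------------
# spatial PCA
# ----------------------------------------------------------------------

@dataclass
class SPCAResults:
    eigenvalues: np.ndarray     # all, descending (signed)
    global_axes: np.ndarray     # loci x n_axes eigenvectors (most positive)
    local_axes: np.ndarray      # loci x n_axes eigenvectors (most negative)
    scores: np.ndarray          # samples x n_axes (global)
    lagged_scores: np.ndarray   # samples x n_axes (global)
    axis_variance: np.ndarray
    axis_moran: np.ndarray
    sample_ids: list = field(default_factory=list)

    def frame(self) -> pd.DataFrame:
        cols = {}
        for a in range(self.scores.shape[1]):
            cols[f"score{a + 1}"] = self.scores[:, a]
            cols[f"lagged{a + 1}"] = self.lagged_scores[:, a]
        return pd.DataFrame(cols, index=self.sample_ids)


class SPCA:
    """Spatial PCA of a (complete) candidate dosage matrix on a network.

    Samples map onto network nodes via ``sample_nodes`` (site index per
    sample) when the network is site-level; with one node per sample
    the mapping is the identity.
    """

    def __init__(self, G_candidates: GenotypeMatrix, net: ConnectionNetwork,
                 sample_nodes: np.ndarray | None = None):
        if G_candidates.missing_mask.any():
            raise SoilGEAError("sPCA requires a complete matrix")
        self.G = G_candidates
        self.net = net
        n = G_candidates.n_samples
        if sample_nodes is None:
            if net.n_nodes != n:
                raise SoilGEAError(
                    "network nodes != samples; pass sample_nodes mapping samples to sites"
                )
            self.Wbar = net.W_row
        else:
            sample_nodes = np.asarray(sample_nodes, dtype=int)
            if len(sample_nodes) != n:
                raise SoilGEAError("sample_nodes must have one node per sample")
            # expand a site-level row-standardised W to sample level: the
            # weight a focal sample gives site t is split evenly among the
            # samples at t, so rows still sum to 1.
            counts = np.bincount(sample_nodes, minlength=net.n_nodes).astype(float)
            Ws = net.W_row[np.ix_(sample_nodes, sample_nodes)]
            self.Wbar = Ws / counts[sample_nodes][None, :]

    def fit(self, n_axes: int = 2) -> SPCAResults:
        X = self.G.dosage.astype(float)
        X = X - X.mean(axis=0)
        n = X.shape[0]
        Wsym = (self.Wbar + self.Wbar.T) / 2.0
        M = X.T @ (Wsym @ X) / n
        eigval, eigvec = np.linalg.eigh((M + M.T) / 2)
        order = np.argsort(eigval)[::-1]
        eigval, eigvec = eigval[order], eigvec[:, order]
        rank = min(np.linalg.matrix_rank(X), len(eigval))
        k = min(n_axes, rank)
        if k < n_axes:
            warnings.warn(f"n_axes capped at rank {rank}")
        V = eigvec[:, :k]
        scores = X @ V
        lagged = self.Wbar @ scores
        var = (scores**2).sum(axis=0) / n
        moran = np.array([morans_i(scores[:, a], self.Wbar) for a in range(k)])
        Vloc = eigvec[:, -k:]
        return SPCAResults(
            eigenvalues=eigval,
            global_axes=V,
            local_axes=Vloc,
            scores=scores,
            lagged_scores=lagged,
            axis_variance=var,
            axis_moran=moran,
            sample_ids=list(self.G.sample_ids),
        )


def spca(G_candidates: GenotypeMatrix, net: ConnectionNetwork, n_axes: int = 2,
         sample_nodes=None) -> SPCAResults:
    return SPCA(G_candidates, net, sample_nodes).fit(n_axes=n_axes)


# ----------------------------------------------------------------------
# cline regressions
# ----------------------------------------------------------------------

@dataclass
class ClineRegression:
    axis: int
    univariate: pd.DataFrame    # predictor, intercept, slope, r2_adj, p
    stepwise_terms: list
    stepwise_coef: dict
    stepwise_r2_adj: float
    stepwise_p: float | None
    aic_path: list


def _ols_fit(y: np.ndarray, X: pd.DataFrame):
    import statsmodels.api as sm

    model = sm.OLS(y, sm.add_constant(X, has_constant="add"))
    return model.fit()


def stepwise_cline_regression(
    lagged_scores: np.ndarray | pd.DataFrame,
    predictors: pd.DataFrame,
) -> list[ClineRegression]:
    """Univariate OLS per predictor plus bidirectional AIC-stepwise
    selection from the null model, for every lagged-score axis.

    Predictors are broadcast to individuals by the caller; individuals
    are treated as replicates.
    """
    L = np.asarray(lagged_scores, dtype=float)
    if L.ndim == 1:
        L = L[:, None]
    if len(predictors) != len(L):
        raise SoilGEAError("predictors must be broadcast to one row per individual")
    # drop rank-deficient predictors
    P = predictors.copy()
    for c in list(P.columns):
        if P[c].std() == 0:
            warnings.warn(f"dropping constant predictor {c}")
            P = P.drop(columns=c)
    n = len(P)
    if n <= P.shape[1] + 2:
        raise SoilGEAError("too few individuals for the number of predictors")

    out = []
    for a in range(L.shape[1]):
        y = L[:, a]
        rows = []
        for c in P.columns:
            fit = _ols_fit(y, P[[c]])
            rows.append(
                dict(
                    predictor=c,
                    intercept=float(fit.params.iloc[0]),
                    slope=float(fit.params.iloc[1]),
                    r2_adj=float(fit.rsquared_adj),
                    p=float(fit.f_pvalue),
                )
            )
        uni = pd.DataFrame(rows)

        # bidirectional stepwise by AIC starting from the null model
        import statsmodels.api as sm

        terms: list[str] = []
        null_fit = sm.OLS(y, np.ones((n, 1))).fit()
        best_aic = null_fit.aic
        aic_path = [float(best_aic)]
        improved = True
        while improved:
            improved = False
            candidates = []
            for c in P.columns:
                if c not in terms:
                    candidates.append(("add", c, terms + [c]))
            for c in terms:
                candidates.append(("drop", c, [t for t in terms if t != c]))
            best_step = None
            for action, c, new_terms in candidates:
                fit = (
                    _ols_fit(y, P[new_terms])
                    if new_terms
                    else sm.OLS(y, np.ones((n, 1))).fit()
                )
                if fit.aic < best_aic - 1e-9 and (best_step is None or fit.aic < best_step[2]):
                    best_step = (new_terms, fit, fit.aic)
            if best_step is not None:
                terms, final_fit, best_aic = best_step
                aic_path.append(float(best_aic))
                improved = True
        if terms:
            final_fit = _ols_fit(y, P[terms])
            coef = {"intercept": float(final_fit.params.iloc[0])}
            coef.update({t: float(v) for t, v in final_fit.params.iloc[1:].items()})
            r2a = float(final_fit.rsquared_adj)
            pval = float(final_fit.f_pvalue)
        else:
            coef, r2a, pval = {"intercept": float(np.mean(y))}, 0.0, None
        out.append(
            ClineRegression(
                axis=a + 1,
                univariate=uni,
                stepwise_terms=list(terms),
                stepwise_coef=coef,
                stepwise_r2_adj=r2a,
                stepwise_p=pval,
                aic_path=aic_path,
            )
        )
    return out


# ----------------------------------------------------------------------
# inverse-distance interpolation
# ----------------------------------------------------------------------

def idw_interpolate(
    site_coords,
    site_values,
    grid_spec: dict | None = None,
    power: float = 2.0,
    planar: bool = False,
):
    """Inverse-distance-weighted surface of site values on a grid.

    ``grid_spec`` holds nx, ny and optionally lon/lat bounds (defaults:
    the site bounding box).  Exact at site locations.  Returns
    (grid_lon, grid_lat, surface) with surface shape (ny, nx).
    """
    coords = np.asarray(site_coords, dtype=float)
    vals = np.asarray(site_values, dtype=float)
    if len(coords) < 3:
        raise SoilGEAError("need at least 3 sites to interpolate")
    spec = dict(nx=50, ny=50)
    spec.update(grid_spec or {})
    lon0 = spec.get("lon_min", coords[:, 0].min())
    lon1 = spec.get("lon_max", coords[:, 0].max())
    lat0 = spec.get("lat_min", coords[:, 1].min())
    lat1 = spec.get("lat_max", coords[:, 1].max())
    if lon1 < coords[:, 0].min() or lon0 > coords[:, 0].max():
        warnings.warn("grid does not cover any site; pure extrapolation")
    gx = np.linspace(lon0, lon1, spec["nx"])
    gy = np.linspace(lat0, lat1, spec["ny"])
    GX, GY = np.meshgrid(gx, gy)
    pts = np.column_stack([GX.ravel(), GY.ravel()])
    if planar:
        diff = pts[:, None, :] - coords[None, :, :]
        d = np.sqrt((diff**2).sum(axis=-1))
    else:
        d = haversine_km(pts, coords)
    surface = np.empty(len(pts))
    exact = d < 1e-9
    any_exact = exact.any(axis=1)
    with np.errstate(divide="ignore"):
        w = 1.0 / d**power
    w[any_exact] = 0.0
    surface = (w * vals[None, :]).sum(axis=1) / np.maximum(w.sum(axis=1), 1e-300)
    for i in np.flatnonzero(any_exact):
        surface[i] = vals[np.argmax(exact[i])]
    return gx, gy, surface.reshape(spec["ny"], spec["nx"])
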