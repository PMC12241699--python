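"""Soil-predictor preparation: correlation pruning, univariate
Anderson-Darling and multivariate Royston normality tests, VIF
screening and an environmental PCA whose first two axes (EPC1/EPC2)
feed the cline regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd
from scipy import stats

from .io import SoilGEAError


@dataclass
class EnvPrepReport:
    dropped_by_correlation: list = field(default_factory=list)  # (dropped, kept, r)
    ad_p: dict = field(default_factory=dict)
    royston_h: float | None = None
    royston_p: float | None = None
    royston_computed: bool = False
    vif: dict = field(default_factory=dict)
    retained: list = field(default_factory=list)

    def to_json(self, path: str) -> str:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)
        return path


def prune_correlated(S: pd.DataFrame, r_max: float = 0.75):
    """Iteratively remove one member of every |r| >= r_max pair.

    Zero-variance variables are dropped first.  From the worst
    (highest |r|) remaining pair the member with the larger mean |r|
    to all other variables is removed, which keeps the less redundant
    one; deterministic.
    """
    if S.shape[1] < 2:
        raise SoilGEAError("need at least two variables")
    report = []
    S = S.copy()
    for v in list(S.columns):
        if S[v].std() == 0:
            report.append((v, None, float("nan")))
            S = S.drop(columns=v)
    while S.shape[1] >= 2:
        r = S.corr().abs().to_numpy()
        np.fill_diagonal(r, 0.0)
        i, j = np.unravel_index(np.argmax(r), r.shape)
        if r[i, j] < r_max:
            break
        mean_r = r.mean(axis=0) * r.shape[0] / (r.shape[0] - 1)
        drop, keep = (i, j) if mean_r[i] >= mean_r[j] else (j, i)
        report.append((S.columns[drop], S.columns[keep], float(r[i, j])))
        S = S.drop(columns=S.columns[drop])
    return S, report


# ----------------------------------------------------------------------
# normality
# ----------------------------------------------------------------------

def anderson_darling_p(x: np.ndarray) -> float:
    """Anderson-Darling test of normality with estimated mean/variance
    (case 3), p-value via the D'Agostino-Stephens approximation."""
    from statsmodels.stats.diagnostic import normal_ad

    stat, p = normal_ad(np.asarray(x, dtype=float))
    return float(p)


def royston_test(S: pd.DataFrame) -> tuple[float, float]:
    """Royston's (1992) multivariate extension of Shapiro-Wilk.

    Each variable's W statistic is normalised to a z-score (the
    Shapiro-Wilk p already embeds Royston's AS R94 transformation);
    z is folded to r = [Phi^-1(p/2)]^2 and the statistic
    H = e * mean(r) is referred to chi-square with the equivalent
    degrees of freedom e, which discounts for inter-variable
    correlation.
    """
    X = S.to_numpy(dtype=float)
    n, p = X.shape
    if n < 8:
        raise SoilGEAError("Royston's test needs at least 8 observations")
    r_j = np.empty(p)
    for j in range(p):
        w, pval = stats.shapiro(X[:, j])
        pval = min(max(pval, 1e-300), 1 - 1e-12)
        r_j[j] = stats.norm.ppf(pval / 2.0) ** 2
    # equivalent degrees of freedom (Royston 1992, as used by the MVN test)
    u = 0.715
    ln_n = np.log(n)
    v = 0.21364 + 0.015124 * ln_n**2 - 0.0018034 * ln_n**3
    lam = 5.0
    C = np.corrcoef(X, rowvar=False)
    if p == 1:
        e = 1.0
    else:
        iu = np.triu_indices(p, k=1)
        c = np.abs(C[iu])
        g = c**lam * (1 - (u * (1 - c) ** u) / v)
        cbar = 2 * g.sum() / (p * (p - 1))
        e = p / (1 + (p - 1) * cbar)
    H = e * r_j.mean()
    pval = float(stats.chi2.sf(H, df=e))
    return float(H), pval


def normality_tests(S: pd.DataFrame) -> EnvPrepReport:
    """Univariate AD per variable plus Royston's joint test (n >= 8)."""
    rep = EnvPrepReport()
    for v in S.columns:
        rep.ad_p[v] = anderson_darling_p(S[v].to_numpy())
    if len(S) >= 8:
        rep.royston_h, rep.royston_p = royston_test(S)
        rep.royston_computed = True
    else:
        rep.royston_computed = False
    rep.retained = list(S.columns)
    return rep


# ----------------------------------------------------------------------
# VIF
# ----------------------------------------------------------------------

def _vif_values(S: pd.DataFrame) -> pd.Series:
    X = (S - S.mean()) / S.std()
    out = {}
    for v in S.columns:
        y = X[v].to_numpy()
        Z = X.drop(columns=v).to_numpy()
        Z = np.column_stack([np.ones(len(Z)), Z])
        beta, res, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(y @ y)
        r2 = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
        out[v] = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_screen(S: pd.DataFrame, vif_max: float = 3.0):
    """Drop the largest-VIF variable until all VIF < vif_max."""
    if S.shape[1] < 2:
        return S.copy(), _vif_values_single(S)
    if len(S) <= S.shape[1]:
        raise SoilGEAError("need more sites than variables for VIF screening")
    S = S.copy()
    while S.shape[1] >= 2:
        vif = _vif_values(S)
        worst = vif.idxmax()
        if np.isfinite(vif[worst]) and vif[worst] < vif_max:
            break
        S = S.drop(columns=worst)
    final = _vif_values(S) if S.shape[1] >= 2 else pd.Series({S.columns[0]: 1.0})
    return S, final


def _vif_values_single(S: pd.DataFrame) -> pd.Series:
    return pd.Series({c: 1.0 for c in S.columns})


# ----------------------------------------------------------------------
# environmental PCA
# ----------------------------------------------------------------------

@dataclass
class EnvPCA:
    scores: pd.DataFrame    # sites x EPC axes
    loadings: pd.DataFrame  # variables x axes
    pve: np.ndarray


def env_pca(S: pd.DataFrame, n_axes: int | None = None) -> EnvPCA:
    """Z-score standardisation followed by PCA; exposes EPC1, EPC2, ..."""
    sd = S.std(ddof=1)
    if (sd == 0).any():
        bad = list(S.columns[sd == 0])
        raise SoilGEAError(f"constant variables cannot be standardised: {bad}")
    Z = ((S - S.mean()) / sd).to_numpy()
    n = Z.shape[0]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = s**2 / (n - 1)
    k = min(n_axes or len(eig), len(eig))
    cols = [f"EPC{i+1}" for i in range(k)]
    return EnvPCA(
        scores=pd.DataFrame(U[:, :k] * s[:k], index=S.index, columns=cols),
        loadings=pd.DataFrame(Vt[:k].T, index=S.columns, columns=cols),
        pve=eig[:k] / eig.sum(),
    )


def prepare_predictors(S: pd.DataFrame, r_max: float = 0.75, vif_max: float = 3.0):
    """Correlation pruning then VIF screening; full report returned."""
    pruned, dropped = prune_correlated(S, r_max=r_max)
    rep = normality_tests(pruned)
    rep.dropped_by_correlation = [
        (str(a), None if b is None else str(b), r) for a, b, r in dropped
    ]
    retained, vif = vif_screen(pruned, vif_max=vif_max)
    rep.vif = {str(k): float(v) for k, v in vif.items()}
    rep.retained = list(retained.columns)
    return retained, rep
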