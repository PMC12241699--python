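"""Genotype-environment association detectors.

Three conceptually different scans are provided, mirroring the standard
landscape-genomics trio:

* :func:`latent_factor_gea` — a deterministic latent-factor association
  model (the least-squares analogue of an LFMM): population structure
  is absorbed by the top-K left singular vectors of the genotype matrix
  after projecting off the environmental covariate, and each locus is
  tested by OLS of dosage on [variable, factors], with genomic-control
  calibration and Benjamini-Hochberg FDR.
* :func:`logistic_gea` — logistic regression of minor-allele presence
  on the soil variable with admixture covariates, tested by the
  likelihood-ratio G-score against chi-square(1) and a Bonferroni
  family over all locus x variable tests.
* :func:`fstenv_gea` — a permutation test asking whether a locus's
  population-differentiation profile tracks the environmental distance
  of each population from the range average (the distance-based,
  FST-outlier flavour of GEA), with Storey q-values.

Candidates from any subset of methods are merged by
:func:`combine_candidates` with per-method membership retained for
Venn-style reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, SoilGEAError

#: chi-square(1) median, the genomic-control denominator
CHI2_1_MEDIAN = 0.45494


# ----------------------------------------------------------------------
# calibration / multiple testing
# ----------------------------------------------------------------------

def genomic_inflation_factor(z: np.ndarray) -> float:
    z = np.asarray(z, dtype=float)
    return float(np.median(z**2) / CHI2_1_MEDIAN)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def storey_qvalues(p: np.ndarray, lambda_storey: float = 0.5) -> np.ndarray:
    """Storey q-values with pi0 estimated at a single lambda."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    pi0 = min(1.0, float((p > lambda_storey).mean()) / (1.0 - lambda_storey))
    pi0 = max(pi0, 1.0 / m)  # avoid a degenerate zero
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, pi0 * p[idx] * m / rank)
        q[idx] = running
    return q


def calibrate_and_adjust(
    z_scores: np.ndarray | None = None,
    p_values: np.ndarray | None = None,
    scheme: str = "gif+bh",
    alpha: float = 0.05,
) -> dict:
    """Genomic-control calibration plus a multiple-testing correction.

    With z-scores, lambda = median(z^2)/0.45494 and calibrated p come
    from the upper tail of chi-square(1) applied to z^2/lambda.  With
    raw p-values, calibration is skipped.  ``scheme`` selects the
    adjustment: 'gif+bh' (BH step-up), 'bonferroni' (threshold
    alpha/m), or 'storey' (q-values, pi0 at lambda=0.5).
    """
    if scheme not in {"gif+bh", "bonferroni", "storey"}:
        raise ValueError(f"unknown scheme {scheme!r}")
    if z_scores is not None:
        z = np.asarray(z_scores, dtype=float)
        if z.size == 0:
            raise SoilGEAError("empty input")
        lam = genomic_inflation_factor(z)
        p_cal = stats.chi2.sf(z**2 / lam, df=1)
    elif p_values is not None:
        p_cal = np.asarray(p_values, dtype=float)
        if p_cal.size == 0:
            raise SoilGEAError("empty input")
        lam = None
    else:
        raise SoilGEAError("provide z_scores or p_values")
    p_cal = np.clip(p_cal, 1e-300, 1.0)
    m = len(p_cal)
    out = {"lambda_gif": lam, "p_calibrated": p_cal, "alpha": alpha, "m": m}
    if scheme == "gif+bh":
        adj = bh_adjust(p_cal)
        out.update(adjusted=adj, flagged=adj <= alpha)
    elif scheme == "bonferroni":
        thr = alpha / m
        out.update(adjusted=np.clip(p_cal * m, 0, 1), threshold=thr, flagged=p_cal <= thr)
    else:
        q = storey_qvalues(p_cal)
        out.update(adjusted=q, flagged=q <= alpha)
    return out


# ----------------------------------------------------------------------
# result containers
# ----------------------------------------------------------------------

@dataclass
class AssociationResult:
    """Per (locus, variable) association statistics for one method."""

    method: str
    table: pd.DataFrame  # locus, variable, effect, z, p_raw, p_cal, adj, flagged
    lambda_gif: dict = field(default_factory=dict)  # variable -> lambda
    scale: str | None = None

    def flagged(self) -> pd.DataFrame:
        return self.table[self.table["flagged"]]

    def to_tsv(self, path: str) -> str:
        self.table.to_csv(path, sep="\t", index=False)
        return path


@dataclass
class CandidateSet:
    """Union of loci flagged by >= 1 method, with per-method provenance."""

    entries: pd.DataFrame      # locus, variable, methods (comma-joined)
    method_counts: dict
    venn_counts: dict          # frozenset label -> count
    scale: str | None = None

    @property
    def loci(self) -> list:
        return list(pd.unique(self.entries["locus"]))

    def to_tsv(self, path: str) -> str:
        self.entries.to_csv(path, sep="\t", index=False)
        return path


# ----------------------------------------------------------------------
# latent-factor detector
# ----------------------------------------------------------------------

def _ols_scan(Y: np.ndarray, X: np.ndarray, ridge: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-column OLS of Y on X; returns (beta_x, z) for X's first column."""
    n, p = X.shape
    XtX = X.T @ X + ridge * np.eye(p)
    XtY = X.T @ Y
    beta = np.linalg.solve(XtX, XtY)              # p x L
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.linalg.inv(XtX)[0, 0] * sigma2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, beta[0] / se, 0.0)
    return beta[0], z


def latent_factor_gea(
    G: GenotypeMatrix,
    S_by_sample: pd.DataFrame,
    K_latent: int,
    ridge: float = 1e-5,
    alpha: float = 0.05,
    scale: str | None = None,
) -> AssociationResult:
    """Deterministic latent-factor association scan.

    The latent factors U are the top ``K_latent`` left singular vectors
    of the centred dosage matrix, estimated once and shared across
    variables; per locus an OLS of dosage on [variable, U, 1] yields a
    z-score for the variable coefficient (``ridge`` stabilises the
    normal equations).  Estimating the factors from the raw matrix
    rather than a covariate-residualised one keeps the null z-scores
    calibrated (a covariate-residualised factor basis misses exactly
    the structure component aligned with the covariate and inflates
    lambda); residual confounding is handled by the genomic-control
    step.  z-scores are calibrated and BH-adjusted at ``alpha``.
    """
    if G.missing_mask.any():
        raise SoilGEAError("latent_factor_gea requires a complete matrix")
    n = G.n_samples
    if K_latent >= n:
        raise SoilGEAError("K_latent must be smaller than the number of samples")
    Y = G.dosage.astype(float)
    Y = Y - Y.mean(axis=0)
    if K_latent > 0:
        U, _, _ = np.linalg.svd(Y, full_matrices=False)
        Ufac = U[:, :K_latent]
    frames, lambdas = [], {}
    for var in S_by_sample.columns:
        x = S_by_sample[var].to_numpy(dtype=float)
        if np.std(x) == 0:
            raise SoilGEAError(f"soil variable {var!r} is constant")
        x = (x - x.mean()) / x.std()
        if K_latent > 0:
            X = np.column_stack([x, Ufac, np.ones(n)])
        else:
            X = np.column_stack([x, np.ones(n)])
        effect, z = _ols_scan(Y, X, ridge=ridge)
        cal = calibrate_and_adjust(z_scores=z, scheme="gif+bh", alpha=alpha)
        lambdas[var] = cal["lambda_gif"]
        frames.append(
            pd.DataFrame(
                {
                    "locus": G.locus_ids,
                    "variable": var,
                    "effect": effect,
                    "z": z,
                    "p_raw": stats.chi2.sf(z**2, df=1),
                    "p_cal": cal["p_calibrated"],
                    "adj": cal["adjusted"],
                    "flagged": cal["flagged"],
                }
            )
        )
    return AssociationResult("latent_factor", pd.concat(frames, ignore_index=True), lambdas, scale)


# ----------------------------------------------------------------------
# logistic detector
# ----------------------------------------------------------------------

def _batched_logistic_loglik(Y: np.ndarray, X: np.ndarray, ridge: float = 1e-6,
                             max_iter: int = 50, tol: float = 1e-8):
    """Fit logistic models for every response column by batched Newton
    iterations; returns (loglik per column, separation flag)."""
    n, p = X.shape
    L = Y.shape[1]
    beta = np.zeros((L, p))
    eye = ridge * np.eye(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta.T, -30, 30)         # n x L
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu) + 1e-10
        grad = X.T @ (Y - mu)                       # p x L
        H = np.einsum("np,nl,nq->lpq", X, W, X) + eye
        step = np.linalg.solve(H, grad.T[:, :, None])[:, :, 0]
        beta += step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(X @ beta.T, -30, 30)
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    ll = (Y * np.log(mu) + (1 - Y) * np.log(1 - mu)).sum(axis=0)
    sep = np.abs(X @ beta.T).max(axis=0) >= 29.0
    return ll, beta, sep


def logistic_gea(
    G: GenotypeMatrix,
    S_by_sample: pd.DataFrame,
    structure_covariates: np.ndarray | None = None,
    alpha: float = 0.05,
    ridge: float = 1e-6,
    scale: str | None = None,
) -> AssociationResult:
    """Logistic-regression G-score scan of minor-allele presence.

    Response per locus is presence of the minor allele (dosage > 0 for
    the minor encoding); nested models with and without the soil
    variable (both holding K-1 admixture covariates) are compared by
    G = 2(l1 - l0) ~ chi-square(1).  The Bonferroni family is all
    locus x variable tests.  Quasi-separated fits are flagged and kept
    (the small ridge keeps them finite).
    """
    if G.missing_mask.any():
        raise SoilGEAError("logistic_gea requires a complete matrix")
    n = G.n_samples
    freq = G.allele_freq()
    # encode "presence of the minor allele"
    d = G.dosage.astype(float)
    minor_presence = np.where(freq[None, :] <= 0.5, d > 0, d < 2).astype(float)

    Z = np.ones((n, 1))
    if structure_covariates is not None and np.size(structure_covariates):
        Q = np.asarray(structure_covariates, dtype=float)
        if Q.ndim == 1:
            Q = Q[:, None]
        Z = np.column_stack([np.ones(n), Q])
    frames = []
    m_family = G.n_loci * S_by_sample.shape[1]
    for var in S_by_sample.columns:
        x = S_by_sample[var].to_numpy(dtype=float)
        if np.std(x) == 0:
            g = np.zeros(G.n_loci)
            p_raw = np.ones(G.n_loci)
            eff = np.zeros(G.n_loci)
            sep = np.zeros(G.n_loci, bool)
        else:
            xz = (x - x.mean()) / x.std()
            X1 = np.column_stack([Z, xz])
            ll0, _, sep0 = _batched_logistic_loglik(minor_presence, Z, ridge)
            ll1, beta1, sep1 = _batched_logistic_loglik(minor_presence, X1, ridge)
            g = np.maximum(2.0 * (ll1 - ll0), 0.0)
            p_raw = stats.chi2.sf(g, df=1)
            eff = beta1[:, -1]
            sep = sep0 | sep1
        bon = np.clip(p_raw * m_family, 0, 1)
        frames.append(
            pd.DataFrame(
                {
                    "locus": G.locus_ids,
                    "variable": var,
                    "effect": eff,
                    "z": np.sqrt(g),
                    "p_raw": p_raw,
                    "p_cal": p_raw,
                    "adj": bon,
                    "flagged": p_raw <= alpha / m_family,
                    "separation": sep,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    return AssociationResult("logistic", table, {}, scale)


# ----------------------------------------------------------------------
# FST-environment detector
# ----------------------------------------------------------------------

def environmental_distance(values: np.ndarray, signed: bool = False) -> np.ndarray:
    """Per-population environmental distance from the range average,
    normalised to max 1 (absolute by default)."""
    x = np.asarray(values, dtype=float)
    dev = x - x.mean()
    if not signed:
        dev = np.abs(dev)
    denom = np.max(np.abs(dev))
    if denom == 0:
        raise SoilGEAError("variable has zero spread; environmental distances undefined")
    return dev / denom


def fstenv_gea(
    G: GenotypeMatrix,
    meta: pd.DataFrame,
    S: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    signed: bool = False,
    scale: str | None = None,
) -> AssociationResult:
    """Permutation test of locus differentiation against environmental
    distance.

    Per locus i and population j, the differentiation contribution is
    t_ij = (p_ij - pbar_i)^2 / (pbar_i (1 - pbar_i)); the statistic is
    the Pearson correlation of (t_i., d.) where d is the normalised
    environmental distance.  The null distribution comes from
    ``n_perm`` permutations of d across populations (the same
    permutations shared by all loci); p is one-sided (upper) with +1
    smoothing; Storey q-values flag candidates at ``alpha``.
    """
    pops_all = meta.set_index("sample_id").loc[G.sample_ids, "population"].to_numpy()
    pops = list(pd.unique(pops_all))
    if len(pops) < 4:
        raise SoilGEAError("need at least 4 populations")
    d = G.dosage_float()
    # population allele frequencies (ignoring missing)
    P = np.vstack([
        np.nanmean(d[pops_all == p], axis=0) / 2.0 for p in pops
    ])
    pbar = np.nanmean(P, axis=0)
    ok = (pbar > 0) & (pbar < 1) & np.isfinite(pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        T = (P - pbar[None, :]) ** 2 / (pbar * (1 - pbar))[None, :]
    T[:, ~ok] = 0.0  # degenerate loci carry no signal; excluded via `usable`
    rng = np.random.default_rng(seed)
    n_pop = len(pops)
    perms = np.vstack([rng.permutation(n_pop) for _ in range(n_perm)])

    frames = []
    for var in S.columns:
        dist = environmental_distance(S.loc[pops, var].to_numpy(), signed=signed)
        dz = dist - dist.mean()
        denom_d = np.sqrt((dz**2).sum())
        if denom_d == 0:
            # distances identical across populations: correlation undefined,
            # every locus skipped, zero candidates for this variable
            frames.append(
                pd.DataFrame(
                    {
                        "locus": G.locus_ids,
                        "variable": var,
                        "effect": np.nan,
                        "z": np.nan,
                        "p_raw": np.nan,
                        "p_cal": np.nan,
                        "adj": np.nan,
                        "flagged": False,
                        "skipped": True,
                    }
                )
            )
            continue
        Tz = T - np.nanmean(T, axis=0)[None, :]
        denom_t = np.sqrt(np.nansum(Tz**2, axis=0))
        usable = ok & (denom_t > 0)
        denom_safe = np.where(denom_t > 0, denom_t, 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            s_obs = np.nansum(Tz * dz[:, None], axis=0) / (denom_safe * denom_d)
        # shared permutations: correlations for permuted d, all loci at once
        dz_perm = dz[perms]                               # n_perm x n_pop
        S_perm = (dz_perm @ np.nan_to_num(Tz)) / (denom_safe[None, :] * denom_d)
        exceed = (S_perm >= s_obs[None, :]).sum(axis=0)
        p_raw = (exceed + 1) / (n_perm + 1)
        p_use = p_raw[usable]
        q = np.full(G.n_loci, np.nan)
        if p_use.size:
            q[usable] = storey_qvalues(p_use)
        frames.append(
            pd.DataFrame(
                {
                    "locus": G.locus_ids,
                    "variable": var,
                    "effect": s_obs,
                    "z": np.where(usable, stats.norm.isf(np.clip(p_raw, 1e-15, 1 - 1e-15)), np.nan),
                    "p_raw": np.where(usable, p_raw, np.nan),
                    "p_cal": np.where(usable, p_raw, np.nan),
                    "adj": q,
                    "flagged": np.where(usable, q <= alpha, False),
                    "skipped": ~usable,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table["flagged"] = table["flagged"].fillna(False).astype(bool)
    return AssociationResult("fst_env", table, {}, scale)


# ----------------------------------------------------------------------
# candidate combination
# ----------------------------------------------------------------------

def combine_candidates(results: list[AssociationResult]) -> CandidateSet:
    """Union of flagged (locus, variable) pairs over methods, with
    per-method membership and Venn intersection counts."""
    if not results:
        raise SoilGEAError("no association results supplied")
    scales = {r.scale for r in results}
    if len(scales) > 1:
        raise SoilGEAError(f"mixed-scale inputs: {scales}")
    membership: dict[tuple, set] = {}
    for res in results:
        for _, row in res.flagged().iterrows():
            membership.setdefault((row["locus"], row["variable"]), set()).add(res.method)
    rows = [
        {"locus": loc, "variable": var, "methods": ",".join(sorted(meths))}
        for (loc, var), meths in sorted(membership.items())
    ]
    entries = pd.DataFrame(rows, columns=["locus", "variable", "methods"])
    methods = [r.method for r in results]
    method_counts = {
        m: int(sum(1 for meths in membership.values() if m in meths)) for m in methods
    }
    venn = {}
    for k in range(1, len(methods) + 1):
        for combo in combinations(sorted(set(methods)), k):
            venn["&".join(combo)] = int(
                sum(1 for meths in membership.values() if set(combo) <= meths)
            )
    return CandidateSet(entries, method_counts, venn, scale=next(iter(scales)))
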