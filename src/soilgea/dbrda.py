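"""Distance-based redundancy analysis (dbRDA) and the polygenic-model
machinery built on it: forward selection of soil predictors,
MAF-matched null locus ensembles, and cross-scale candidate transfer.

The partition follows McArdle & Anderson (2001): the dissimilarity
matrix D is Gower-centred to G = -1/2 C D^2 C; conditioning covariates
claim tr(Hz G Hz); predictors residualised on the conditioners claim
the constrained inertia tr(Hx|z G Hx|z); the residual is the remainder,
so total = conditional + constrained + residual holds by construction
and negative eigenvalues of G stay inside the traces (no Lingoes or
Cailliez correction).  Significance comes from permuting the
reduced-model residual structure of G.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import GenotypeMatrix, SoilGEAError
from .gea import CandidateSet


# ----------------------------------------------------------------------
# distances
# ----------------------------------------------------------------------

def bray_curtis(G_subset: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Bray-Curtis dissimilarity on dosage rows.

    BC(i,j) = sum|g_i - g_j| / sum(g_i + g_j); an all-zero pair is 0 by
    convention.
    """
    X = G_subset.dosage.astype(float) if isinstance(G_subset, GenotypeMatrix) else np.asarray(G_subset, float)
    if isinstance(G_subset, GenotypeMatrix) and G_subset.missing_mask.any():
        raise SoilGEAError("bray_curtis requires a complete matrix")
    if (X < 0).any():
        raise ValueError("negative dosages are not valid abundances")
    if X.shape[0] < 2:
        raise SoilGEAError("need at least two samples")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        D = squareform(pdist(X, metric="braycurtis"))
    D[~np.isfinite(D)] = 0.0  # all-zero pairs
    return D


# ----------------------------------------------------------------------
# model / results
# ----------------------------------------------------------------------

def _hat(X: np.ndarray) -> np.ndarray:
    """Orthogonal-projection (hat) matrix onto the column space of X."""
    Q, R = np.linalg.qr(X)
    rank = int((np.abs(np.diag(R)) > 1e-10 * max(1.0, np.abs(R).max())).sum())
    Q = Q[:, :rank]
    return Q @ Q.T


def ezekiel_adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel's adjusted R^2: 1 - (1 - R^2)(n - 1)/(n - m - 1)."""
    if n - m - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


@dataclass
class DbRDAResults:
    inertia: dict                 # total/conditional/constrained/residual
    proportions: dict
    r2: float
    r2_adj: float
    eigenvalues: np.ndarray       # constrained-axis eigenvalues (desc.)
    axis_scores: np.ndarray | None  # samples x constrained axes (biplots)
    axis_p: np.ndarray | None
    marginal_p: dict | None       # predictor -> p
    pseudo_f: float
    p_value: float | None
    n_perm: int
    seed: int
    n: int
    predictor_names: list = field(default_factory=list)
    conditioner_names: list = field(default_factory=list)
    selected: list | None = None

    def summary(self) -> str:
        lines = [
            "Distance-based redundancy analysis",
            f"  n = {self.n}; predictors: {', '.join(self.predictor_names) or '(none)'}",
            f"  conditioners: {', '.join(self.conditioner_names) or '(none)'}",
            "  Inertia partition:",
        ]
        for k in ("total", "conditional", "constrained", "residual"):
            lines.append(
                f"    {k:<12s} {self.inertia[k]:10.4f}  ({100 * self.proportions[k]:6.2f}%)"
            )
        lines.append(f"  R2 = {self.r2:.4f}   R2_adj (Ezekiel) = {self.r2_adj:.4f}")
        if self.p_value is not None:
            lines.append(
                f"  pseudo-F = {self.pseudo_f:.3f}, permutation p = {self.p_value:.4f} "
                f"({self.n_perm} permutations)"
            )
        return "\n".join(lines)

    def to_json(self, path: str) -> str:
        payload = {
            "inertia": self.inertia,
            "proportions": self.proportions,
            "r2": self.r2,
            "r2_adj": self.r2_adj,
            "eigenvalues": list(map(float, self.eigenvalues)),
            "axis_p": None if self.axis_p is None else list(map(float, self.axis_p)),
            "marginal_p": self.marginal_p,
            "pseudo_f": self.pseudo_f,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "n": self.n,
            "predictors": self.predictor_names,
            "conditioners": self.conditioner_names,
            "selected": self.selected,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return path


class DBRDA:
    """dbRDA model of a dissimilarity matrix on predictors, optionally
    conditioned on covariates (partial dbRDA).

    Parameters
    ----------
    D : (n, n) dissimilarity matrix
    predictors : DataFrame or array, one row per sample
    conditioners : optional DataFrame or array, one row per sample
    """

    def __init__(self, D, predictors, conditioners=None):
        D = np.asarray(D, dtype=float)
        if D.ndim != 2 or D.shape[0] != D.shape[1]:
            raise SoilGEAError("D must be a square dissimilarity matrix")
        if not np.allclose(D, D.T, atol=1e-10):
            raise SoilGEAError("D must be symmetric")
        self.D = D
        self.n = D.shape[0]
        self.X, self.predictor_names = self._as_matrix(predictors, "x")
        if conditioners is None or (hasattr(conditioners, "shape") and np.size(conditioners) == 0):
            self.Z, self.conditioner_names = None, []
        else:
            self.Z, self.conditioner_names = self._as_matrix(conditioners, "z")
        # Gower-centred inner-product matrix
        C = np.eye(self.n) - np.ones((self.n, self.n)) / self.n
        self.G = -0.5 * C @ (D**2) @ C

    @staticmethod
    def _as_matrix(M, prefix):
        if isinstance(M, pd.DataFrame):
            return M.to_numpy(dtype=float), list(map(str, M.columns))
        M = np.asarray(M, dtype=float)
        if M.ndim == 1:
            M = M[:, None]
        return M, [f"{prefix}{i + 1}" for i in range(M.shape[1])]

    # ------------------------------------------------------------------
    def _projections(self):
        n = self.n
        ones = np.ones((n, 1))
        if self.Z is not None:
            Zc = np.column_stack([ones, self.Z - self.Z.mean(axis=0)])
            Hz = _hat(Zc)
        else:
            Hz = _hat(ones)
        Xc = self.X - self.X.mean(axis=0)
        Xr = Xc - Hz @ Xc               # predictors residualised on conditioners
        Hx = _hat(Xr) if np.linalg.norm(Xr) > 1e-12 else np.zeros((n, n))
        return Hz, Hx

    def fit(self, n_perm: int = 999, seed: int = 0, marginal: bool = False) -> DbRDAResults:
        Hz, Hx = self._projections()
        G = self.G
        n = self.n
        total = float(np.trace(G))
        # conditional inertia beyond the intercept
        H1 = _hat(np.ones((n, 1)))
        conditional = float(np.trace(Hz @ G @ Hz) - np.trace(H1 @ G @ H1))
        Gr = (np.eye(n) - Hz) @ G @ (np.eye(n) - Hz)    # reduced-model residual
        constrained = float(np.trace(Hx @ Gr @ Hx))
        residual = total - conditional - constrained
        qx = int(round(np.trace(Hx)))
        qz = int(round(np.trace(Hz))) - 1
        dof_res = n - 1 - qz - qx
        r2 = constrained / (total - conditional) if total - conditional > 0 else 0.0
        r2_adj = ezekiel_adjusted_r2(r2, n - qz, qx)

        # constrained-axis eigenvalues and sample (ordination) scores
        M = (lambda A: (A + A.T) / 2)(Hx @ Gr @ Hx)
        eigval, eigvec = np.linalg.eigh(M)
        eigval, eigvec = eigval[::-1], eigvec[:, ::-1]
        eig = eigval[: max(qx, 1)]
        k_pos = int((eig > 1e-12).sum())
        axis_scores = eigvec[:, :k_pos] * np.sqrt(eig[:k_pos])[None, :] if k_pos else None

        pseudo_f = np.nan
        p_value = None
        if qx > 0 and dof_res > 0:
            pseudo_f = (constrained / qx) / max(residual / dof_res, 1e-300)
        if n_perm and qx > 0:
            rng = np.random.default_rng(seed)
            exceed = 0
            for _ in range(n_perm):
                perm = rng.permutation(n)
                Gp = Gr[np.ix_(perm, perm)]
                cons_p = float(np.trace(Hx @ Gp @ Hx))
                res_p = float(np.trace(Gp)) - cons_p
                f_p = (cons_p / qx) / max(res_p / dof_res, 1e-300)
                if f_p >= pseudo_f:
                    exceed += 1
            p_value = (exceed + 1) / (n_perm + 1)

        marginal_p = None
        if marginal and self.X.shape[1] > 1 and n_perm:
            marginal_p = {}
            for j, name in enumerate(self.predictor_names):
                others = np.delete(self.X, j, axis=1)
                cond = others if self.Z is None else np.column_stack([self.Z, others])
                sub = DBRDA(self.D, self.X[:, [j]], cond)
                res = sub.fit(n_perm=n_perm, seed=seed + 7 * (j + 1))
                marginal_p[name] = res.p_value

        proportions = {
            "total": 1.0,
            "conditional": conditional / total if total else 0.0,
            "constrained": constrained / total if total else 0.0,
            "residual": residual / total if total else 0.0,
        }
        return DbRDAResults(
            inertia={
                "total": total,
                "conditional": conditional,
                "constrained": constrained,
                "residual": residual,
            },
            proportions=proportions,
            r2=r2,
            r2_adj=r2_adj,
            eigenvalues=eig,
            axis_scores=axis_scores,
            axis_p=None,
            marginal_p=marginal_p,
            pseudo_f=float(pseudo_f),
            p_value=p_value,
            n_perm=n_perm,
            seed=seed,
            n=n,
            predictor_names=self.predictor_names,
            conditioner_names=self.conditioner_names,
        )


def dbrda(D, predictors, conditioners=None, n_perm: int = 999, seed: int = 0,
          marginal: bool = False) -> DbRDAResults:
    """Functional wrapper over :class:`DBRDA`."""
    return DBRDA(D, predictors, conditioners).fit(n_perm=n_perm, seed=seed, marginal=marginal)


# ----------------------------------------------------------------------
# forward selection
# ----------------------------------------------------------------------

def forward_select(
    D,
    predictor_pool: pd.DataFrame,
    conditioners=None,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
):
    """Forward selection of predictors for a dbRDA.

    At each step the predictor giving the largest increase in Ezekiel
    adjusted R^2 is admitted if (a) its marginal permutation p <= alpha
    and (b) the cumulative adjusted R^2 does not exceed the
    all-predictor (global) adjusted R^2 — the standard double stopping
    rule.  Returns (ordered selected names, stop reason, final result).
    """
    if predictor_pool.shape[1] == 0:
        raise SoilGEAError("empty predictor pool")
    global_r2adj = DBRDA(D, predictor_pool, conditioners).fit(n_perm=0).r2_adj
    selected: list[str] = []
    current_r2adj = -np.inf
    stop = "pool exhausted"
    while True:
        remaining = [c for c in predictor_pool.columns if c not in selected]
        if not remaining:
            stop = "pool exhausted"
            break
        best = None
        for cand in remaining:
            cols = selected + [cand]
            res = DBRDA(D, predictor_pool[cols], conditioners).fit(n_perm=0)
            if best is None or res.r2_adj > best[1]:
                best = (cand, res.r2_adj)
        cand, cand_r2adj = best
        if cand_r2adj <= current_r2adj:
            stop = "no adjusted-R2 improvement"
            break
        if cand_r2adj > global_r2adj + 1e-12:
            stop = "global adjusted-R2 cap"
            break
        # marginal significance of the candidate given current terms
        cond = (
            None
            if conditioners is None and not selected
            else (
                predictor_pool[selected]
                if conditioners is None
                else np.column_stack(
                    [np.asarray(conditioners, float).reshape(len(predictor_pool), -1)]
                    + ([predictor_pool[selected].to_numpy()] if selected else [])
                )
            )
        )
        res = DBRDA(D, predictor_pool[[cand]], cond).fit(n_perm=n_perm, seed=seed + len(selected))
        if res.p_value is None or res.p_value > alpha:
            stop = "no significant predictor remains"
            break
        selected.append(cand)
        current_r2adj = cand_r2adj
    final = (
        DBRDA(D, predictor_pool[selected], conditioners).fit(n_perm=n_perm, seed=seed)
        if selected
        else None
    )
    if final is not None:
        final.selected = list(selected)
    return selected, stop, final


# ----------------------------------------------------------------------
# MAF-matched null ensembles
# ----------------------------------------------------------------------

@dataclass
class NullEnsemble:
    n_sets: int
    candidate_result: DbRDAResults
    null_results: list
    null_loci: list                    # list of lists of locus ids
    matching_report: dict              # bin label -> candidate count
    exceedance_rank: int               # 1 = candidate above every null
    candidate_loci: list = field(default_factory=list)

    @property
    def null_constrained(self) -> np.ndarray:
        return np.array([r.proportions["constrained"] for r in self.null_results])

    def to_json(self, path: str) -> str:
        payload = {
            "n_sets": self.n_sets,
            "candidate_constrained": self.candidate_result.proportions["constrained"],
            "null_constrained": list(map(float, self.null_constrained)),
            "matching_report": self.matching_report,
            "exceedance_rank": self.exceedance_rank,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
        return path


def matched_null_ensemble(
    G: GenotypeMatrix,
    candidates: CandidateSet | list,
    predictors: pd.DataFrame,
    conditioners=None,
    n_sets: int = 20,
    maf_bin: float = 0.05,
    n_perm: int = 999,
    seed: int = 0,
    null_n_perm: int = 0,
) -> NullEnsemble:
    """dbRDA of the candidate panel against ``n_sets`` random
    non-candidate panels matched to the candidates' number and MAF.

    Candidate MAFs are binned at width ``maf_bin``; each null set
    samples non-candidate loci (without replacement within a set)
    matching the per-bin counts.  A bin lacking enough non-candidates
    is widened by one bin step on each side (with a warning); if still
    short the ensemble fails.  The exceedance rank places the candidate
    constrained proportion inside {candidate} u nulls, rank 1 meaning
    the candidate panel beats every null set.
    """
    cand_loci = candidates.loci if isinstance(candidates, CandidateSet) else list(candidates)
    cand_loci = [l for l in dict.fromkeys(cand_loci)]
    pos = {l: i for i, l in enumerate(G.locus_ids)}
    missing = [l for l in cand_loci if l not in pos]
    if missing:
        raise SoilGEAError(f"candidate loci absent from panel: {missing[:5]}")
    freq = G.allele_freq()
    maf = np.minimum(freq, 1 - freq)
    cand_idx = np.array([pos[l] for l in cand_loci])
    non_cand = np.setdiff1d(np.arange(G.n_loci), cand_idx)
    bins_all = (maf / maf_bin).astype(int)
    cand_bins = bins_all[cand_idx]
    bin_counts = pd.Series(cand_bins).value_counts().to_dict()

    rng = np.random.default_rng(seed)
    null_sets = []
    for _ in range(n_sets):
        chosen = []
        for b, count in sorted(bin_counts.items()):
            pool = non_cand[bins_all[non_cand] == b]
            if len(pool) < count:
                warnings.warn(f"MAF bin {b * maf_bin:.2f} short of non-candidates; widening")
                pool = non_cand[np.abs(bins_all[non_cand] - b) <= 1]
            pool = np.setdiff1d(pool, np.array(chosen, dtype=int))
            if len(pool) < count:
                raise SoilGEAError(
                    f"not enough non-candidate loci in MAF bin {b * maf_bin:.2f} even after widening"
                )
            chosen.extend(rng.choice(pool, size=count, replace=False).tolist())
        null_sets.append(np.array(chosen))

    cand_D = bray_curtis(G.subset_loci(cand_idx))
    cand_res = DBRDA(cand_D, predictors, conditioners).fit(n_perm=n_perm, seed=seed)
    null_results = []
    for k, idxs in enumerate(null_sets):
        Dk = bray_curtis(G.subset_loci(idxs))
        null_results.append(
            DBRDA(Dk, predictors, conditioners).fit(n_perm=null_n_perm, seed=seed + k + 1)
        )
    null_prop = np.array([r.proportions["constrained"] for r in null_results])
    rank = 1 + int((null_prop >= cand_res.proportions["constrained"]).sum())
    return NullEnsemble(
        n_sets=n_sets,
        candidate_result=cand_res,
        null_results=null_results,
        null_loci=[[G.locus_ids[i] for i in idxs] for idxs in null_sets],
        matching_report={f"{b * maf_bin:.2f}": int(c) for b, c in sorted(bin_counts.items())},
        exceedance_rank=rank,
        candidate_loci=cand_loci,
    )


def cross_scale_transfer(
    candidates_other_scale: CandidateSet | list,
    G_this_scale: GenotypeMatrix,
    predictors: pd.DataFrame,
    conditioners=None,
    n_perm: int = 999,
    seed: int = 0,
    same_scale_result: DbRDAResults | None = None,
    null_ensemble: NullEnsemble | None = None,
):
    """dbRDA of this scale's genotypes restricted to the other scale's
    candidate loci, with a comparison record against the same-scale
    candidate model and the null ensemble."""
    loci = (
        candidates_other_scale.loci
        if isinstance(candidates_other_scale, CandidateSet)
        else list(candidates_other_scale)
    )
    present = [l for l in dict.fromkeys(loci) if l in set(G_this_scale.locus_ids)]
    dropped = len(set(loci)) - len(present)
    if not present:
        raise SoilGEAError("no transferable loci found in this scale's panel")
    D = bray_curtis(G_this_scale.subset_loci(np.asarray(present, dtype=object)))
    res = DBRDA(D, predictors, conditioners).fit(n_perm=n_perm, seed=seed)
    comparison = {
        "n_transferred": len(present),
        "n_dropped": dropped,
        "transferred_constrained": res.proportions["constrained"],
        "transferred_p": res.p_value,
    }
    if same_scale_result is not None:
        comparison["same_scale_constrained"] = same_scale_result.proportions["constrained"]
        comparison["same_scale_p"] = same_scale_result.p_value
    if null_ensemble is not None:
        nulls = null_ensemble.null_constrained
        comparison["null_min"] = float(nulls.min())
        comparison["null_max"] = float(nulls.max())
        comparison["within_null_range"] = bool(res.proportions["constrained"] <= nulls.max())
    return res, comparison
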