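"""Population structure: Patterson-scaled PCA, admixture proportions via
an EM algorithm with cross-validated choice of K, DAPC-style cluster
search, and pairwise Weir-Cockerham FST with permutation p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .io import GenotypeMatrix, MISSING, SoilGEAError


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray        # samples x axes
    loadings: np.ndarray      # loci x axes
    eigenvalues: np.ndarray   # descending, >= 0
    pve: np.ndarray           # proportion of variance per axis
    sample_ids: list = field(default_factory=list)
    locus_ids: list = field(default_factory=list)


def genotype_pca(G: GenotypeMatrix, n_axes: int | None = None) -> PCAResult:
    """PCA of the dosage matrix under Patterson scaling.

    Columns are centred at 2p and scaled by sqrt(2p(1-p)); constant
    loci (which cannot be scaled) are dropped with a warning.
    """
    if G.missing_mask.any():
        raise SoilGEAError("genotype_pca requires a complete matrix; impute first")
    X = G.dosage.astype(float)
    p = X.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant loci before PCA")
    X = X[:, keep]
    p = p[keep]
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    n = Z.shape[0]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = s**2 / (n - 1)
    total = eig.sum()
    k = min(n_axes or len(eig), len(eig))
    return PCAResult(
        scores=U[:, :k] * s[:k],
        loadings=Vt[:k].T,
        eigenvalues=eig[:k],
        pve=eig[:k] / total,
        sample_ids=list(G.sample_ids),
        locus_ids=[l for l, m in zip(G.locus_ids, keep) if m],
    )


# ----------------------------------------------------------------------
# admixture (binomial EM)
# ----------------------------------------------------------------------

@dataclass
class AdmixtureResults:
    """Ancestry fractions Q, cluster allele frequencies F and the CV path."""

    K: int
    Q: np.ndarray            # samples x K, rows sum to 1
    F: np.ndarray            # K x loci in [0,1]
    loglik: float
    converged: bool
    cv_error: dict           # K -> mean masked-entry MSE
    chosen_K: int
    loglik_path: np.ndarray
    sample_ids: list = field(default_factory=list)

    def q_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.Q, index=self.sample_ids, columns=[f"Q{k+1}" for k in range(self.K)]
        )


def _admixture_em(dosage, K, rng, max_iter=300, tol=1e-6):
    """EM for the binomial admixture likelihood; monotone in loglik.

    ``dosage`` may contain missing entries (MISSING); they contribute
    nothing to the expected counts.
    """
    n, L = dosage.shape
    obs = dosage != MISSING
    g = np.where(obs, dosage, 0).astype(float)
    w1 = g * obs          # observed alt-allele copies
    w0 = (2 - g) * obs    # observed ref-allele copies
    nloci_obs = obs.sum(axis=1, keepdims=True).astype(float)

    Q = rng.dirichlet(np.ones(K), size=n)
    F = np.clip(rng.uniform(0.05, 0.95, size=(K, L)), 1e-6, 1 - 1e-6)
    path = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        P = Q @ F                       # n x L, P(alt allele)
        P = np.clip(P, 1e-12, 1 - 1e-12)
        ll = float(np.sum(w1 * np.log(P) + w0 * np.log(1 - P)))
        path.append(ll)
        if ll - prev < tol * max(1.0, abs(ll)) and len(path) > 2:
            converged = True
            break
        prev = ll
        # responsibilities: A[i,k,l] = Q_ik F_kl / P_il  (alt copies)
        #                   B[i,k,l] = Q_ik (1-F_kl) / (1-P_il)
        ratio1 = w1 / P                 # n x L
        ratio0 = w0 / (1 - P)
        # accumulate expected allele counts without an n x K x L array:
        #   alt counts to (k,l): sum_i Q_ik F_kl w1_il / P_il = F * (Q^T @ ratio1)
        alt_kl = F * (Q.T @ ratio1)
        ref_kl = (1 - F) * (Q.T @ ratio0)
        #   counts to (i,k): sum_l [Q_ik F_kl w1/P + Q_ik (1-F_kl) w0/(1-P)]
        cnt_ik = Q * (ratio1 @ F.T + ratio0 @ (1 - F).T)
        F = np.clip(alt_kl / np.maximum(alt_kl + ref_kl, 1e-12), 1e-6, 1 - 1e-6)
        Q = cnt_ik / np.maximum(2 * nloci_obs, 1e-12)
        Q = np.clip(Q, 1e-9, None)
        Q /= Q.sum(axis=1, keepdims=True)
    P = np.clip(Q @ F, 1e-12, 1 - 1e-12)
    ll = float(np.sum(w1 * np.log(P) + w0 * np.log(1 - P)))
    path.append(ll)
    return Q, F, ll, converged, np.asarray(path)


class AdmixtureModel:
    """Binomial admixture model g_il ~ Binomial(2, (QF)_il).

    ``fit`` alternates EM updates of Q and F from random starts and
    chooses K by entry-masking cross-validation: a random 5% of dosage
    entries are hidden, the model is fit on the rest, and the CV error
    is the mean squared error of the predicted dosage 2(QF) on the
    hidden entries.
    """

    def __init__(self, G: GenotypeMatrix):
        self.G = G

    def fit(
        self,
        K_range=range(1, 11),
        replicates: int = 10,
        cv_mask: float = 0.05,
        seed: int = 0,
        max_iter: int = 300,
    ) -> AdmixtureResults:
        rng = np.random.default_rng(seed)
        d = self.G.dosage
        obs_idx = np.argwhere(d != MISSING)
        cv_error, best = {}, {}
        for K in K_range:
            errs, fits = [], []
            for _ in range(replicates):
                rep_rng = np.random.default_rng(rng.integers(2**31))
                mask_sel = rep_rng.random(len(obs_idx)) < cv_mask
                masked = obs_idx[mask_sel]
                d_train = d.copy()
                d_train[masked[:, 0], masked[:, 1]] = MISSING
                Q, F, ll, conv, path = _admixture_em(d_train, K, rep_rng, max_iter=max_iter)
                pred = 2 * (Q @ F)
                truth = d[masked[:, 0], masked[:, 1]].astype(float)
                errs.append(float(np.mean((pred[masked[:, 0], masked[:, 1]] - truth) ** 2)))
                fits.append((ll, Q, F, conv, path))
            cv_error[K] = float(np.mean(errs))
            best[K] = max(fits, key=lambda t: t[0])
        chosen_K = min(cv_error, key=cv_error.get)
        # final fit on the full data at the chosen K, best of replicates
        final = None
        for _ in range(replicates):
            rep_rng = np.random.default_rng(rng.integers(2**31))
            fit = _admixture_em(d, chosen_K, rep_rng, max_iter=max_iter)
            if final is None or fit[2] > final[2]:
                final = fit
        Q, F, ll, conv, path = final
        if not conv:
            warnings.warn("admixture EM did not converge; returning best iterate")
        return AdmixtureResults(
            K=chosen_K,
            Q=Q,
            F=F,
            loglik=ll,
            converged=conv,
            cv_error=cv_error,
            chosen_K=chosen_K,
            loglik_path=path,
            sample_ids=list(self.G.sample_ids),
        )


def admixture_fit(G: GenotypeMatrix, K_range=range(1, 11), replicates=10,
                  cv_mask=0.05, seed=0, max_iter=300) -> AdmixtureResults:
    return AdmixtureModel(G).fit(K_range, replicates, cv_mask, seed, max_iter)


def align_q_to_truth(Q: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Permute Q columns to best match a truth matrix (Hungarian)."""
    K = Q.shape[1]
    cost = np.zeros((K, truth.shape[1]))
    for a in range(K):
        for b in range(truth.shape[1]):
            cost[a, b] = np.abs(Q[:, a] - truth[:, b]).sum()
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(K, dtype=int)
    perm[cols] = rows
    return Q[:, perm]


# ----------------------------------------------------------------------
# DAPC-style cluster search
# ----------------------------------------------------------------------

@dataclass
class DAPCResult:
    bic_mean: dict            # K -> mean BIC across iterations
    chosen_K: int
    assignments: np.ndarray
    discriminant_axes: np.ndarray | None
    n_pcs: int


def dapc(
    G: GenotypeMatrix,
    candidate_mask=None,
    K_max: int = 20,
    iters: int = 60,
    n_pcs: int | None = None,
    pve_target: float = 0.95,
    seed: int = 0,
) -> DAPCResult:
    """find.clusters-style search: k-means over retained PC scores, with
    BIC(K) = n ln(W_K/n) + K ln(n) averaged over random starts, followed
    by linear discriminant axes on the chosen clustering.
    """
    from sklearn.cluster import KMeans
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    Gm = G.subset_loci(candidate_mask) if candidate_mask is not None else G
    pca = genotype_pca(Gm)
    if n_pcs is None:
        n_pcs = int(np.searchsorted(np.cumsum(pca.pve), pve_target) + 1)
    n_pcs = min(n_pcs, pca.scores.shape[1])
    X = pca.scores[:, :n_pcs]
    n = X.shape[0]
    if K_max >= n:
        warnings.warn(f"K_max {K_max} >= n {n}; capping at n - 1")
        K_max = n - 1
    rng = np.random.default_rng(seed)
    bic_mean, labels_of = {}, {}
    for K in range(1, K_max + 1):
        bics, best_labels, best_W = [], None, np.inf
        for _ in range(iters):
            if K == 1:
                labels = np.zeros(n, dtype=int)
                W = float(((X - X.mean(axis=0)) ** 2).sum())
            else:
                km = KMeans(n_clusters=K, n_init=1, random_state=int(rng.integers(2**31)))
                labels = km.fit_predict(X)
                W = float(km.inertia_)
            bics.append(n * np.log(max(W, 1e-300) / n) + K * np.log(n))
            if W < best_W:
                best_W, best_labels = W, labels
        bic_mean[K] = float(np.mean(bics))
        labels_of[K] = best_labels
    chosen_K = min(bic_mean, key=bic_mean.get)
    axes = None
    if chosen_K > 1:
        lda = LinearDiscriminantAnalysis(n_components=min(chosen_K - 1, n_pcs))
        lda.fit(X, labels_of[chosen_K])
        axes = lda.transform(X)
    return DAPCResult(bic_mean, chosen_K, labels_of[chosen_K], axes, n_pcs)


# ----------------------------------------------------------------------
# Weir-Cockerham FST
# ----------------------------------------------------------------------

def wc_variance_components(dosage: np.ndarray, pop_labels: np.ndarray):
    """Per-locus Weir-Cockerham (1984) variance components a, b, c.

    ``dosage`` is samples x loci with MISSING for no-calls; components
    are computed per locus over populations with >= 1 observed call.
    Returns three (loci,) arrays.
    """
    pops = pd.unique(pop_labels)
    r_max = len(pops)
    L = dosage.shape[1]
    n_il = np.zeros((r_max, L))
    p_il = np.zeros((r_max, L))
    h_il = np.zeros((r_max, L))
    for i, pop in enumerate(pops):
        d = dosage[pop_labels == pop]
        obs = d != MISSING
        n = obs.sum(axis=0).astype(float)
        n_il[i] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            p_il[i] = np.where(n > 0, np.where(obs, d, 0).sum(axis=0) / (2 * n), np.nan)
            h_il[i] = np.where(n > 0, np.where(obs, d == 1, False).sum(axis=0) / n, np.nan)

    valid = n_il > 0
    r = valid.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_sum = np.where(valid, n_il, 0).sum(axis=0)
        nbar = n_sum / r
        nc = (n_sum - np.where(valid, n_il**2, 0).sum(axis=0) / n_sum) / (r - 1)
        pbar = np.where(valid, n_il * p_il, 0).sum(axis=0) / n_sum
        s2 = np.where(valid, n_il * (p_il - pbar[None, :]) ** 2, 0).sum(axis=0) / ((r - 1) * nbar)
        hbar = np.where(valid, n_il * h_il, 0).sum(axis=0) / n_sum

        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    bad = (r < 2) | ~np.isfinite(a)
    a[bad] = b[bad] = c[bad] = np.nan
    return a, b, c


def multilocus_theta(dosage: np.ndarray, pop_labels: np.ndarray) -> float:
    """Multi-locus Weir-Cockerham theta: ratio of summed components."""
    a, b, c = wc_variance_components(dosage, pop_labels)
    ok = np.isfinite(a)
    denom = np.nansum(a[ok] + b[ok] + c[ok])
    return float(np.nansum(a[ok]) / denom) if denom != 0 else 0.0


@dataclass
class FstMatrix:
    populations: list
    theta: pd.DataFrame
    p_value: pd.DataFrame
    n_permutations: int

    def to_tsv(self, path: str) -> str:
        out = self.theta.copy()
        with open(path, "w") as fh:
            fh.write("# pairwise Weir-Cockerham theta (lower) and permutation p (upper)\n")
            combined = out.copy()
            for i, a in enumerate(self.populations):
                for j, b in enumerate(self.populations):
                    if j > i:
                        combined.iloc[i, j] = self.p_value.iloc[i, j]
            combined.to_csv(fh, sep="\t")
        return path


def pairwise_fst(
    G: GenotypeMatrix,
    meta: pd.DataFrame,
    n_perm: int = 10000,
    seed: int = 0,
) -> FstMatrix:
    """Pairwise multi-locus theta with permutation significance.

    For each population pair, individuals are shuffled between the two
    groups ``n_perm`` times; p is the +1-smoothed fraction of permuted
    theta values >= observed.  Populations with fewer than 2 samples
    are excluded with a warning.  Negative theta values are reported as
    computed.
    """
    pops_all = meta.set_index("sample_id").loc[G.sample_ids, "population"].to_numpy()
    counts = pd.Series(pops_all).value_counts()
    pops = [p for p in pd.unique(pops_all) if counts[p] >= 2]
    dropped = [p for p in pd.unique(pops_all) if counts[p] < 2]
    if dropped:
        warnings.warn(f"excluding populations with n < 2: {dropped}")
    if len(pops) < 2:
        raise SoilGEAError("need at least two populations with n >= 2")
    rng = np.random.default_rng(seed)
    k = len(pops)
    theta = np.zeros((k, k))
    pval = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            mask = np.isin(pops_all, [pops[i], pops[j]])
            d = G.dosage[mask]
            labels = pops_all[mask]
            obs = multilocus_theta(d, labels)
            exceed = 0
            lab = labels.copy()
            for _ in range(n_perm):
                rng.shuffle(lab)
                if multilocus_theta(d, lab) >= obs:
                    exceed += 1
            p = (exceed + 1) / (n_perm + 1)
            theta[i, j] = theta[j, i] = obs
            pval[i, j] = pval[j, i] = p
    idx = pd.Index(pops, name="population")
    return FstMatrix(
        pops,
        pd.DataFrame(theta, index=idx, columns=idx),
        pd.DataFrame(pval, index=idx, columns=idx),
        n_perm,
    )
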