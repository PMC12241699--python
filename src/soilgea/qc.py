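"""Locus quality control: exact HWE test, filtering, KNN imputation and
per-population diversity statistics.

Filtering reproduces the common SNP-panel recipe: drop monomorphic loci,
then loci with a missing call rate above 20%, then loci with minor
allele frequency below 5%, then loci out of Hardy-Weinberg equilibrium
(exact-test p below 1e-6) in any population with at least five
non-missing genotypes.  Statistics are computed on the raw calls before
imputation.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, exp

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, MISSING, SoilGEAError


class EmptyPanelError(SoilGEAError):
    """All loci removed by filtering."""


class ImputationError(SoilGEAError):
    pass


# ----------------------------------------------------------------------
# Hardy-Weinberg exact test
# ----------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test of Hardy-Weinberg equilibrium.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote configurations no more probable than the one
    observed (two-sided, the usual "exact HWE" construction).

    Returns a p-value in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa + n_Aa          # minor-ish allele count (either works)
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    # possible het counts share the parity of the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)

    def logprob(h):
        # P(N_Aa = h | allele counts) ∝ n! / (n_AA! n_Aa! n_aa!) * 2^h
        hom_rare = (rare - h) // 2
        hom_common = n - h - hom_rare
        return (
            h * np.log(2)
            + lgamma(n + 1)
            - lgamma(h + 1)
            - lgamma(hom_rare + 1)
            - lgamma(hom_common + 1)
        )

    logs = np.array([logprob(int(h)) for h in hets])
    logs -= logs.max()
    probs = np.exp(logs)
    probs /= probs.sum()
    p_obs = probs[hets == n_Aa]
    if p_obs.size == 0:
        raise ValueError("observed heterozygote count inconsistent with allele counts")
    p = probs[probs <= p_obs[0] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


# ----------------------------------------------------------------------
# filtering
# ----------------------------------------------------------------------

@dataclass
class LocusStats:
    """Per-locus QC statistics with drop reasons for the whole input panel."""

    table: pd.DataFrame  # locus, maf, missing_rate, monomorphic, min_hwe_p, drop_reason

    def to_tsv(self, path: str) -> str:
        self.table.to_csv(path, sep="\t", index=False)
        return path


def _genotype_counts(dosage_col: np.ndarray) -> tuple[int, int, int]:
    obs = dosage_col[dosage_col != MISSING]
    return int((obs == 0).sum()), int((obs == 1).sum()), int((obs == 2).sum())


def filter_loci(
    G: GenotypeMatrix,
    meta: pd.DataFrame,
    max_missing: float = 0.20,
    min_maf: float = 0.05,
    hwe_alpha: float = 1e-6,
    hwe_min_n: int = 5,
) -> tuple[GenotypeMatrix, LocusStats]:
    """Drop loci in fixed order: monomorphic, missingness, MAF, HWE.

    The HWE filter removes a locus if the exact test rejects at
    ``hwe_alpha`` in *any* population with >= ``hwe_min_n`` non-missing
    genotypes.
    """
    pops = meta.set_index("sample_id").loc[G.sample_ids, "population"].to_numpy()
    d = G.dosage
    obs = d != MISSING
    n_obs = obs.sum(axis=0)
    missing_rate = 1.0 - n_obs / G.n_samples

    with np.errstate(invalid="ignore"):
        freq = np.where(n_obs > 0, np.where(obs, d, 0).sum(axis=0) / (2.0 * np.maximum(n_obs, 1)), np.nan)
    maf = np.where(np.isnan(freq), np.nan, np.minimum(freq, 1 - freq))

    monomorphic = np.array(
        [len(np.unique(d[obs[:, j], j])) <= 1 for j in range(G.n_loci)]
    )

    reason = np.array([""] * G.n_loci, dtype=object)
    reason[monomorphic] = "monomorphic"
    live = ~monomorphic

    drop_missing = live & (missing_rate > max_missing)
    reason[drop_missing] = "missing_rate"
    live &= ~drop_missing

    drop_maf = live & (maf < min_maf)
    reason[drop_maf] = "maf"
    live &= ~drop_maf

    min_hwe_p = np.full(G.n_loci, np.nan)
    if hwe_alpha > 0:
        pop_masks = [(pops == p) for p in pd.unique(pops)]
        for j in np.flatnonzero(live):
            pmin = np.nan
            for mask in pop_masks:
                col = d[mask, j]
                col = col[col != MISSING]
                if col.size < hwe_min_n:
                    continue
                counts = (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))
                p = hwe_exact_test(*counts)
                pmin = p if np.isnan(pmin) else min(pmin, p)
            min_hwe_p[j] = pmin
            if not np.isnan(pmin) and pmin < hwe_alpha:
                reason[j] = "hwe"
                live[j] = False

    table = pd.DataFrame(
        {
            "locus": G.locus_ids,
            "maf": maf,
            "missing_rate": missing_rate,
            "monomorphic": monomorphic,
            "min_hwe_p": min_hwe_p,
            "drop_reason": reason,
        }
    )
    if not live.any():
        raise EmptyPanelError("all loci removed by filtering; check thresholds")
    return G.subset_loci(live), LocusStats(table)


# ----------------------------------------------------------------------
# KNN imputation
# ----------------------------------------------------------------------

def _pairwise_complete_corr(dosage: np.ndarray) -> np.ndarray:
    """Pearson correlation between loci over pairwise-complete samples."""
    X = dosage.astype(float)
    M = (dosage != MISSING).astype(float)
    X = np.where(M > 0, X, 0.0)
    n = M.T @ M                                # counts of complete pairs
    sx = X.T @ M
    sy = M.T @ X
    sxy = X.T @ X
    sxx = (X * X).T @ M
    syy = M.T @ (X * X)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / np.maximum(n, 1)
        vx = sxx - sx**2 / np.maximum(n, 1)
        vy = syy - sy**2 / np.maximum(n, 1)
        r = cov / np.sqrt(vx * vy)
    r[(n < 3) | ~np.isfinite(r)] = 0.0
    return r


def impute_knn(G: GenotypeMatrix, k: int = 5, n_ld_sites: int = 30) -> GenotypeMatrix:
    """LD-guided K-nearest-neighbour genotype imputation.

    For each missing call the ``n_ld_sites`` loci most correlated (r^2,
    pairwise-complete) with the target locus define a similarity
    1 - mean|dosage difference| between the focal sample and every
    sample observed at the target locus; the imputed value is the
    similarity-weighted modal dosage among the ``k`` most similar, ties
    broken toward the lower dosage.
    """
    d = G.dosage.copy()
    miss = d == MISSING
    if not miss.any():
        return G.copy()
    n_obs = (~miss).sum(axis=0)
    short = np.flatnonzero(n_obs < k)
    if short.size:
        raise ImputationError(
            f"locus {G.locus_ids[short[0]]} has fewer than k={k} observed calls"
        )
    r2 = _pairwise_complete_corr(d) ** 2
    np.fill_diagonal(r2, -1.0)

    df = d.astype(float)
    df[miss] = np.nan
    out = d.copy()
    for j in np.flatnonzero(miss.any(axis=0)):
        ld = np.argsort(r2[j])[::-1][:n_ld_sites]
        observed_at_j = np.flatnonzero(~miss[:, j])
        block_obs = df[np.ix_(observed_at_j, ld)]
        for i in np.flatnonzero(miss[:, j]):
            diff = np.abs(block_obs - df[i, ld][None, :])
            overlap = ~np.isnan(diff)
            n_overlap = overlap.sum(axis=1)
            mean_diff = np.where(
                n_overlap > 0, np.nansum(np.where(overlap, diff, 0), axis=1) / np.maximum(n_overlap, 1), 2.0
            )
            sim = 1.0 - mean_diff
            order = np.argsort(-sim, kind="stable")[:k]
            weights = np.maximum(sim[order], 0.0) + 1e-9
            votes = np.zeros(3)
            for w, s in zip(weights, observed_at_j[order]):
                votes[d[s, j]] += w
            out[i, j] = int(np.argmax(votes))  # argmax takes lowest dosage on ties
    return GenotypeMatrix(out, G.sample_ids, G.locus_ids)


# ----------------------------------------------------------------------
# diversity statistics
# ----------------------------------------------------------------------

def diversity_stats(
    G: GenotypeMatrix,
    meta: pd.DataFrame,
    tag_length_bp: int = 82,
    n_tags: int | None = None,
) -> pd.DataFrame:
    """Per-population Ho, He and per-nucleotide pi.

    Ho is the mean observed heterozygote fraction across loci; He the
    mean unbiased expected heterozygosity (2n/(2n-1)) * 2p(1-p); pi is
    the He sum rescaled per nucleotide over the sequenced tag length
    (``n_tags`` defaults to the number of loci, i.e. one SNP per tag).
    """
    pops = meta.set_index("sample_id").loc[G.sample_ids, "population"]
    n_tags = G.n_loci if n_tags is None else n_tags
    rows = []
    groups = list(pd.unique(pops)) + ["__whole__"]
    for pop in groups:
        mask = np.ones(G.n_samples, bool) if pop == "__whole__" else (pops == pop).to_numpy()
        if mask.sum() < 2:
            raise SoilGEAError(f"population {pop} has fewer than 2 samples")
        d = G.dosage[mask]
        obs = d != MISSING
        n = obs.sum(axis=0).astype(float)
        ok = n >= 2
        het = np.where(obs, d == 1, False).sum(axis=0)
        ho = het[ok] / n[ok]
        p = np.where(obs, d, 0).sum(axis=0)[ok] / (2 * n[ok])
        he = (2 * n[ok] / (2 * n[ok] - 1)) * 2 * p * (1 - p)
        pi = he.sum() / (n_tags * tag_length_bp)
        rows.append(
            dict(
                population="whole_sample" if pop == "__whole__" else pop,
                n=int(mask.sum()),
                n_loci=int(ok.sum()),
                Ho=float(ho.mean()),
                He=float(he.mean()),
                pi=float(pi),
            )
        )
    return pd.DataFrame(rows)
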