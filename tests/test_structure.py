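"""Population structure: PCA scaling/oracle, admixture EM properties
and recovery, DAPC cluster search, Weir-Cockerham FST."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from soilgea import GenotypeMatrix, SimConfig, simulate_dataset
from soilgea.structure import (
    AdmixtureModel,
    _admixture_em,
    align_q_to_truth,
    dapc,
    genotype_pca,
    multilocus_theta,
    pairwise_fst,
    wc_variance_components,
)


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

def test_pca_matches_dense_covariance_oracle():
    rng = np.random.default_rng(1)
    d = rng.integers(0, 3, size=(30, 50)).astype(np.int8)
    d[:, d.sum(axis=0) == 0] = 1  # avoid constant-zero loci
    G = GenotypeMatrix(d, [f"s{i}" for i in range(30)], [f"l{j}" for j in range(50)])
    res = genotype_pca(G)
    # oracle: explicit covariance eigendecomposition of Patterson-scaled data
    X = d.astype(float)
    p = X.mean(axis=0) / 2
    keep = (p > 0) & (p < 1)
    Z = (X[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
    C = Z @ Z.T / (Z.shape[0] - 1)
    eig_oracle = np.sort(np.linalg.eigvalsh(C))[::-1]
    k = len(res.eigenvalues)
    assert np.allclose(res.eigenvalues, eig_oracle[:k], atol=1e-8)


def test_pca_separates_fixed_populations():
    """Two populations fixed for alternate alleles load PC1 entirely."""
    d = np.vstack([np.zeros((10, 40)), np.full((10, 40), 2)]).astype(np.int8)
    G = GenotypeMatrix(d, [f"s{i}" for i in range(20)], [f"l{j}" for j in range(40)])
    res = genotype_pca(G)
    assert res.pve[0] > 0.999
    side = np.sign(res.scores[:, 0])
    assert len(set(side[:10])) == 1 and side[0] != side[-1]


def test_pca_weak_structure_regime(three_cluster_dataset):
    """Hierarchical drift gives leading axes that each explain only a
    few percent of total variance, as expected for a weakly structured
    conifer panel."""
    G, *_ = three_cluster_dataset
    res = genotype_pca(G)
    assert 0.01 < res.pve[0] < 0.25
    assert res.pve[1] < res.pve[0]


# ----------------------------------------------------------------------
# admixture
# ----------------------------------------------------------------------

def test_admixture_k1_closed_form():
    cfg = SimConfig(n_clusters=1, pops_per_cluster=2, samples_per_pop=15,
                    n_loci=100, missing_rate=0.0, seed=5)
    G, *_ = simulate_dataset(cfg)
    res = AdmixtureModel(G).fit(K_range=[1], replicates=2, seed=0)
    assert np.allclose(res.Q, 1.0)
    freq = G.dosage.mean(axis=0) / 2
    assert np.allclose(res.F[0], freq, atol=1e-3)
    g = G.dosage.astype(float)
    p = np.clip(res.F[0], 1e-12, 1 - 1e-12)
    ll = float(np.sum(g * np.log(p)[None, :] + (2 - g) * np.log(1 - p)[None, :]))
    assert res.loglik == pytest.approx(ll, rel=1e-6)


def test_admixture_loglik_ascent(three_cluster_dataset):
    G, *_ = three_cluster_dataset
    rng = np.random.default_rng(3)
    _, _, _, _, path = _admixture_em(G.dosage, K=3, rng=rng, max_iter=100)
    assert np.all(np.diff(path) > -1e-6 * np.abs(path[:-1]))


def test_admixture_recovers_three_clusters():
    cfg = SimConfig(n_clusters=3, pops_per_cluster=3, samples_per_pop=8,
                    n_loci=300, f_cluster=0.15, f_pop=0.01, prop_adaptive=0.0,
                    missing_rate=0.0, seed=77)
    G, meta, _, truth = simulate_dataset(cfg)
    res = AdmixtureModel(G).fit(K_range=range(1, 6), replicates=5, seed=1, max_iter=200)
    assert res.chosen_K == 3
    truth_Q = pd.get_dummies(meta["cluster"]).to_numpy(float)
    Q = align_q_to_truth(res.Q, truth_Q)
    assert np.abs(Q - truth_Q).mean() < 0.1


def test_admixture_rows_sum_to_one(three_cluster_dataset):
    G, *_ = three_cluster_dataset
    res = AdmixtureModel(G).fit(K_range=[3], replicates=2, seed=2, max_iter=120)
    assert np.allclose(res.Q.sum(axis=1), 1.0, atol=1e-8)
    assert res.F.min() >= 0 and res.F.max() <= 1


# ----------------------------------------------------------------------
# DAPC
# ----------------------------------------------------------------------

def test_dapc_single_cloud_chooses_k1():
    rng = np.random.default_rng(4)
    d = rng.binomial(2, 0.4, size=(60, 120)).astype(np.int8)
    G = GenotypeMatrix(d, [f"s{i}" for i in range(60)], [f"l{j}" for j in range(120)])
    res = dapc(G, K_max=6, iters=10, seed=0)
    assert res.chosen_K == 1


def test_dapc_recovers_separated_clusters(three_cluster_dataset):
    G, meta, _, truth = three_cluster_dataset
    cand = list(truth.adaptive_loci)
    res = dapc(G, K_max=6, iters=10, seed=0)
    assert res.chosen_K == 3
    # assignments line up with the true clusters
    ct = pd.crosstab(res.assignments, meta["cluster"])
    assert (ct.max(axis=0) / ct.sum(axis=0)).min() > 0.9
    # any locus mask is accepted
    res_c = dapc(G, candidate_mask=np.asarray(cand, dtype=object), K_max=4, iters=5, seed=0)
    assert res_c.assignments.shape[0] == G.n_samples


def test_dapc_bic_formula_k1():
    """For K=1 the clustering is deterministic, so the mean BIC must
    equal n*ln(TSS/n) + ln(n) exactly."""
    rng = np.random.default_rng(8)
    d = rng.binomial(2, 0.5, size=(40, 60)).astype(np.int8)
    G = GenotypeMatrix(d, [f"s{i}" for i in range(40)], [f"l{j}" for j in range(60)])
    res = dapc(G, K_max=3, iters=4, seed=0)
    X = genotype_pca(G).scores[:, : res.n_pcs]
    n = X.shape[0]
    W1 = float(((X - X.mean(axis=0)) ** 2).sum())
    assert res.bic_mean[1] == pytest.approx(n * np.log(W1 / n) + np.log(n), rel=1e-12)


# ----------------------------------------------------------------------
# Weir-Cockerham FST
# ----------------------------------------------------------------------

def wc_theta_oracle_single_locus(genotypes_by_pop):
    """Independent scalar implementation of the WC-1984 single-locus
    variance components (a, b, c) from per-population genotype lists."""
    pops = [np.asarray(g, dtype=float) for g in genotypes_by_pop]
    r = len(pops)
    n_i = np.array([len(g) for g in pops], dtype=float)
    p_i = np.array([g.sum() / (2 * len(g)) for g in pops])
    h_i = np.array([(g == 1).mean() for g in pops])
    nbar = n_i.mean()
    nc = (n_i.sum() - (n_i**2).sum() / n_i.sum()) / (r - 1)
    pbar = (n_i * p_i).sum() / (r * nbar)
    s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
    hbar = (n_i * h_i).sum() / (r * nbar)
    a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
    )
    c = hbar / 2
    return a, b, c


def test_wc_components_match_oracle_on_random_toys():
    rng = np.random.default_rng(10)
    for _ in range(20):
        sizes = rng.integers(3, 12, size=rng.integers(2, 5))
        pops, rows, labels = [], [], []
        for i, s in enumerate(sizes):
            g = rng.integers(0, 3, size=s)
            if len({int(v) for p in pops + [list(g)] for v in p}) == 1:
                g[0] = (g[0] + 1) % 3  # avoid a fully monomorphic locus
            pops.append(list(g))
            rows.extend(g)
            labels.extend([f"P{i}"] * s)
        d = np.asarray(rows, dtype=np.int8)[:, None]
        a, b, c = wc_variance_components(d, np.asarray(labels, dtype=object))
        ao, bo, co = wc_theta_oracle_single_locus(pops)
        assert a[0] == pytest.approx(ao, abs=1e-10)
        assert b[0] == pytest.approx(bo, abs=1e-10)
        assert c[0] == pytest.approx(co, abs=1e-10)


def test_theta_extremes():
    rng = np.random.default_rng(2)
    # identical frequencies, large n -> theta ~ 0
    d = rng.binomial(2, 0.35, size=(200, 5000)).astype(np.int8)
    labels = np.array(["A"] * 100 + ["B"] * 100, dtype=object)
    assert abs(multilocus_theta(d, labels)) < 0.01
    # fixed alternate alleles -> theta = 1
    d2 = np.vstack([np.zeros((10, 50)), np.full((10, 50), 2)]).astype(np.int8)
    labels2 = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
    assert multilocus_theta(d2, labels2) == pytest.approx(1.0, abs=1e-12)


def test_pairwise_fst_matrix_contract():
    cfg = SimConfig(n_clusters=1, pops_per_cluster=3, samples_per_pop=8,
                    n_loci=120, f_pop=0.10, missing_rate=0.0, prop_adaptive=0.0, seed=15)
    G, meta, _, _ = simulate_dataset(cfg)
    fst = pairwise_fst(G, meta, n_perm=99, seed=0)
    th = fst.theta.to_numpy()
    assert np.allclose(th, th.T)
    assert np.allclose(np.diag(th), 0)
    p = fst.p_value.to_numpy()[np.triu_indices(3, 1)]
    assert ((p > 0) & (p <= 1)).all()
    # differentiated pops at f_pop = 0.10 should test significant
    assert (p <= 0.05).all()


def test_fst_permutation_p_uniform_under_null():
    """Over many neutral pairs (single panmictic pool split in two),
    permutation p-values are Uniform(0,1)."""
    rng = np.random.default_rng(3)
    pvals = []
    labels = np.array(["A"] * 12 + ["B"] * 12, dtype=object)
    meta = pd.DataFrame({"sample_id": [f"s{i}" for i in range(24)], "population": labels})
    for rep in range(150):
        d = rng.binomial(2, rng.uniform(0.1, 0.9, 40)[None, :], size=(24, 40)).astype(np.int8)
        G = GenotypeMatrix(d, list(meta["sample_id"]), [f"l{j}" for j in range(40)])
        fst = pairwise_fst(G, meta, n_perm=49, seed=rep)
        pvals.append(fst.p_value.iloc[0, 1])
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01, ks
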