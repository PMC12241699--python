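"""GEA detectors: calibration/adjustment machinery, latent-factor scan,
logistic G-score vs a direct likelihood oracle, FST-environment
permutation test, and candidate combination."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import minimize

from soilgea import GenotypeMatrix, SimConfig, simulate_dataset
from soilgea.gea import (
    AssociationResult,
    bh_adjust,
    calibrate_and_adjust,
    combine_candidates,
    environmental_distance,
    fstenv_gea,
    latent_factor_gea,
    logistic_gea,
    storey_qvalues,
)
from soilgea.io import SoilGEAError, soil_by_sample


# ----------------------------------------------------------------------
# calibration / adjustment
# ----------------------------------------------------------------------

def test_lambda_near_one_for_standard_normal_z():
    rng = np.random.default_rng(0)
    out = calibrate_and_adjust(z_scores=rng.standard_normal(10000))
    assert 0.95 <= out["lambda_gif"] <= 1.05


def test_bh_step_up_hand_example():
    p = np.array([0.01, 0.02, 0.04, 0.8])
    out = calibrate_and_adjust(p_values=p, scheme="gif+bh", alpha=0.05)
    # step-up by hand: 0.8 -> 0.8; 0.04*4/3 = 0.0533; 0.02*2 = 0.04; 0.01*4=0.04
    assert np.allclose(out["adjusted"], [0.04, 0.04, 0.05333333, 0.8])
    assert list(out["flagged"]) == [True, True, False, False]


def test_bonferroni_threshold_is_alpha_over_m():
    p = np.full(1582, 0.5)
    out = calibrate_and_adjust(p_values=p, scheme="bonferroni", alpha=0.05)
    assert out["threshold"] == pytest.approx(3.16e-5, rel=2e-3)
    assert not out["flagged"].any()


def test_storey_qvalues_monotone_and_bounded():
    rng = np.random.default_rng(1)
    p = np.concatenate([rng.uniform(0, 1, 900), rng.uniform(0, 1e-4, 100)])
    q = storey_qvalues(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-12).all()
    assert (q <= bh_adjust(p) + 1e-12).all()  # pi0 <= 1 makes q <= BH


def test_calibrate_empty_input_errors():
    with pytest.raises(SoilGEAError):
        calibrate_and_adjust(z_scores=np.array([]))


# ----------------------------------------------------------------------
# latent-factor scan
# ----------------------------------------------------------------------

def test_latent_factor_finds_single_causal_locus():
    """K=0, no structure, one strongly driven locus -> smallest p."""
    rng = np.random.default_rng(3)
    n, L = 80, 100
    x = rng.standard_normal(n)
    d = rng.binomial(2, 0.5, size=(n, L)).astype(np.int8)
    p_causal = 1 / (1 + np.exp(-(2 * (x - x.mean()) / x.std())))
    d[:, 0] = rng.binomial(2, p_causal)
    G = GenotypeMatrix(d, [f"s{i}" for i in range(n)], [f"l{j}" for j in range(L)])
    S = pd.DataFrame({"v": x}, index=G.sample_ids)
    res = latent_factor_gea(G, S, K_latent=0)
    assert res.table["p_cal"].idxmin() == 0


def test_latent_factor_affine_invariance(three_cluster_dataset):
    """Rescaling the soil variable leaves z, p and lambda unchanged."""
    G, meta, soil, _ = three_cluster_dataset
    S1 = soil_by_sample(soil[["Ca"]], meta)
    S2 = 3.7 * S1 - 11.0
    r1 = latent_factor_gea(G, S1, K_latent=2)
    r2 = latent_factor_gea(G, S2, K_latent=2)
    assert np.allclose(r1.table["z"], r2.table["z"], atol=1e-8)
    assert r1.lambda_gif["Ca"] == pytest.approx(r2.lambda_gif["Ca"], abs=1e-10)


def test_latent_factor_locus_order_invariance(three_cluster_dataset):
    G, meta, soil, _ = three_cluster_dataset
    S = soil_by_sample(soil[["EC"]], meta)
    r1 = latent_factor_gea(G, S, K_latent=2)
    perm = np.random.default_rng(0).permutation(G.n_loci)
    Gp = G.subset_loci(perm)
    r2 = latent_factor_gea(Gp, S, K_latent=2)
    t1 = r1.table.set_index("locus")["z"]
    t2 = r2.table.set_index("locus")["z"]
    assert np.allclose(t1.loc[t2.index], t2, atol=1e-8)


def test_latent_factor_rejects_bad_inputs(three_cluster_dataset):
    G, meta, soil, _ = three_cluster_dataset
    S = soil_by_sample(soil[["Ca"]], meta)
    with pytest.raises(SoilGEAError):
        latent_factor_gea(G, S, K_latent=G.n_samples)
    with pytest.raises(SoilGEAError):
        latent_factor_gea(G, S.assign(Ca=1.0), K_latent=2)


# ----------------------------------------------------------------------
# logistic G-score
# ----------------------------------------------------------------------

def _nll(beta, X, y):
    eta = X @ beta
    return float(np.sum(np.log1p(np.exp(eta))) - y @ eta)


def test_logistic_gscore_matches_direct_mle_oracle():
    """G on a 12-sample toy equals 2*(l1 - l0) from direct numerical
    maximum-likelihood fits of both nested models."""
    rng = np.random.default_rng(5)
    n = 12
    x = rng.standard_normal(n)
    q = rng.uniform(0, 1, n)
    d = np.array([0, 1, 2, 1, 0, 2, 1, 0, 1, 2, 0, 1], dtype=np.int8)
    G = GenotypeMatrix(d[:, None], [f"s{i}" for i in range(n)], ["L"])
    S = pd.DataFrame({"v": x}, index=G.sample_ids)
    res = logistic_gea(G, S, structure_covariates=q[:, None], ridge=0.0)
    g_pkg = res.table["z"].iloc[0] ** 2

    y = (d > 0).astype(float)  # freq > 0.5 -> minor allele is REF... check
    freq = d.mean() / 2
    y = (d > 0).astype(float) if freq <= 0.5 else (d < 2).astype(float)
    xz = (x - x.mean()) / x.std()
    X0 = np.column_stack([np.ones(n), q])
    X1 = np.column_stack([np.ones(n), q, xz])
    l0 = -minimize(_nll, np.zeros(2), args=(X0, y), method="BFGS").fun
    l1 = -minimize(_nll, np.zeros(3), args=(X1, y), method="BFGS").fun
    assert g_pkg == pytest.approx(2 * (l1 - l0), abs=1e-6)


def test_logistic_constant_variable_gives_null_result(three_cluster_dataset):
    G, meta, soil, _ = three_cluster_dataset
    Gs = G.subset_loci(np.arange(20))
    S = pd.DataFrame({"flat": np.ones(G.n_samples)}, index=G.sample_ids)
    res = logistic_gea(Gs, S)
    assert (res.table["z"] == 0).all()
    assert (res.table["p_raw"] == 1).all()


def test_logistic_bonferroni_family_is_locus_by_variable(three_cluster_dataset):
    G, meta, soil, _ = three_cluster_dataset
    Gs = G.subset_loci(np.arange(50))
    S = soil_by_sample(soil[["Ca", "EC"]], meta)
    res = logistic_gea(Gs, S)
    m = 50 * 2
    # adj = min(1, p * m)
    sub = res.table[res.table["p_raw"] < 1 / m]
    assert np.allclose(sub["adj"], sub["p_raw"] * m, rtol=1e-12)


# ----------------------------------------------------------------------
# FST-environment scan
# ----------------------------------------------------------------------

def test_environmental_distance_normalised():
    d = environmental_distance(np.array([1.0, 2.0, 3.0, 6.0]))
    assert d.max() == pytest.approx(1.0)
    assert (d >= 0).all()
    with pytest.raises(SoilGEAError):
        environmental_distance(np.ones(4))


def test_fstenv_degenerate_distances_skip_all_loci(three_cluster_dataset):
    G, meta, soil, _ = three_cluster_dataset
    pops = meta["population"].unique()
    # distances |x - mean| identical across populations (alternating +/-1)
    S = pd.DataFrame({"alt": [1.0 if i % 2 else -1.0 for i in range(len(pops))]},
                     index=pops)
    Gs = G.subset_loci(np.arange(30))
    res = fstenv_gea(Gs, meta, S, n_perm=49, seed=0)
    assert res.table["skipped"].all()
    assert not res.table["flagged"].any()


def test_fstenv_null_p_uniform():
    cfg = SimConfig(n_clusters=1, pops_per_cluster=10, samples_per_pop=6,
                    n_loci=1000, f_pop=0.05, prop_adaptive=0.0,
                    missing_rate=0.0, seed=51)
    G, meta, soil, _ = simulate_dataset(cfg)
    res = fstenv_gea(G, meta, soil[["Ca"]], n_perm=199, seed=1)
    p = res.table["p_raw"].dropna()
    ks = stats.kstest(p, "uniform")
    assert ks.pvalue > 0.01, ks


def test_fstenv_ranks_adaptive_loci_high():
    cfg = SimConfig(n_clusters=1, pops_per_cluster=12, samples_per_pop=8,
                    n_loci=500, prop_adaptive=0.05, beta=2.0, driver_vars=("Ca",),
                    f_pop=0.03, missing_rate=0.0, seed=52)
    G, meta, soil, truth = simulate_dataset(cfg)
    res = fstenv_gea(G, meta, soil[["Ca"]], n_perm=199, seed=2)
    tab = res.table.set_index("locus")
    ranks = tab["effect"].rank(ascending=False)
    med = ranks.loc[truth.adaptive_loci].median()
    assert med <= 0.10 * G.n_loci, med


# ----------------------------------------------------------------------
# candidate combination
# ----------------------------------------------------------------------

def _fake_result(method, pairs, scale="range_wide"):
    rows = [
        {"locus": l, "variable": v, "effect": 1.0, "z": 3.0, "p_raw": 1e-4,
         "p_cal": 1e-4, "adj": 1e-3, "flagged": True}
        for l, v in pairs
    ]
    table = pd.DataFrame(rows, columns=["locus", "variable", "effect", "z",
                                        "p_raw", "p_cal", "adj", "flagged"])
    return AssociationResult(method, table, {}, scale)


def test_combine_disjoint_sets():
    res = combine_candidates([
        _fake_result("latent_factor", [("a", "pH")]),
        _fake_result("logistic", [("b", "pH")]),
        _fake_result("fst_env", [("c", "pH")]),
    ])
    assert len(res.entries) == 3
    assert res.venn_counts["fst_env&latent_factor&logistic"] == 0
    assert res.method_counts == {"latent_factor": 1, "logistic": 1, "fst_env": 1}


def test_combine_set_algebra():
    res = combine_candidates([
        _fake_result("latent_factor", [("a", "pH"), ("b", "pH")]),
        _fake_result("logistic", [("b", "pH"), ("c", "pH")]),
        _fake_result("fst_env", [("b", "pH")]),
    ])
    assert len(res.entries) == 3
    assert res.venn_counts["fst_env&latent_factor&logistic"] == 1
    b = res.entries.set_index("locus").loc["b", "methods"]
    assert set(b.split(",")) == {"latent_factor", "logistic", "fst_env"}


def test_combine_singleton_identity():
    r = _fake_result("latent_factor", [("a", "pH"), ("d", "EC")])
    out = combine_candidates([r])
    assert set(out.loci) == {"a", "d"}


def test_combine_mixed_scales_error():
    with pytest.raises(SoilGEAError, match="scale"):
        combine_candidates([
            _fake_result("latent_factor", [("a", "pH")], scale="range_wide"),
            _fake_result("logistic", [("a", "pH")], scale="local"),
        ])
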