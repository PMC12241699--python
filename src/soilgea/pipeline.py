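"""End-to-end single-scale analysis: QC -> structure -> predictor prep
-> three GEA scans -> candidate combination -> polygenic dbRDA with
MAF-matched nulls (and optional cross-scale transfer) -> spatial PCA
clines.  Every stage writes its tabular output under the run directory,
and a manifest records config hash, seeds and per-file checksums so
that a rerun with the same config is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

import importlib

from . import io as sgio
from . import qc, structure, envprep, gea, spatial
from .io import SoilGEAError, ConfigurationError

# the package namespace re-exports a `dbrda` *function*, so fetch the
# module of the same name explicitly
dbr = importlib.import_module(".dbrda", __package__)


class StageError(SoilGEAError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}] {code}: {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    genotypes: str
    metadata: str
    soil: str
    outdir: str
    scale: str = "range_wide"
    other_scale_candidates: str | None = None
    # thresholds (module defaults)
    max_missing: float = 0.20
    min_maf: float = 0.05
    hwe_alpha: float = 1e-6
    knn_k: int = 5
    n_ld_sites: int = 30
    K_range: list = field(default_factory=lambda: list(range(1, 7)))
    admixture_replicates: int = 5
    r_max: float = 0.75
    vif_max: float = 3.0
    gea_alpha: float = 0.05
    fstenv_n_perm: int = 999
    dbrda_n_perm: int = 999
    n_null_sets: int = 20
    maf_bin: float = 0.05
    fst_n_perm: int = 0        # pairwise FST permutations (0 = skip FST stage)
    spca_k: int = 3
    n_axes: int = 2
    tag_length_bp: int = 82
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        try:
            cfg = cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(str(exc)) from exc
        for key in ("genotypes", "metadata", "soil"):
            p = getattr(cfg, key)
            if not os.path.exists(p):
                raise ConfigurationError(f"{key} file not found: {p}")
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


#: pipeline stage order; a run can stop after any of them
STAGES = ("qc", "structure", "envprep", "gea", "polygenic", "spatial")


def run_scale_analysis(config: RunConfig, log=None, stop_after: str | None = None) -> dict:
    """Execute the single-scale analysis; returns the summary dict.

    ``stop_after`` truncates the run after the named stage (the 'gea'
    stage implies qc/structure/envprep, its prerequisites).
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ConfigurationError(f"unknown stage {stop_after!r}; expected one of {STAGES}")

    def say(stage, msg):
        if log:
            log(f"[{stage}] {msg}")

    os.makedirs(config.outdir, exist_ok=True)
    manifest = {
        "package": "soilgea",
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }
    summary: dict = {"scale": config.scale, "schema_version": 1}
    outputs: dict[str, str] = {}
    t_start = time.time()

    def record(stage, files):
        manifest["stages"][stage] = {
            "files": {os.path.basename(f): _sha256(f) for f in files},
            "elapsed_s": round(time.time() - t_start, 3),
        }
        outputs.update({os.path.basename(f): f for f in files})

    def finish():
        p_sum = os.path.join(config.outdir, "summary.json")
        with open(p_sum, "w") as fh:
            json.dump(summary, fh, indent=1, default=float)
        manifest["stages"]["summary"] = {"files": {"summary.json": _sha256(p_sum)}}
        p_man = os.path.join(config.outdir, "manifest.json")
        with open(p_man, "w") as fh:
            json.dump(manifest, fh, indent=1)
        say("done", f"summary written to {p_sum}")
        return summary

    # ------------------------------------------------------------ load
    try:
        if config.genotypes.endswith((".vcf", ".vcf.gz")):
            G = sgio.read_vcf(config.genotypes)
        else:
            G = sgio.read_dosage_tsv(config.genotypes)
        meta = sgio.read_metadata(config.metadata)
        soil = sgio.read_soil(config.soil)
        G, meta = sgio.align(G, meta)
    except SoilGEAError as exc:
        raise StageError("load", "E_INPUT", str(exc)) from exc
    say("load", f"{G.n_samples} samples x {G.n_loci} loci")

    # -------------------------------------------------------------- qc
    try:
        G_f, stats_ = qc.filter_loci(
            G, meta, config.max_missing, config.min_maf, config.hwe_alpha
        )
        G_imp = qc.impute_knn(G_f, k=config.knn_k, n_ld_sites=config.n_ld_sites)
        div = qc.diversity_stats(G_f, meta, tag_length_bp=config.tag_length_bp)
    except SoilGEAError as exc:
        raise StageError("qc", "E_QC", str(exc)) from exc
    p_stats = os.path.join(config.outdir, "locus_stats.tsv")
    stats_.to_tsv(p_stats)
    p_div = os.path.join(config.outdir, "diversity.tsv")
    div.to_csv(p_div, sep="\t", index=False)
    p_vcf = os.path.join(config.outdir, "filtered.vcf")
    sgio.write_vcf(G_f, p_vcf)
    record("qc", [p_stats, p_div, p_vcf])
    summary["qc"] = {
        "n_input_loci": G.n_loci,
        "n_retained_loci": G_f.n_loci,
        "n_samples": G.n_samples,
    }
    say("qc", f"retained {G_f.n_loci} loci")
    if stop_after == "qc":
        return finish()

    # ------------------------------------------------------- structure
    try:
        pca = structure.genotype_pca(G_imp)
        adm = structure.AdmixtureModel(G_imp).fit(
            K_range=config.K_range,
            replicates=config.admixture_replicates,
            seed=config.seed,
        )
    except SoilGEAError as exc:
        raise StageError("structure", "E_STRUCT", str(exc)) from exc
    p_eig = os.path.join(config.outdir, "pca_eigenvalues.tsv")
    pd.DataFrame({"eigenvalue": pca.eigenvalues, "pve": pca.pve}).to_csv(p_eig, sep="\t", index=False)
    p_q = os.path.join(config.outdir, "admixture_Q.tsv")
    adm.q_frame().to_csv(p_q, sep="\t", index_label="sample_id")
    files = [p_eig, p_q]
    if config.fst_n_perm > 0:
        fst = structure.pairwise_fst(G_f, meta, n_perm=config.fst_n_perm, seed=config.seed)
        p_fst = os.path.join(config.outdir, "fst.tsv")
        fst.to_tsv(p_fst)
        files.append(p_fst)
    record("structure", files)
    summary["structure"] = {
        "chosen_K": adm.chosen_K,
        "cv_error": {str(k): v for k, v in adm.cv_error.items()},
        "pve_pc1": float(pca.pve[0]),
        "pve_pc2": float(pca.pve[1]) if len(pca.pve) > 1 else None,
    }
    say("structure", f"chosen K = {adm.chosen_K}")
    if stop_after == "structure":
        return finish()

    # --------------------------------------------------------- envprep
    try:
        predictors_site, env_report = envprep.prepare_predictors(
            soil, r_max=config.r_max, vif_max=config.vif_max
        )
        epca = envprep.env_pca(predictors_site, n_axes=2)
    except SoilGEAError as exc:
        raise StageError("envprep", "E_ENV", str(exc)) from exc
    p_env = os.path.join(config.outdir, "envprep_report.json")
    env_report.to_json(p_env)
    record("envprep", [p_env])
    summary["envprep"] = {
        "retained": env_report.retained,
        "royston_p": env_report.royston_p,
        "vif": env_report.vif,
    }
    say("envprep", f"retained predictors: {env_report.retained}")
    if stop_after == "envprep":
        return finish()

    # ------------------------------------------------------------- gea
    try:
        S_sample = sgio.soil_by_sample(predictors_site, meta)
        # K clusters span a rank-(K-1) subspace once the intercept is in
        K_latent = max(adm.chosen_K - 1, 1)
        res_lf = gea.latent_factor_gea(
            G_imp, S_sample, K_latent=K_latent, alpha=config.gea_alpha, scale=config.scale
        )
        Qcov = adm.Q[:, :-1] if adm.chosen_K > 1 else None
        res_lg = gea.logistic_gea(
            G_imp, S_sample, structure_covariates=Qcov, alpha=config.gea_alpha, scale=config.scale
        )
        res_fe = gea.fstenv_gea(
            G_imp, meta, predictors_site, n_perm=config.fstenv_n_perm,
            seed=config.seed, alpha=config.gea_alpha, scale=config.scale,
        )
        candidates = gea.combine_candidates([res_lf, res_lg, res_fe])
    except SoilGEAError as exc:
        raise StageError("gea", "E_GEA", str(exc)) from exc
    files = []
    for res in (res_lf, res_lg, res_fe):
        p = os.path.join(config.outdir, f"gea_{res.method}.tsv")
        res.to_tsv(p)
        files.append(p)
    p_cand = os.path.join(config.outdir, "candidates.tsv")
    candidates.to_tsv(p_cand)
    p_venn = os.path.join(config.outdir, "venn_counts.json")
    with open(p_venn, "w") as fh:
        json.dump(candidates.venn_counts, fh, indent=1)
    record("gea", files + [p_cand, p_venn])
    summary["gea"] = {
        "lambda": {k: float(v) for k, v in res_lf.lambda_gif.items()},
        "method_counts": candidates.method_counts,
        "venn_counts": candidates.venn_counts,
        "n_candidates": len(candidates.loci),
        "per_variable": candidates.entries.groupby("variable").size().to_dict()
        if len(candidates.entries)
        else {},
    }
    say("gea", f"{len(candidates.loci)} candidate loci")
    if stop_after == "gea":
        return finish()

    # ------------------------------------------------------- polygenic
    try:
        n_cond = max(adm.chosen_K - 1, 1)
        conditioners = pca.scores[:, :n_cond]
        if len(candidates.loci) < 2:
            raise SoilGEAError("fewer than 2 candidate loci; polygenic model undefined")
        ens = dbr.matched_null_ensemble(
            G_imp,
            candidates,
            S_sample,
            conditioners,
            n_sets=config.n_null_sets,
            maf_bin=config.maf_bin,
            n_perm=config.dbrda_n_perm,
            seed=config.seed,
        )
        selected, stop, fs_res = dbr.forward_select(
            dbr.bray_curtis(G_imp.subset_loci(np.asarray(candidates.loci, dtype=object))),
            S_sample,
            conditioners,
            alpha=0.05,
            n_perm=config.dbrda_n_perm,
            seed=config.seed,
        )
        transfer = None
        if config.other_scale_candidates:
            other = pd.read_csv(config.other_scale_candidates, sep="\t")
            t_res, t_cmp = dbr.cross_scale_transfer(
                list(other["locus"]), G_imp, S_sample, conditioners,
                n_perm=config.dbrda_n_perm, seed=config.seed,
                same_scale_result=ens.candidate_result, null_ensemble=ens,
            )
            transfer = t_cmp
    except SoilGEAError as exc:
        raise StageError("polygenic", "E_POLY", str(exc)) from exc
    p_db = os.path.join(config.outdir, "dbrda_candidates.json")
    ens.candidate_result.to_json(p_db)
    p_null = os.path.join(config.outdir, "null_ensemble.json")
    ens.to_json(p_null)
    files = [p_db, p_null]
    if ens.candidate_result.axis_scores is not None:
        p_sc = os.path.join(config.outdir, "dbrda_scores.tsv")
        sc = ens.candidate_result.axis_scores
        pd.DataFrame(
            sc, index=G_imp.sample_ids,
            columns=[f"CAP{i + 1}" for i in range(sc.shape[1])],
        ).to_csv(p_sc, sep="\t", index_label="sample_id")
        files.append(p_sc)
    record("polygenic", files)
    summary["polygenic"] = {
        "inertia": ens.candidate_result.inertia,
        "proportions": ens.candidate_result.proportions,
        "r2_adj": ens.candidate_result.r2_adj,
        "p_value": ens.candidate_result.p_value,
        "exceedance_rank": ens.exceedance_rank,
        "null_constrained_mean": float(ens.null_constrained.mean()),
        "forward_selected": selected,
        "forward_stop": stop,
        "transfer": transfer,
    }
    say("polygenic", f"candidate constrained proportion "
        f"{ens.candidate_result.proportions['constrained']:.3f}, "
        f"exceedance rank {ens.exceedance_rank}/{config.n_null_sets + 1}")
    if stop_after == "polygenic":
        return finish()

    # --------------------------------------------------------- spatial
    try:
        sites = meta.drop_duplicates("population")
        coords = sites[["longitude", "latitude"]].to_numpy()
        net = spatial.build_connection_network(coords, k=min(config.spca_k, len(coords) - 1))
        node_of = {p: i for i, p in enumerate(sites["population"])}
        sample_nodes = meta["population"].map(node_of).to_numpy()
        Gc = G_imp.subset_loci(np.asarray(candidates.loci, dtype=object))
        sp = spatial.spca(Gc, net, n_axes=config.n_axes, sample_nodes=sample_nodes)
        epc_sample = sgio.soil_by_sample(epca.scores, meta)
        reg_pred = pd.concat(
            [S_sample.reset_index(drop=True), epc_sample.reset_index(drop=True)], axis=1
        )
        clines = spatial.stepwise_cline_regression(sp.lagged_scores, reg_pred)
    except SoilGEAError as exc:
        raise StageError("spatial", "E_SPATIAL", str(exc)) from exc
    p_sp = os.path.join(config.outdir, "spca_scores.tsv")
    sp.frame().to_csv(p_sp, sep="\t", index_label="sample_id")
    p_cl = os.path.join(config.outdir, "cline_regressions.json")
    with open(p_cl, "w") as fh:
        json.dump(
            [
                {
                    "axis": c.axis,
                    "univariate": c.univariate.to_dict(orient="records"),
                    "stepwise_terms": c.stepwise_terms,
                    "stepwise_coef": c.stepwise_coef,
                    "stepwise_r2_adj": c.stepwise_r2_adj,
                    "stepwise_p": c.stepwise_p,
                }
                for c in clines
            ],
            fh,
            indent=1,
        )
    record("spatial", [p_sp, p_cl])
    summary["spatial"] = {
        "eigenvalues": list(map(float, sp.eigenvalues[: config.n_axes])),
        "axis_moran": list(map(float, sp.axis_moran)),
        "cline_r2_adj": [c.stepwise_r2_adj for c in clines],
        "cline_terms": [c.stepwise_terms for c in clines],
    }

    return finish()
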