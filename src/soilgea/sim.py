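"""Synthetic metapopulation, soil-chemistry and genotype generator.

The generator emulates the sampling design of a range-wide plus local
landscape-genomics survey of a montane conifer: a handful of genetic
clusters, each holding several small populations of diploids, genotyped
at 1,500-2,000 biallelic SNPs, with site-level soil chemistry (pH, EC,
OC, OM, Ca2+, K+, Mg2+, Na+, SAR) sampled from spatially autocorrelated
Gaussian fields.  Allele frequencies follow the Balding-Nichols
hierarchical Beta model, which has closed-form FST expectations: the
population frequency for drift parameter f around ancestral frequency p
is Beta(p(1-f)/f, (1-p)(1-f)/f), so E[FST] = f.  A configurable minority
of "adaptive" loci have their population frequency shifted on the logit
scale by ``beta`` per standard deviation of a chosen soil driver before
genotypes are drawn, which is exactly the signal a genotype-environment
association scan is designed to detect.

Every draw flows from a single :class:`numpy.random.Generator`, so a
given config + seed reproduces the dataset byte for byte.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import (
    GenotypeMatrix,
    ConfigurationError,
    write_vcf,
    write_metadata,
    write_soil,
)

#: soil chemistry variables, with plausible field means / SDs / floors
SOIL_VARIABLES = {
    # name: (mean, sd, floor)
    "pH": (6.0, 0.6, 3.5),
    "EC": (0.8, 0.3, 0.05),   # dS/m
    "OC": (6.0, 2.0, 0.2),    # kg/m2
    "OM": (8.0, 3.0, 0.3),    # percent
    "Ca": (10.0, 4.0, 0.5),   # cmol+/kg
    "K": (0.8, 0.3, 0.02),
    "Mg": (4.0, 1.5, 0.1),
    "Na": (0.5, 0.2, 0.01),
    "SAR": (1.5, 0.6, 0.05),
}

#: bounding box (lon_min, lon_max, lat_min, lat_max) used for synthetic
#: site coordinates; mimics a trans-Mexican volcanic-belt extent purely
#: so that great-circle distances are realistic.
DEFAULT_BBOX = (-104.0, -97.0, 18.9, 21.0)

EARTH_RADIUS_KM = 6371.0088


@dataclass
class SimConfig:
    """Study-design knobs for one simulated scale."""

    n_clusters: int = 3
    pops_per_cluster: int = 6
    samples_per_pop: int | list = 6
    n_loci: int = 1585
    prop_adaptive: float = 0.05
    f_cluster: float = 0.10
    f_pop: float = 0.05
    beta: float = 1.5
    driver_vars: tuple = ("Ca", "EC", "pH")
    soil_range: float = 50.0           # km, exponential correlation length
    soil_corr: np.ndarray | None = None
    soil_vars: tuple = tuple(SOIL_VARIABLES)
    missing_rate: float = 0.05
    tag_length_bp: int = 82
    scale_label: str = "range_wide"
    bbox: tuple = DEFAULT_BBOX
    cluster_spread_deg: float = 0.5    # geographic spread of pops in a cluster
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.f_cluster < 1 and 0 < self.f_pop < 1):
            raise ConfigurationError("f_cluster and f_pop must lie in (0, 1)")
        if not (0 <= self.prop_adaptive <= 1):
            raise ConfigurationError("prop_adaptive must lie in [0, 1]")
        if not (0 <= self.missing_rate < 1):
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if self.soil_range <= 0:
            raise ConfigurationError("soil_range must be positive")
        for v in self.driver_vars:
            if v not in self.soil_vars:
                raise ConfigurationError(f"driver variable {v!r} not among soil_vars")

    @property
    def n_pops(self) -> int:
        return self.n_clusters * self.pops_per_cluster

    @property
    def n_adaptive(self) -> int:
        return int(round(self.prop_adaptive * self.n_loci))


def local_scale_config(**overrides) -> SimConfig:
    """Defaults mimicking the local-scale design: 3 stands of ~29
    diploids with at most two weak clusters and 5 soil predictors."""
    defaults = dict(
        n_clusters=1,
        pops_per_cluster=3,
        samples_per_pop=29,
        f_cluster=0.02,
        f_pop=0.01,
        driver_vars=("EC", "OC"),
        soil_range=5.0,
        cluster_spread_deg=0.05,
        scale_label="local",
        bbox=(-99.9, -99.8, 19.1, 19.2),
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@dataclass
class TruthRecord:
    """Ground truth of a simulated dataset, for recovery tests."""

    adaptive_loci: list
    driver_of: dict           # locus id -> soil variable name
    beta_of: dict             # locus id -> effect size
    cluster_of: dict          # population id -> cluster id
    pop_freqs: pd.DataFrame   # populations x loci allele frequencies

    def to_json(self, path: str) -> str:
        payload = {
            "adaptive_loci": list(self.adaptive_loci),
            "driver_of": self.driver_of,
            "beta_of": self.beta_of,
            "cluster_of": {str(k): int(v) for k, v in self.cluster_of.items()},
            "pop_freqs": {
                "index": list(map(str, self.pop_freqs.index)),
                "columns": list(map(str, self.pop_freqs.columns)),
                "values": self.pop_freqs.to_numpy().tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)
        return path

    @classmethod
    def from_json(cls, path: str) -> "TruthRecord":
        with open(path) as fh:
            d = json.load(fh)
        pf = pd.DataFrame(
            np.asarray(d["pop_freqs"]["values"]),
            index=d["pop_freqs"]["index"],
            columns=d["pop_freqs"]["columns"],
        )
        return cls(
            adaptive_loci=d["adaptive_loci"],
            driver_of=d["driver_of"],
            beta_of={k: float(v) for k, v in d["beta_of"].items()},
            cluster_of={k: int(v) for k, v in d["cluster_of"].items()},
            pop_freqs=pf,
        )


# ----------------------------------------------------------------------
# geometry
# ----------------------------------------------------------------------

def haversine_km(coords_a: np.ndarray, coords_b: np.ndarray | None = None) -> np.ndarray:
    """Great-circle distance matrix (km) between (lon, lat) rows."""
    a = np.radians(np.asarray(coords_a, dtype=float))
    b = a if coords_b is None else np.radians(np.asarray(coords_b, dtype=float))
    lon1, lat1 = a[:, 0][:, None], a[:, 1][:, None]
    lon2, lat2 = b[:, 0][None, :], b[:, 1][None, :]
    dlon, dlat = lon2 - lon1, lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def simulate_metadata(config: SimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Sample site coordinates and population/cluster labels.

    Cluster centres are spread along the bounding box so that clusters
    are geographically coherent (needed for cline-like spatial signal).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    lon0, lon1, lat0, lat1 = config.bbox
    centers_lon = np.linspace(lon0 + 0.1 * (lon1 - lon0), lon1 - 0.1 * (lon1 - lon0), config.n_clusters)
    centers_lat = rng.uniform(lat0, lat1, size=config.n_clusters)
    rows = []
    spp = config.samples_per_pop
    sizes = (
        list(spp) if isinstance(spp, (list, tuple)) else [spp] * config.n_pops
    )
    if len(sizes) != config.n_pops:
        raise ConfigurationError("samples_per_pop list must have one entry per population")
    p = 0
    for c in range(config.n_clusters):
        for _ in range(config.pops_per_cluster):
            lon = np.clip(centers_lon[c] + rng.normal(0, config.cluster_spread_deg), lon0, lon1)
            lat = np.clip(centers_lat[c] + rng.normal(0, config.cluster_spread_deg), lat0, lat1)
            elev = rng.uniform(2400, 3600)
            pop = f"P{p:02d}"
            for i in range(sizes[p]):
                rows.append(
                    dict(
                        sample_id=f"{pop}_{i:02d}",
                        population=pop,
                        longitude=round(float(lon), 5),
                        latitude=round(float(lat), 5),
                        elevation=round(float(elev), 1),
                        scale=config.scale_label,
                        cluster=c,
                    )
                )
            p += 1
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# soil fields
# ----------------------------------------------------------------------

def simulate_soil(
    site_coords,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    site_ids=None,
) -> pd.DataFrame:
    """Draw soil chemistry as spatially autocorrelated Gaussian fields.

    Each variable is a zero-mean unit field with exponential covariance
    exp(-d / soil_range) over great-circle distances; variables are then
    linearly mixed through the Cholesky factor of ``soil_corr`` and
    shifted/scaled into plausible positive ranges.
    """
    coords = np.asarray(site_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[0] < 2:
        raise ConfigurationError("need at least two distinct sites")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    nvars = len(config.soil_vars)
    corr = np.eye(nvars) if config.soil_corr is None else np.asarray(config.soil_corr, float)
    if corr.shape != (nvars, nvars) or not np.allclose(corr, corr.T):
        raise ConfigurationError("soil_corr must be a symmetric matrix matching soil_vars")
    try:
        mix = np.linalg.cholesky(corr + 1e-10 * np.eye(nvars))
    except np.linalg.LinAlgError as exc:
        raise ConfigurationError("soil_corr is not positive semidefinite") from exc

    d = haversine_km(coords)
    cov = np.exp(-d / config.soil_range)
    # jitter for numerical PSD at near-duplicate sites
    spat = np.linalg.cholesky(cov + 1e-8 * np.eye(len(coords)))
    z = spat @ rng.standard_normal((len(coords), nvars))  # independent fields
    z = z @ mix.T                                          # cross-correlated

    data = {}
    for j, name in enumerate(config.soil_vars):
        mean, sd, floor = SOIL_VARIABLES[name]
        data[name] = np.maximum(mean + sd * z[:, j], floor)
    index = (
        [f"S{i:02d}" for i in range(len(coords))] if site_ids is None else list(site_ids)
    )
    return pd.DataFrame(data, index=pd.Index(index, name="site"))


# ----------------------------------------------------------------------
# genotypes
# ----------------------------------------------------------------------

def _balding_nichols(rng, p_anc: np.ndarray, f: float, size=None) -> np.ndarray:
    """Draw descendant allele frequencies around ``p_anc`` with drift f."""
    scale = (1.0 - f) / f
    a = np.clip(p_anc * scale, 1e-12, None)
    b = np.clip((1.0 - p_anc) * scale, 1e-12, None)
    return rng.beta(a, b, size=size)


def simulate_genotypes(
    meta: pd.DataFrame,
    soil: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Hierarchical Balding-Nichols genotypes with soil-driven loci.

    Neutral loci: ancestral p0 ~ U(0.05, 0.95); cluster frequency drawn
    Beta around p0 with f_cluster; population frequency drawn Beta
    around the cluster frequency with f_pop.  Adaptive loci additionally
    shift the population frequency by ``beta`` x standardized driver
    value on the logit scale before genotypes ~ Binomial(2, p) are
    drawn.  Missing calls are injected completely at random.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    pops = list(dict.fromkeys(meta["population"]))
    missing_pops = set(pops) - set(soil.index.astype(str))
    if missing_pops:
        raise ConfigurationError(f"soil table does not cover populations {sorted(missing_pops)}")
    if "cluster" in meta.columns:
        cluster_of = {p: int(meta.loc[meta["population"] == p, "cluster"].iloc[0]) for p in pops}
    else:
        cluster_of = {p: 0 for p in pops}
    clusters = sorted(set(cluster_of.values()))

    L = config.n_loci
    locus_ids = [f"L{j:05d}" for j in range(L)]
    p0 = rng.uniform(0.05, 0.95, size=L)
    # cluster-level frequencies
    clus_freq = np.vstack([_balding_nichols(rng, p0, config.f_cluster) for _ in clusters])
    # population-level frequencies
    pop_freq = np.vstack(
        [_balding_nichols(rng, clus_freq[cluster_of[p]], config.f_pop) for p in pops]
    )

    # adaptive loci: logit-shift population frequency along the driver
    n_adapt = config.n_adaptive
    adaptive_idx = rng.choice(L, size=n_adapt, replace=False) if n_adapt else np.array([], int)
    driver_of, beta_of = {}, {}
    drivers = list(config.driver_vars)
    if n_adapt:
        absent = [v for v in drivers if v not in soil.columns]
        if absent:
            raise ConfigurationError(f"driver variables absent from soil table: {absent}")
    for r, j in enumerate(np.sort(adaptive_idx)):
        var = drivers[r % len(drivers)]
        x = soil.loc[pops, var].to_numpy(dtype=float)
        xz = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
        pf = np.clip(pop_freq[:, j], 1e-9, 1 - 1e-9)
        pop_freq[:, j] = expit(logit(pf) + config.beta * xz)
        driver_of[locus_ids[j]] = var
        beta_of[locus_ids[j]] = float(config.beta)

    pop_index = {p: i for i, p in enumerate(pops)}
    rows_pop = meta["population"].map(pop_index).to_numpy()
    dosage = rng.binomial(2, pop_freq[rows_pop, :]).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = -1

    G = GenotypeMatrix(dosage, list(meta["sample_id"]), locus_ids)
    truth = TruthRecord(
        adaptive_loci=[locus_ids[j] for j in np.sort(adaptive_idx)],
        driver_of=driver_of,
        beta_of=beta_of,
        cluster_of=cluster_of,
        pop_freqs=pd.DataFrame(pop_freq, index=pops, columns=locus_ids),
    )
    return G, truth


def simulate_dataset(config: SimConfig):
    """Full dataset draw: metadata, soil, genotypes, truth (one seed)."""
    rng = np.random.default_rng(config.seed)
    meta = simulate_metadata(config, rng)
    sites = meta.drop_duplicates("population")
    coords = sites[["longitude", "latitude"]].to_numpy()
    soil = simulate_soil(coords, config, rng, site_ids=sites["population"])
    G, truth = simulate_genotypes(meta, soil, config, rng)
    return G, meta, soil, truth


def write_dataset(G: GenotypeMatrix, meta: pd.DataFrame, soil: pd.DataFrame,
                  truth: TruthRecord | None, outdir: str) -> dict:
    """Emit VCF + metadata TSV + soil CSV (+ truth JSON); returns paths."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "vcf": write_vcf(G, os.path.join(outdir, "genotypes.vcf")),
        "metadata": write_metadata(
            meta[[c for c in meta.columns if c != "cluster"]],
            os.path.join(outdir, "metadata.tsv"),
        ),
        "soil": write_soil(soil, os.path.join(outdir, "soil.csv")),
    }
    if truth is not None:
        paths["truth"] = truth.to_json(os.path.join(outdir, "truth.json"))
    return paths
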