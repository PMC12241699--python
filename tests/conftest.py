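import warnings

import pytest

from soilgea import SimConfig, simulate_dataset

# expected warnings from degenerate simulated panels are noise in tests
warnings.filterwarnings("ignore", message="dropping .* constant loci")
warnings.filterwarnings("ignore", message="connection network is not connected")
warnings.filterwarnings("ignore", message="MAF bin .* short of non-candidates")


@pytest.fixture(scope="session")
def three_cluster_dataset():
    """3 clusters x 4 pops x 8 diploids, 500 loci, 6% adaptive (beta=2),
    complete calls; shared across read-only structure/GEA tests."""
    cfg = SimConfig(
        n_clusters=3,
        pops_per_cluster=4,
        samples_per_pop=8,
        n_loci=500,
        prop_adaptive=0.06,
        beta=2.0,
        f_cluster=0.10,
        f_pop=0.02,
        missing_rate=0.0,
        driver_vars=("Ca", "EC"),
        seed=20250901,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_missing_dataset():
    """Small panel with 5% missing calls for QC/imputation tests."""
    cfg = SimConfig(
        n_clusters=2,
        pops_per_cluster=3,
        samples_per_pop=10,
        n_loci=300,
        prop_adaptive=0.0,
        f_cluster=0.08,
        f_pop=0.05,
        missing_rate=0.05,
        seed=7,
    )
    return simulate_dataset(cfg)

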