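import numpy as np
import pandas as pd
import pytest

from polycage.pipeline import RunConfig, run_all
from polycage.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=0, n_genes=60, n_multi_tss_genes=20, n_enhancers=10
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def pipeline_result(small_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("run")
    cfg = RunConfig(outdir=str(outdir), seed=0, simulation=small_config)
    return run_all(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def nb_counts(rng, mean, dispersion, size):
    """Shared NB sampler for simulation-based tests."""
    n = 1.0 / dispersion
    p = n / (n + np.asarray(mean, dtype=float))
    return rng.negative_binomial(n, p, size=size)


@pytest.fixture()
def toy_track_frame():
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 4,
            "pos": [100, 101, 200, 300],
            "strand": ["+", "+", "-", "+"],
            "count": [3, 4, 5, 8],
        }
    )
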