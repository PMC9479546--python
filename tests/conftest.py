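import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import floranet as fn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> fn.SimConfig:
    """A small but full-featured study: 400 genes, hub block, planted DE."""
    return fn.SimConfig(n_genes=400, seed=42)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    counts, truth = fn.simulate_counts(small_config)
    return counts, truth


@pytest.fixture(scope="session")
def small_fpkm(small_dataset):
    counts, _ = small_dataset
    return fn.compute_fpkm(counts)


@pytest.fixture(scope="session")
def design(small_config):
    return small_config.design()


@pytest.fixture(scope="session")
def scheme(design):
    return {c.name: c for c in fn.build_contrast_scheme(design)}
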