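import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from boostae import (NOISE_FACTOR_STAIRLIKE, TrainConfig, default_timeseries_design,
                     simulate_binary_groups, stairlike_design,
                     standardize_and_rescale_noise, standardized_bundle)
from boostae.simulate import NOISE_FACTOR_TIMESERIES


@pytest.fixture(scope="session")
def table1_design():
    return default_timeseries_design()


@pytest.fixture(scope="session")
def table1_standardized(table1_design):
    """Standardized per-time-point matrices of the time-structured design."""
    bundle = simulate_binary_groups(table1_design, seed=7)
    return [s.values for s in standardized_bundle(bundle, NOISE_FACTOR_TIMESERIES)], bundle


def stairlike_matrix(seed, cells_per_group=100):
    """Standardized stair-like data with damped noise columns (none by default
    layout: every gene belongs to a block, so the factor is a no-op there)."""
    design = stairlike_design(cells_per_group=cells_per_group)
    bundle = simulate_binary_groups(design, seed)
    X = standardize_and_rescale_noise(bundle.matrices[0], sorted(design.noise_genes),
                                      NOISE_FACTOR_STAIRLIKE).values
    return X, bundle.group_labels[0], design


@pytest.fixture(scope="session")
def stairlike_small():
    """Reduced stair-like dataset for fast unit tests."""
    return stairlike_matrix(seed=3, cells_per_group=30)


def rng_standardized(rng, n, p):
    """Random matrix with z-scored columns."""
    X = rng.normal(size=(n, p))
    return (X - X.mean(0)) / X.std(0, ddof=1)
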