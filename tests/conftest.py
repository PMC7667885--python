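import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from chromaprime import (
    SimulationConfig,
    apply_factors,
    count_cuts,
    make_windows,
    pool_summits,
    simulate_experiment,
    topn_median_factors,
)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale simulation: small enough for fast unit tests, large
    enough that class structure is recoverable."""
    return SimulationConfig(
        n_chroms=2,
        chrom_length=2_000_000,
        n_dependent_primed=30,
        n_inducible=30,
        n_invariant=120,
        n_genes=40,
        seed=12345,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_experiment(small_config)


@pytest.fixture(scope="session")
def small_matrices(small_dataset):
    """(windows, raw matrix, normalized matrix) for the small dataset."""
    union = pool_summits(small_dataset.summits.values())
    windows = make_windows(union)
    raw = count_cuts(windows, small_dataset.cut_tracks)
    factors = topn_median_factors(raw, n_top=len(windows))
    norm = apply_factors(raw, factors)
    return windows, raw, norm


@pytest.fixture
def rng():
    return np.random.default_rng(77)
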