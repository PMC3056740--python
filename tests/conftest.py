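import numpy as np
import pytest

from mitoflow import (
    PartitionParams,
    TransferParams,
)
from mitoflow.simulate import SimConfig, default_edges, sample_to_histograms, simulate_pair


@pytest.fixture(scope="session")
def u2os_params() -> TransferParams:
    """Operating point measured on QD-labelled U2-OS cells: mean splitting
    ratio 0.71, spread 0.11, dividing fraction 0.98 over a 19 h interval."""
    return TransferParams(PartitionParams(0.71, 0.11), 0.98, interval_h=19.0)


@pytest.fixture(scope="session")
def make_pair():
    """Factory: simulate a measurement pair and bin it on shared linear edges."""

    def _make(params: TransferParams, n: int, seed: int, bins: int = 256):
        cfg = SimConfig(n_cells=n, params=params, seed=seed)
        sample = simulate_pair(cfg)
        h0, ht = sample_to_histograms(
            sample, default_edges(sample, bins), interval_h=params.interval_h
        )
        return h0, ht, sample

    return _make


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20250925)
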