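import numpy as np
import pytest
from hypothesis import settings

import bmhnet as B

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def example1():
    """The five-node worked-example digraph."""
    return B.example1_graph()


@pytest.fixture(scope="session")
def example_grid():
    return B.ThresholdGrid(0.0, 0.5, 6)


@pytest.fixture(scope="session")
def small_spaces():
    """A handful of random closed quasimetric spaces for property tests."""
    return [B.random_quasimetric(8, seed) for seed in range(6)]


@pytest.fixture(scope="session")
def tiny_partition():
    """Three regions per subnetwork (27 regions total)."""
    return B.default_partition(3)


def var_series(coupling, T=200, seed=0, noise_sd=1.0):
    coupling = np.asarray(coupling, dtype=float)
    return B.var1_timeseries(
        B.VARSpec(n_regions=coupling.shape[0], coupling=coupling,
                  noise_sd=noise_sd, T=T, seed=seed)
    )
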