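import numpy as np
import pytest

import microswitch as ms


@pytest.fixture(scope="session")
def small_spec() -> ms.SyntheticSpec:
    """Two ensembles, one replica each, small enough for fast I/O tests."""
    return ms.SyntheticSpec(
        n_ensembles=2,
        replicas_per_ensemble=1,
        n_frames=400,
        n_residues=6,
        n_microstates=3,
        coupled_residues=[(1, 1.0)],
        seed=42,
    )


@pytest.fixture(scope="session")
def small_ensemble(small_spec):
    return ms.simulate_ensemble(small_spec)


@pytest.fixture(scope="session")
def scheme():
    return ms.build_default_scheme()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
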