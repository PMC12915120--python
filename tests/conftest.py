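import numpy as np
import pytest

from cellsqueeze3d import NucleusObservation, SwarmConfig, TissueParams, generate_tissue


@pytest.fixture(scope="session")
def small_tissue():
    """A 20-cell feasible packing with its 2D observations."""
    params = TissueParams(n_cells=20, field_size=(256.0, 256.0))
    return generate_tissue(params, seed=42)


@pytest.fixture(scope="session")
def default_config():
    return SwarmConfig()


@pytest.fixture()
def fast_config():
    """Small swarm settings for quick optimizer tests."""
    return SwarmConfig(n_swarm=10, T=15, seed=0)


@pytest.fixture()
def three_nuclei():
    return [
        NucleusObservation(id=1, x=10.0, y=10.0, r_nuc=4.0),
        NucleusObservation(id=2, x=40.0, y=12.0, r_nuc=3.0),
        NucleusObservation(id=3, x=25.0, y=40.0, r_nuc=5.0),
    ]


def random_configuration(rng, n, box=100.0, r_lo=2.0, r_hi=8.0):
    """Random centers and nuclear radii for penalty-oracle tests."""
    centers = rng.uniform(0, box, size=(n, 3))
    r_nuc = rng.uniform(r_lo, r_hi, size=n)
    return centers, r_nuc
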