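import numpy as np
import pytest

from celldosim import build_cho_cell
from celldosim.geometry import PlacementSpec, place_nanoparticles


@pytest.fixture(scope="session")
def default_geom():
    """Default cell (nucleus + 90 mitochondria), fixed seed, shared
    read-only across tests."""
    return build_cho_cell(rng=np.random.default_rng(0))


@pytest.fixture(scope="session")
def small_geom():
    """A small world (5 mitochondria, 10 nanoparticles) for brute-force
    cross-checks."""
    geom = build_cho_cell(n_mitochondria=5, rng=np.random.default_rng(1))
    place_nanoparticles(geom, PlacementSpec(n_np=10, r_np=50.0,
                                            fraction_targeted=0.5),
                        np.random.default_rng(2))
    return geom
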