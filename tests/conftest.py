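import numpy as np
import pytest

import memfes as m


@pytest.fixture(scope="session")
def toy_protein():
    return m.build_toy_protein(seed=1)


@pytest.fixture(scope="session")
def membrane():
    """Anionic mixture: BMP:CHOL:SM:DOPG:POPC = 20:10:0:0:70."""
    return m.build_membrane_patch([20, 10, 0, 0, 70], 200, seed=2)


@pytest.fixture(scope="session")
def popc_membrane():
    """Flat single-species bilayer: leaflet P COMs align exactly."""
    return m.build_membrane_patch([0, 0, 0, 0, 100], 100, seed=3)


@pytest.fixture(scope="session")
def landscape():
    return m.two_basin_landscape()


@pytest.fixture(scope="session")
def small_campaign(landscape):
    """Short full-layout campaign shared by estimator tests."""
    scheme = m.build_window_scheme(-10.0, 42.0, 4, 1, k=10.0)
    params = m.LangevinParams(n_steps=20000, seed=11, frame_stride=20)
    return m.run_campaign(landscape, scheme, params=params,
                          exchange_stride=250)


def point_structure(xyz, charges=None, radii=None, species="ION",
                    box=(10.0, 10.0, 10.0)):
    """Minimal structure from bare coordinates, for geometry tests."""
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    n = len(xyz)
    return m.ToyStructure(
        names=np.full(n, "X", dtype="U4"),
        resids=np.arange(1, n + 1),
        resnames=np.full(n, species[:4], dtype="U4"),
        species=np.full(n, species, dtype="U4"),
        xyz=xyz,
        charges=np.zeros(n) if charges is None else np.asarray(charges, float),
        radii=np.full(n, 0.2) if radii is None else np.asarray(radii, float),
        box=np.asarray(box, dtype=float),
    )
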