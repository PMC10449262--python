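import math

import numpy as np
import pytest

from octoprops import (
    AScanProfile,
    DepthGrid,
    LayerSpec,
    PhantomSpec,
    make_phantom2,
    simulate_aline,
)
from octoprops.forward_model import phantom2_grid


@pytest.fixture(scope="session")
def phantom2():
    return make_phantom2()


@pytest.fixture(scope="session")
def grid2():
    return phantom2_grid()


@pytest.fixture(scope="session")
def phantom2_aline(phantom2, grid2) -> AScanProfile:
    return simulate_aline(phantom2, grid2)


def make_homogeneous(
    mu: float = 2.0,
    R: float = 0.005,
    beta_L0: float = 1.0,
    surface: float = 0.125,
    dz: float = 0.001,
    depth: float = 3.0,
):
    phantom = PhantomSpec(
        surface_depth=surface,
        layers=(LayerSpec(thickness=math.inf, mu=mu, R=R),),
        beta_L0=beta_L0,
    )
    grid = DepthGrid(0.0, dz, int(round(depth / dz)))
    return phantom, grid, simulate_aline(phantom, grid)


@pytest.fixture()
def homogeneous():
    return make_homogeneous()


@pytest.fixture(scope="session")
def retina_bscan_small():
    """Reduced-count retinal Monte Carlo B-scan shared by the slow tests."""
    from octoprops.mc_sim import retina_scene, simulate_bscan

    return simulate_bscan(retina_scene(), n_photons_per_aline=100_000,
                          n_alines=20, seed=20231)
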