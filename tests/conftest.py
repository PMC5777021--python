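import numpy as np
import pytest

from gridspac.soil_params import SoilHydraulics, build_profile
from gridspac.synthetic_data import dairy_north_fixture


@pytest.fixture(scope="session")
def dairy():
    """The 30-cell Dairy North fixture (shared, treat as read-only)."""
    return dairy_north_fixture()


@pytest.fixture
def loam_hydraulics():
    """A moderately coarse loam: mild retention curve, fast convergence."""
    return SoilHydraulics(theta_s=0.45, theta_r=0.05, vg_alpha=2.0,
                          vg_n=1.6, K_sat=0.3)


@pytest.fixture
def uniform_profile(loam_hydraulics):
    """Ten uniform 0.1 m layers of loam, pipe at 0.8 m."""
    return build_profile([0.1] * 10, [loam_hydraulics] * 10, pipe_depth=0.8)


@pytest.fixture
def chemistry_profile(loam_hydraulics):
    """Five 0.2 m layers with non-trivial initial chemistry."""
    chem = [{"NH4": 2.0, "NO3": 5.0, "DOC": 30.0, "som_fast_c": 800.0,
             "som_slow_c": 30000.0, "som_cn": 9.0, "pH": 5.8}
            for _ in range(5)]
    return build_profile([0.2] * 5, [loam_hydraulics] * 5, chem,
                         pipe_depth=0.8)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
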