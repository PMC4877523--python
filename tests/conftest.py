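import numpy as np
import pytest

from aridpatch import RainfallRegime, SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cfg():
    """5x5 grid at the standard calibration, short horizon."""
    return SimConfig(nx=5, ny=5, T_end=10.0,
                     rain=RainfallRegime("constant", R0=0.3))


@pytest.fixture
def unit_cfg():
    """1 m parcels: per-parcel biomass totals and densities coincide."""
    return SimConfig(nx=8, ny=8, dx=1.0, T_end=10.0,
                     rain=RainfallRegime("constant", R0=0.3))


@pytest.fixture
def saturating_cfg():
    """Parent-model (saturating) infiltration variant, for the analytic
    bare-soil equilibrium and the hand-evaluated infiltration examples."""
    return SimConfig(nx=5, ny=5, T_end=10.0,
                     infiltration_literal_denominator=False,
                     rain=RainfallRegime("constant", R0=0.3))
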