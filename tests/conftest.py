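"""Shared fixtures: reference parameter sets and reusable simulations.

Expensive full-resolution runs are session-scoped so several tests can share
one integration.
"""

import numpy as np
import pytest

from fibrolysis import (
    Conditions,
    KineticParams,
    MaterialGeometry,
    simulate,
    yields,
)

# fitted rate parameters at the three calibration temperatures (Kelvin)
CALIBRATED = {
    383.15: KineticParams(k_a=2.0630e-4, k_b=1.5434e-5, k_d=7.9618e-9, alpha=0.32016),
    398.15: KineticParams(k_a=5.7028e-4, k_b=5.7128e-5, k_d=5.3401e-8, alpha=0.17809),
    413.15: KineticParams(k_a=1.6667e-2, k_b=1.2914e-4, k_d=2.6999e-7, alpha=0.05211),
}

# Arrhenius constants derived from the calibrated rates
ARRHENIUS_CONSTANTS = {
    "k_a": (1.6467e22, 1.9129e5),
    "k_b": (8.9850e7, 9.3422e4),
    "k_d": (9.9506e12, 1.54675e5),
}

ALPHA_LAW_CONSTANTS = (4.1820e9, 6.0514e-2)


@pytest.fixture(scope="session")
def params_110C():
    return CALIBRATED[383.15]


@pytest.fixture(scope="session")
def default_geom():
    return MaterialGeometry()


@pytest.fixture
def small_geom():
    """Reduced chain system and coarse grid for fast unit tests."""
    return MaterialGeometry(N=12, m=4, n_fibre=6, n_hydro=4)


@pytest.fixture
def small_cond():
    t_end = 120 * 60.0
    return Conditions(T=383.15, t_end=t_end, output_times=np.linspace(0, t_end, 25))


@pytest.fixture(scope="session")
def small_trajectory():
    """One coarse two-region trajectory with all couplings active."""
    geom = MaterialGeometry(N=12, m=4, n_fibre=6, n_hydro=4)
    t_end = 240 * 60.0
    cond = Conditions(T=383.15, t_end=t_end, output_times=np.linspace(0, t_end, 33))
    params = KineticParams(k_a=2.06e-4, k_b=1.54e-5, k_d=4e-8, alpha=0.32)
    traj = simulate(geom, cond, params)
    return geom, cond, params, traj


@pytest.fixture(scope="session")
def full_simulation_110C(default_geom, params_110C):
    """Full-resolution 110 degC run with the calibrated parameters."""
    t_end = 360 * 60.0
    cond = Conditions(
        T=383.15, C_H=51.0, t_end=t_end, output_times=np.linspace(0, t_end, 61)
    )
    traj = simulate(default_geom, cond, params_110C)
    series = yields(traj, default_geom, params_110C, include_solid=True)
    return cond, traj, series
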