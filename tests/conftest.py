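import logging

import numpy as np
import pytest

from dscfit.io import Thermogram
from dscfit.models import apparent_heat_capacity, simulate_fractions, single_scan


@pytest.fixture(autouse=True)
def _quiet_logs():
    logging.disable(logging.INFO)
    yield
    logging.disable(logging.NOTSET)


@pytest.fixture
def noise_free_first():
    """Noise-free first-run thermogram for a given model (factory)."""

    def _make(model, T0=293.15, T_end=373.15, rate=1 / 60, grid_step=0.1):
        traj = simulate_fractions(model, single_scan(T0, T_end, rate), grid_step)
        T, Cp = apparent_heat_capacity(model, traj, "first")
        return Thermogram(T=T, Cp=Cp, rate=rate)

    return _make


def brute_force_native_fraction(p, T_grid, v, x0=1.0, step=0.001):
    """Independent fixed-step (RK4, 0.001 K) integration of dx/dT = -(k/v) x.

    Oracle for the closed-form/quadrature propagation of one irreversible
    step; deliberately shares no code with the package's fast paths.
    """
    from dscfit.thermo import R

    def k(T):
        return np.exp(-(p.E / R) * (1.0 / T - 1.0 / p.Tf))

    out = np.empty(len(T_grid))
    x = x0
    T = T_grid[0]
    out[0] = x
    for i in range(1, len(T_grid)):
        target = T_grid[i]
        h = step if target > T else -step
        while abs(target - T) > abs(h) / 2:
            hh = h if abs(target - T) > abs(h) else target - T
            f = lambda TT, xx: -(k(TT) / v) * xx
            k1 = f(T, x)
            k2 = f(T + hh / 2, x + hh / 2 * k1)
            k3 = f(T + hh / 2, x + hh / 2 * k2)
            k4 = f(T + hh, x + hh * k3)
            x = x + hh / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            T = T + hh
        out[i] = x
    return out
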