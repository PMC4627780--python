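"""Shared fixtures: reference parameter sets, designs, and a fixed-step
RK4 integrator used as an independent oracle for the ODE solver."""

import numpy as np
import pytest

from odmgrowth import ModelParams, ObservationDesign

# Four-parameter optimum from the rich colon-carcinoma validation study.
RIBBA = dict(kp=0.0058, kRp=13.37, KH=25.9, KN=20.2)

# Two-parameter optimum for the Colo205 xenograft (KH/KN held fixed).
COLO205 = dict(kp=0.0005, kRp=3.17)

DAYS_3_PER_WEEK = (0.0, 2.0, 4.0, 7.0, 9.0, 11.0, 14.0, 16.0, 18.0, 21.0, 23.0, 25.0, 28.0)
DAYS_WEEKLY = (7.0, 14.0, 21.0, 28.0)


@pytest.fixture
def ribba_params() -> ModelParams:
    return ModelParams(**RIBBA)


@pytest.fixture
def colo205_params() -> ModelParams:
    return ModelParams(kp=COLO205["kp"], kRp=COLO205["kRp"], KH=RIBBA["KH"], KN=RIBBA["KN"])


@pytest.fixture
def rich_design() -> ObservationDesign:
    """Volume 3x/week plus weekly hypoxia and necrosis over 28 days."""
    return ObservationDesign.from_days(DAYS_3_PER_WEEK, DAYS_WEEKLY, DAYS_WEEKLY, VTo=0.1)


@pytest.fixture
def volume_only_design() -> ObservationDesign:
    return ObservationDesign.from_days(DAYS_3_PER_WEEK, VTo=0.1)


def rk4(rhs, y0, t_end, dt):
    """Fixed-step classical Runge-Kutta; independent of the LSODA path."""
    y = np.asarray(y0, dtype=float).copy()
    t = 0.0
    n_steps = int(round(t_end / dt))
    for _ in range(n_steps):
        k1 = rhs(y)
        k2 = rhs(y + 0.5 * dt * k1)
        k3 = rhs(y + 0.5 * dt * k2)
        k4 = rhs(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return y


def naive_shell_oxygen(i, n, VT, VTo, kRp, Pmax):
    """Direct, numerically naive evaluation of the per-shell oxygen
    formula (inside-out summation form); oracle for the stable path."""
    rT = VT ** (1.0 / 3.0)
    Pb = Pmax * (VTo / VT) ** (2.0 / 3.0)
    c = np.cosh(kRp * rT)
    return Pb * (1.0 / c + (i / n) * (1.0 - 1.0 / c))
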