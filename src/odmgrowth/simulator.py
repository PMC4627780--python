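"""Forward integration of the oxygen-driven growth model.

The state is the vector of material shell volumes (plus the stromal
compartment for the extended model).  Oxygen is algebraic — recomputed from
the current total volume at every right-hand-side evaluation — which is the
quasi-steady-state limit of oxygen equilibrating much faster than cell
division.  Hypoxic and necrotic volumes are algebraic partitions of the
state evaluated at the requested output times; they are never integrated.

Integration uses LSODA (``scipy.integrate.odeint``) with a hand-derived
analytic Jacobian; dense output is interpolated to the requested times and
solver steps are never forced onto observation times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .model_core import (
    ModelParams,
    StromaParams,
    initial_shell_volumes,
    partition_volume,
    shell_index_fractions,
    _sech,
)

__all__ = [
    "Trajectory",
    "IntegrationError",
    "simulate",
    "simulate_stroma",
    "closed_form_flat_oxygen",
    "growth_rate_window",
    "GROWTH_RATE_THRESHOLD",
]

#: Mean growth-rate threshold (cm^3/day) splitting slower- from
#: faster-growing xenografts (SGX vs FGX).
GROWTH_RATE_THRESHOLD = 0.05

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails to produce a trajectory."""


@dataclass
class Trajectory:
    """Time-indexed output of a forward simulation.

    ``shell_volumes`` is (T, n): volume of each material shell at each
    output time.  ``shell_oxygen`` is (T, n): the oxygen tension driving
    each shell (shell-centre index by default), centre to rim.  ``VH``/``VN``
    are the total hypoxic/necrotic volumes; ``VS`` is present only for the
    stroma-extended model.
    """

    times: np.ndarray
    shell_volumes: np.ndarray
    shell_oxygen: np.ndarray
    VT: np.ndarray
    VH: np.ndarray
    VN: np.ndarray
    VS: np.ndarray | None = None
    orientation: str = "complement"

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per (time, shell)."""
        T, n = self.shell_volumes.shape
        rows = {
            "time_day": np.repeat(self.times, n),
            "shell": np.tile(np.arange(1, n + 1), T),
            "volume_cm3": self.shell_volumes.ravel(),
            "oxygen_mmHg": self.shell_oxygen.ravel(),
            "VT": np.repeat(self.VT, n),
            "VH": np.repeat(self.VH, n),
            "VN": np.repeat(self.VN, n),
            "VS": np.repeat(self.VS if self.VS is not None else np.zeros(T), n),
        }
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot(self, ax=None):
        """Growth-curve figure: total, hypoxic and necrotic volume vs time."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.VT, label="total", color="tab:blue")
        ax.plot(self.times, self.VH, label="hypoxic", color="tab:orange")
        ax.plot(self.times, self.VN, label="necrotic", color="tab:red")
        if self.VS is not None:
            ax.plot(self.times, self.VS, label="stroma", color="tab:green")
        ax.set_xlabel("time (days)")
        ax.set_ylabel("volume (cm$^3$)")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# Right-hand sides and analytic Jacobians (fast scalar paths; must agree
# with model_core.growth_rhs / stroma_rhs, which the tests verify)


def _oxygen_and_dP(y, f, VTo, kRp, Pmax):
    """Driving oxygen P_i per shell and dP_i/dVT at the current state.

    ``f`` holds the index fractions of the shells (centre or outer, see
    :func:`odmgrowth.model_core.shell_index_fractions`).
    """
    VT = float(np.sum(y))
    if VT <= 0.0:
        return None
    rT = VT ** (1.0 / 3.0)
    Pb = Pmax * (VTo / VT) ** (2.0 / 3.0)
    x = kRp * rT
    s = _sech(x)
    th = math.tanh(x)
    g = f + (1.0 - f) * s
    P = Pb * g
    # dP/dVT = -(2/3) Pb g / VT + Pb (1-f) * d sech/drT * drT/dVT
    dsdVT = -kRp * s * th * rT / (3.0 * VT)  # (1/3) VT^{-2/3} = rT/(3 VT)
    dP = -(2.0 / 3.0) * P / VT + Pb * (1.0 - f) * dsdVT
    return VT, P, dP


def _rhs_base(y, t, kp, kRp, Pmax, f, VTo):
    out = _oxygen_and_dP(y, f, VTo, kRp, Pmax)
    if out is None:
        return np.zeros(f.size)
    _, P, _ = out
    return kp * P * y


def _jac_base(y, t, kp, kRp, Pmax, f, VTo):
    n = f.size
    out = _oxygen_and_dP(y, f, VTo, kRp, Pmax)
    if out is None:
        return np.zeros((n, n))
    _, P, dP = out
    J = np.outer(kp * y * dP, np.ones(n))
    J[np.diag_indices(n)] += kp * P
    return J


def _rhs_stroma(y, t, kPG, kS, kRp, Pmax, f, VTo):
    n = f.size
    V, VS = y[:n], y[n]
    out = _oxygen_and_dP(V, f, VTo, kRp, Pmax)
    dy = np.empty(n + 1)
    if out is None:
        dy[:] = 0.0
        return dy
    VT, P, _ = out
    dy[:n] = kPG * P * V * VS
    dy[n] = kS * VT
    return dy


def _jac_stroma(y, t, kPG, kS, kRp, Pmax, f, VTo):
    n = f.size
    V, VS = y[:n], y[n]
    J = np.zeros((n + 1, n + 1))
    out = _oxygen_and_dP(V, f, VTo, kRp, Pmax)
    if out is None:
        return J
    VT, P, dP = out
    J[:n, :n] = np.outer(kPG * VS * V * dP, np.ones(n))
    J[np.arange(n), np.arange(n)] += kPG * VS * P
    J[:n, n] = kPG * P * V
    J[n, :n] = kS
    return J


# ---------------------------------------------------------------------------
# Public simulation API


def _check_times(times) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 2:
        raise ValueError("times must be a 1-D array with at least two points")
    if times[0] != 0:
        raise ValueError(f"times must start at 0, got {times[0]}")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    return times


def _integrate(rhs, jac, y0, times, args, rtol, atol, context: str):
    y, info = odeint(
        rhs,
        y0,
        times,
        args=args,
        Dfun=jac,
        rtol=rtol,
        atol=atol,
        full_output=True,
        mxstep=10000,
    )
    if info["message"] != "Integration successful.":
        raise IntegrationError(
            f"ODE integration failed for {context}: {info['message']}"
        )
    if not np.all(np.isfinite(y)):
        raise IntegrationError(f"non-finite state in {context}")
    # clamp solver-tolerance negative excursions
    np.clip(y, 0.0, None, out=y)
    return y


def _partitions(P, V, KH, KN, orientation):
    VH = np.sum(partition_volume(P, KH, V, orientation), axis=-1)
    VN = np.sum(partition_volume(P, KN, V, orientation), axis=-1)
    return VH, VN


def simulate(
    params: ModelParams,
    VTo: float,
    times: Sequence[float],
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    orientation: str = "complement",
    oxygen_index: str = "mid",
) -> Trajectory:
    """Integrate the base model from initial volume ``VTo`` over ``times``.

    ``times`` must start at 0 and be strictly increasing.  Hypoxic and
    necrotic volumes are computed algebraically from the state at each
    output time.
    """
    times = _check_times(times)
    if VTo <= 0:
        raise ValueError(f"VTo must be > 0, got {VTo}")
    n = params.n_shells
    f = shell_index_fractions(n, oxygen_index)
    y0 = initial_shell_volumes(n, VTo, params.kRp)
    y = _integrate(
        _rhs_base,
        _jac_base,
        y0,
        times,
        (params.kp, params.kRp, params.Pmax, f, VTo),
        rtol,
        atol,
        f"base model at {params}",
    )
    P = np.empty_like(y)
    for k in range(times.size):
        out = _oxygen_and_dP(np.maximum(y[k], 0.0), f, VTo, params.kRp, params.Pmax)
        P[k] = out[1] if out is not None else _oxygen_and_dP(
            np.full(n, VTo / n), f, VTo, params.kRp, params.Pmax
        )[1]
    VH, VN = _partitions(P, y, params.KH, params.KN, orientation)
    return Trajectory(
        times=times,
        shell_volumes=y,
        shell_oxygen=P,
        VT=y.sum(axis=1),
        VH=VH,
        VN=VN,
        orientation=orientation,
    )


def simulate_stroma(
    params: StromaParams,
    VTo: float,
    times: Sequence[float],
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    orientation: str = "complement",
    oxygen_index: str = "mid",
) -> Trajectory:
    """Integrate the stroma-extended model; reduces to :func:`simulate`
    when kS = 0, VS0 = 1 and kPG equals the base kp."""
    times = _check_times(times)
    if VTo <= 0:
        raise ValueError(f"VTo must be > 0, got {VTo}")
    n = params.n_shells
    f = shell_index_fractions(n, oxygen_index)
    y0 = np.append(initial_shell_volumes(n, VTo, params.kRp), params.VS0)
    y = _integrate(
        _rhs_stroma,
        _jac_stroma,
        y0,
        times,
        (params.kPG, params.kS, params.kRp, params.Pmax, f, VTo),
        rtol,
        atol,
        f"stroma model at {params}",
    )
    V, VS = y[:, :n], y[:, n]
    P = np.empty_like(V)
    for k in range(times.size):
        out = _oxygen_and_dP(np.maximum(V[k], 0.0), f, VTo, params.kRp, params.Pmax)
        P[k] = out[1] if out is not None else _oxygen_and_dP(
            np.full(n, VTo / n), f, VTo, params.kRp, params.Pmax
        )[1]
    VH, VN = _partitions(P, V, params.KH, params.KN, orientation)
    return Trajectory(
        times=times,
        shell_volumes=V,
        shell_oxygen=P,
        VT=V.sum(axis=1),
        VH=VH,
        VN=VN,
        VS=VS,
        orientation=orientation,
    )


# ---------------------------------------------------------------------------
# Analytic limit and growth-rate classification


def closed_form_flat_oxygen(kp: float, Pmax: float, VTo: float, t):
    """Exact total volume in the kR' -> 0 (flat-oxygen) limit.

    With a flat profile every shell sees P = Pmax (VTo/VT)^(2/3), so
    dVT/dt = kp Pmax VTo^(2/3) VT^(1/3), giving
    VT(t) = VTo (1 + (2/3) kp Pmax t)^(3/2).
    """
    t = np.asarray(t, dtype=float)
    out = VTo * (1.0 + (2.0 / 3.0) * kp * Pmax * t) ** 1.5
    return out if out.ndim else float(out)


def growth_rate_window(trajectory: Trajectory) -> str:
    """Classify a trajectory as faster- (FGX) or slower-growing (SGX).

    The mean growth rate (VT change over study duration) is compared with
    the 0.05 cm^3/day threshold; FGX requires a strictly greater rate, so a
    rate exactly on the threshold classifies as SGX.
    """
    t = trajectory.times
    if t.size < 2 or t[-1] <= t[0]:
        raise ValueError("trajectory must span at least two distinct times")
    rate = (trajectory.VT[-1] - trajectory.VT[0]) / (t[-1] - t[0])
    return "FGX" if rate > GROWTH_RATE_THRESHOLD else "SGX"
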