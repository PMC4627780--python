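"""Practical identifiability diagnostics for the oxygen-driven model.

Given a parameter point and an observation design (which regions — total,
hypoxic, necrotic volume — are observed at which days), the sensitivity
matrix S of the model predictions with respect to the free parameters is
built by central finite differences.  It is normalised elementwise to the
dimensionless S~_{mj} = S_{mj} * theta_j / Y_m, factorised by SVD, and
summarised by the collinearity index gamma = 1/sigma_last and condition
number kappa = sigma_1/sigma_last.  The Fisher information matrix S~^T S~
gives the count of practically identifiable parameters through its
numerical rank; the raw (unnormalised) S is kept for standard-error
covariances.  Thresholds: a parameter set is flagged identifiable when
gamma < 10 and kappa < 1000.

Only *practical* identifiability is covered here — whether the design and
data carry enough information near a parameter point.  Structural
(a-priori, symbolic) identifiability is out of scope.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .model_core import ModelParams
from .simulator import simulate

__all__ = [
    "ObservationDesign",
    "IdentifiabilityReport",
    "predictions",
    "sensitivity_matrix",
    "normalise_sensitivities",
    "collinearity_metrics",
    "fim_and_rank",
    "identifiability_report",
    "GAMMA_THRESHOLD",
    "KAPPA_THRESHOLD",
]

GAMMA_THRESHOLD = 10.0
KAPPA_THRESHOLD = 1000.0

#: Default relative finite-difference step for sensitivities.
DEFAULT_REL_STEP = 1e-6

#: Predictions below this floor (cm^3) are dropped before normalisation.
PREDICTION_FLOOR = 1e-12

_REGION_SERIES = {"T": "VT", "H": "VH", "N": "VN"}

FREE_DEFAULT = ("kp", "kRp", "KH", "KN")


@dataclass(frozen=True)
class ObservationDesign:
    """Observation points of a study: (day, region) pairs plus the initial
    volume the simulation starts from.  Region codes: T total, H hypoxic,
    N necrotic volume."""

    points: tuple
    VTo: float = 0.1

    def __post_init__(self):
        for day, region in self.points:
            if day < 0:
                raise ValueError(f"negative observation day {day}")
            if region not in _REGION_SERIES:
                raise ValueError(f"unknown region {region!r} (use T/H/N)")
        if self.VTo <= 0:
            raise ValueError(f"VTo must be > 0, got {self.VTo}")

    @classmethod
    def from_days(cls, days_t=(), days_h=(), days_n=(), VTo: float = 0.1):
        pts = [(float(d), "T") for d in days_t]
        pts += [(float(d), "H") for d in days_h]
        pts += [(float(d), "N") for d in days_n]
        return cls(points=tuple(pts), VTo=VTo)


def predictions(
    params: ModelParams,
    design: ObservationDesign,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    orientation: str = "complement",
) -> np.ndarray:
    """Model predictions at the design points (one simulation)."""
    days = sorted({d for d, _ in design.points})
    times = np.array(([0.0] if days[0] > 0 else []) + days)
    traj = simulate(params, design.VTo, times, rtol=rtol, atol=atol, orientation=orientation)
    series = {r: dict(zip(traj.times, getattr(traj, s))) for r, s in _REGION_SERIES.items()}
    return np.array([series[r][d] for d, r in design.points])


def sensitivity_matrix(
    params: ModelParams,
    design: ObservationDesign,
    free: Sequence[str] = FREE_DEFAULT,
    *,
    method: str = "fd",
    rel_step: float = DEFAULT_REL_STEP,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    orientation: str = "complement",
) -> np.ndarray:
    """Raw sensitivity matrix S (observations x free parameters).

    S_{mj} = d(prediction m)/d(theta_j).  ``method="fd"`` (default) uses
    central finite differences with relative step ``rel_step`` (absolute
    when theta_j = 0); ``method="forward"`` integrates the forward
    sensitivity equations alongside the state (exact up to solver
    tolerance, no step-size choice).
    """
    if method == "forward":
        return _forward_sensitivities(
            params, design, free, rtol=rtol, atol=atol, orientation=orientation
        )
    if method != "fd":
        raise ValueError(f"method must be 'fd' or 'forward', got {method!r}")
    cols = []
    for name in free:
        theta = getattr(params, name)
        h = rel_step * abs(theta) if theta != 0 else rel_step
        try:
            hi = predictions(
                replace(params, **{name: theta + h}),
                design, rtol=rtol, atol=atol, orientation=orientation,
            )
            lo = predictions(
                replace(params, **{name: theta - h}),
                design, rtol=rtol, atol=atol, orientation=orientation,
            )
        except Exception as err:  # noqa: BLE001 - re-raise with context
            raise RuntimeError(
                f"simulation failed while perturbing parameter {name!r}: {err}"
            ) from err
        cols.append((hi - lo) / (2.0 * h))
    return np.column_stack(cols)


def _forward_sensitivities(
    params: ModelParams,
    design: ObservationDesign,
    free: Sequence[str],
    *,
    rtol: float,
    atol: float,
    orientation: str,
) -> np.ndarray:
    """Sensitivities by integrating dS/dt = J S + df/dtheta with the state.

    Only kp and kR' enter the dynamics; the switch constants KH/KN act on
    the output partitions alone, so their columns are analytic functions
    of the state.
    """
    from scipy.integrate import odeint

    from .model_core import initial_shell_volumes, shell_index_fractions, _sech
    from .simulator import _jac_base, _oxygen_and_dP, _rhs_base

    if orientation not in ("complement", "as_printed"):
        raise ValueError(f"unknown orientation {orientation!r}")
    n = params.n_shells
    fidx = shell_index_fractions(n, "mid")
    VTo = design.VTo
    dyn = [p for p in ("kp", "kRp") if p in free]

    def aug_rhs(z, t):
        y = z[:n]
        out = _oxygen_and_dP(y, fidx, VTo, params.kRp, params.Pmax)
        dz = np.zeros_like(z)
        if out is None:
            return dz
        VT, P, dPdVT = out
        dz[:n] = params.kp * P * y
        J = _jac_base(y, t, params.kp, params.kRp, params.Pmax, fidx, VTo)
        for k, name in enumerate(dyn):
            Sk = z[n * (k + 1): n * (k + 2)]
            if name == "kp":
                F = P * y
            else:  # kRp enters through sech(kRp * rT)
                rT = VT ** (1.0 / 3.0)
                x = params.kRp * rT
                s = _sech(x)
                Pb = params.Pmax * (VTo / VT) ** (2.0 / 3.0)
                dPdkRp = Pb * (1.0 - fidx) * (-s * np.tanh(x) * rT)
                F = params.kp * dPdkRp * y
            dz[n * (k + 1): n * (k + 2)] = J @ Sk + F
        return dz

    days = sorted({d for d, _ in design.points})
    times = np.array(([0.0] if days[0] > 0 else []) + days)
    z0 = np.zeros(n * (1 + len(dyn)))
    z0[:n] = initial_shell_volumes(n, VTo, params.kRp)
    if "kRp" in dyn:
        # the equal-drop initial partition itself depends on kR'
        k = dyn.index("kRp")
        h = 1e-7 * max(params.kRp, 1.0)
        dy0 = (
            initial_shell_volumes(n, VTo, params.kRp + h)
            - initial_shell_volumes(n, VTo, max(params.kRp - h, 0.0))
        ) / (2.0 * h if params.kRp >= h else h)
        z0[n * (k + 1): n * (k + 2)] = dy0
    z = odeint(aug_rhs, z0, times, rtol=rtol, atol=atol, mxstep=10000)

    # assemble output sensitivities per (day, region) point
    day_index = {d: i for i, d in enumerate(times)}
    K = {"H": params.KH, "N": params.KN}
    cols = {name: np.empty(len(design.points)) for name in free}
    for m, (d, region) in enumerate(design.points):
        row = z[day_index[d]]
        y = row[:n]
        out = _oxygen_and_dP(np.maximum(y, 0.0), fidx, VTo, params.kRp, params.Pmax)
        VT, P, dPdVT = out
        rT = VT ** (1.0 / 3.0)
        x = params.kRp * rT
        s = _sech(x)
        Pb = params.Pmax * (VTo / VT) ** (2.0 / 3.0)
        dPdkRp_direct = Pb * (1.0 - fidx) * (-s * np.tanh(x) * rT)
        for k, name in enumerate(dyn):
            Sk = row[n * (k + 1): n * (k + 2)]
            dVT = Sk.sum()
            if region == "T":
                cols[name][m] = dVT
            else:
                Kc = K[region]
                dP = dPdVT * dVT + (dPdkRp_direct if name == "kRp" else 0.0)
                if orientation == "complement":
                    frac = Kc / (Kc + P)
                    dfrac = -Kc / (Kc + P) ** 2 * dP
                else:
                    frac = P / (Kc + P)
                    dfrac = Kc / (Kc + P) ** 2 * dP
                cols[name][m] = np.sum(frac * Sk + dfrac * y)
        for name in free:
            if name in ("KH", "KN"):
                reg = "H" if name == "KH" else "N"
                if region != reg:
                    cols[name][m] = 0.0
                else:
                    Kc = K[reg]
                    if orientation == "complement":
                        dfracdK = P / (Kc + P) ** 2
                    else:
                        dfracdK = -P / (Kc + P) ** 2
                    cols[name][m] = np.sum(dfracdK * y)
    return np.column_stack([cols[name] for name in free])


def normalise_sensitivities(
    S: np.ndarray,
    theta: Sequence[float],
    Y: Sequence[float],
    *,
    floor: float = PREDICTION_FLOOR,
) -> np.ndarray:
    """Dimensionless S~_{mj} = S_{mj} * theta_j / Y_m.

    Observations whose prediction magnitude falls below ``floor`` are
    dropped with a warning; if none survive the design is degenerate.
    """
    S = np.asarray(S, dtype=float)
    theta = np.asarray(theta, dtype=float)
    Y = np.asarray(Y, dtype=float)
    keep = np.abs(Y) >= floor
    if not np.all(keep):
        warnings.warn(
            f"dropping {np.count_nonzero(~keep)} observation(s) with predictions "
            f"below {floor}", stacklevel=2,
        )
    if not np.any(keep):
        raise ValueError("degenerate design: all predictions below the floor")
    return S[keep] * theta[np.newaxis, :] / Y[keep, np.newaxis]


def collinearity_metrics(S_tilde: np.ndarray):
    """(gamma, kappa, singular values) of the normalised sensitivity matrix.

    gamma = 1/sigma_last, kappa = sigma_1/sigma_last; both infinite when the
    matrix is exactly rank-deficient.
    """
    S_tilde = np.atleast_2d(np.asarray(S_tilde, dtype=float))
    if S_tilde.shape[1] < 1:
        raise ValueError("sensitivity matrix needs at least one column")
    sv = np.linalg.svd(S_tilde, compute_uv=False)
    s_last = sv[min(len(sv), S_tilde.shape[1]) - 1] if len(sv) else 0.0
    if s_last == 0.0:
        return float("inf"), float("inf"), sv
    return 1.0 / s_last, sv[0] / s_last, sv


def fim_and_rank(S: np.ndarray, tol: float = 1e-8):
    """Fisher information matrix S^T S, its numerical rank and covariance.

    Rank counts eigenvalues above ``tol`` times the largest eigenvalue; the
    covariance is the (pseudo-)inverse of the FIM, so it stays defined for
    rank-deficient designs.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    FIM = S.T @ S
    eig = np.linalg.eigvalsh(FIM)
    emax = eig[-1] if eig.size else 0.0
    rank = int(np.count_nonzero(eig > tol * emax)) if emax > 0 else 0
    cov = np.linalg.pinv(FIM, rcond=tol)
    return FIM, rank, cov


@dataclass
class IdentifiabilityReport:
    """Summary of practical identifiability at a parameter point."""

    free: tuple
    theta: np.ndarray
    singular_values: np.ndarray
    gamma: float
    kappa: float
    rank: int
    identifiable: bool
    n_obs: int
    S: np.ndarray
    S_tilde: np.ndarray

    def to_dict(self) -> dict:
        return {
            "free": list(self.free),
            "theta": list(map(float, self.theta)),
            "singular_values": list(map(float, self.singular_values)),
            "gamma": float(self.gamma),
            "kappa": float(self.kappa),
            "rank": self.rank,
            "identifiable": self.identifiable,
            "n_obs": self.n_obs,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_table(self) -> pd.DataFrame:
        """One-row table mirroring the usual kappa / gamma / Rank columns."""
        return pd.DataFrame(
            [{
                "kappa": self.kappa,
                "gamma": self.gamma,
                "rank": self.rank,
                "identifiable": self.identifiable,
            }]
        )


def identifiability_report(
    params: ModelParams,
    design: ObservationDesign,
    free: Sequence[str] = FREE_DEFAULT,
    *,
    rel_step: float = DEFAULT_REL_STEP,
    rank_tol: float = 1e-8,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    orientation: str = "complement",
) -> IdentifiabilityReport:
    """Full pipeline: sensitivities -> normalisation -> SVD -> FIM rank.

    gamma, kappa and the FIM rank are computed from the normalised
    (dimensionless) sensitivity matrix; the raw matrix is retained in the
    report for standard-error covariances.
    """
    theta = np.array([getattr(params, name) for name in free], dtype=float)
    Y = predictions(params, design, rtol=rtol, atol=atol, orientation=orientation)
    S = sensitivity_matrix(
        params, design, free, rel_step=rel_step, rtol=rtol, atol=atol,
        orientation=orientation,
    )
    S_tilde = normalise_sensitivities(S, theta, Y)
    gamma, kappa, sv = collinearity_metrics(S_tilde)
    _, rank, _ = fim_and_rank(S_tilde, tol=rank_tol)
    return IdentifiabilityReport(
        free=tuple(free),
        theta=theta,
        singular_values=sv,
        gamma=gamma,
        kappa=kappa,
        rank=rank,
        identifiable=bool(gamma < GAMMA_THRESHOLD and kappa < KAPPA_THRESHOLD),
        n_obs=len(Y),
        S=S,
        S_tilde=S_tilde,
    )
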