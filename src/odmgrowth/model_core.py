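"""Core equations of the oxygen-driven model (ODM) of avascular tumour growth.

The model treats a subcutaneous xenograft as a sphere fed by oxygen
diffusing in from the surrounding tissue.  At steady state, Fick diffusion
with first-order cellular uptake gives a radial oxygen profile

    P(r) = P_b * cosh(kR' * r) / cosh(kR' * rT),

where ``kR'`` (cm^-1) is the *apparent oxygen uptake rate*, a lumped
sqrt(uptake/diffusivity) scaled by (3/4pi)^(1/3) so that the tumour
"radius" can be taken as rT = VT^(1/3) with no geometric prefactors.  The
boundary tension P_b shrinks with the exposed surface area as the tumour
outgrows its initial volume, P_b = Pmax * (VTo/VT)^(2/3).

The sphere is discretised into ``n`` concentric shells placed so that the
oxygen *drop* across every shell is the same (exponentially spaced radii,
dense near the rim where the profile is steep).  Oxygen at shell boundary
``i`` (0 = centre, n = rim) is then linear in ``i``:

    P_i = P_b / (n * cosh(kR'*rT)) * (n - i + i * cosh(kR'*rT)).

Each shell grows in proportion to its oxygen tension, dVi/dt = kp * P_i * Vi,
and hypoxic/necrotic volumes are algebraic saturable partitions of each
shell with switch constants KH and KN (mmHg).  A stroma extension couples
growth to a well-mixed stromal compartment VS recruited in proportion to
tumour volume.

All cosh ratios are evaluated in exponent-difference form so the equations
stay finite for kR' * rT of several hundred.

Units throughout: volumes cm^3, radii cm, oxygen mmHg, time days,
kp (mmHg day)^-1, kR' cm^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParams",
    "StromaParams",
    "ShellState",
    "OxygenProfile",
    "boundary_pressure",
    "continuous_oxygen_profile",
    "shell_oxygen",
    "shell_oxygen_vector",
    "oxygen_drop_per_shell",
    "oxygen_profile",
    "partition_volume",
    "growth_rhs",
    "stroma_rhs",
    "shell_radii",
    "initial_shell_volumes",
    "kRp_from_physical",
]

#: Default peripheral (boundary) oxygen tension, mmHg: partial pressure of
#: oxygen in peritumoural epithelial/connective tissue.
DEFAULT_PMAX = 60.0

#: Default number of concentric shells.
DEFAULT_N_SHELLS = 5

#: Below this value of kR'*rT the equal-drop construction degenerates
#: (flat profile); shell radii fall back to equal-volume spacing.
FLAT_PROFILE_THRESHOLD = 1e-6

ORIENTATIONS = ("complement", "as_printed")

#: Which oxygen value drives a shell's growth: the tension at the shell
#: centre index (i - 1/2, default — second-order accurate in shell count)
#: or at its outer boundary index i.
OXYGEN_INDEX_MODES = ("mid", "outer")


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass(frozen=True)
class ModelParams:
    """Parameter vector of the base oxygen-driven growth model.

    Parameters
    ----------
    kp : float
        Proliferation rate, (mmHg day)^-1.  Cell-line intrinsic.
    kRp : float
        Apparent oxygen uptake rate kR', cm^-1.  Lumps diffusion, uptake
        and effective perfusion.
    KH : float
        Hypoxia switch constant, mmHg.
    KN : float
        Necrosis switch constant, mmHg.
    Pmax : float
        Peripheral oxygen tension, mmHg (default 60).
    n_shells : int
        Number of concentric shells (default 5).
    """

    kp: float
    kRp: float
    KH: float
    KN: float
    Pmax: float = DEFAULT_PMAX
    n_shells: int = DEFAULT_N_SHELLS

    def __post_init__(self) -> None:
        if self.kp < 0:
            raise ValueError(f"kp must be >= 0, got {self.kp}")
        if self.kRp < 0:
            raise ValueError(f"kRp must be >= 0, got {self.kRp}")
        if self.KH <= 0:
            raise ValueError(f"KH must be > 0, got {self.KH}")
        if self.KN <= 0:
            raise ValueError(f"KN must be > 0, got {self.KN}")
        if self.Pmax <= 0:
            raise ValueError(f"Pmax must be > 0, got {self.Pmax}")
        if int(self.n_shells) != self.n_shells or self.n_shells < 1:
            raise ValueError(f"n_shells must be a positive integer, got {self.n_shells}")


@dataclass(frozen=True)
class StromaParams:
    """Parameters of the stroma-extended model.

    The tumour grows as dVi/dt = kPG * P_i * Vi * VS with kPG the
    stroma-modulated proliferation rate (mmHg day cm^3)^-1 (the product of
    the bare proliferation rate and a growth-enhancement constant), and the
    stroma is recruited as dVS/dt = kS * sum(Vi), kS in day^-1.
    """

    kPG: float
    kS: float
    kRp: float
    KH: float
    KN: float
    VS0: float = 0.0
    Pmax: float = DEFAULT_PMAX
    n_shells: int = DEFAULT_N_SHELLS

    def __post_init__(self) -> None:
        if self.kPG < 0:
            raise ValueError(f"kPG must be >= 0, got {self.kPG}")
        if self.kS < 0:
            raise ValueError(f"kS must be >= 0, got {self.kS}")
        if self.VS0 < 0:
            raise ValueError(f"VS0 must be >= 0, got {self.VS0}")
        if self.kRp < 0:
            raise ValueError(f"kRp must be >= 0, got {self.kRp}")
        if self.KH <= 0 or self.KN <= 0:
            raise ValueError("KH and KN must be > 0")
        if self.Pmax <= 0:
            raise ValueError(f"Pmax must be > 0, got {self.Pmax}")
        if int(self.n_shells) != self.n_shells or self.n_shells < 1:
            raise ValueError(f"n_shells must be a positive integer, got {self.n_shells}")


@dataclass
class ShellState:
    """Per-shell tumour volumes plus derived totals.

    ``Vi[j]`` is the volume of shell j+1 (shells are numbered 1..n from the
    centre outwards; shell i occupies radii [r_{i-1}, r_i]).  ``VS`` is the
    stromal volume (0 for the base model), ``VTo`` the initial total volume.
    """

    Vi: np.ndarray
    VTo: float
    VS: float = 0.0

    def __post_init__(self) -> None:
        self.Vi = np.asarray(self.Vi, dtype=float)
        if self.Vi.ndim != 1 or self.Vi.size < 1:
            raise ValueError("Vi must be a 1-D vector with at least one shell")
        if np.any(self.Vi < 0):
            raise ValueError("shell volumes must be nonnegative")
        if self.VTo <= 0:
            raise ValueError(f"VTo must be > 0, got {self.VTo}")
        if self.VS < 0:
            raise ValueError(f"VS must be >= 0, got {self.VS}")

    @property
    def n(self) -> int:
        return self.Vi.size

    @property
    def VT(self) -> float:
        """Total tumour volume, cm^3."""
        return float(np.sum(self.Vi))

    @property
    def rT(self) -> float:
        """Tumour radius surrogate rT = VT^(1/3), cm."""
        return self.VT ** (1.0 / 3.0)


@dataclass(frozen=True)
class OxygenProfile:
    """Discretised radial oxygen profile at one instant.

    ``P`` holds tensions at shell boundaries i = 0..n (centre to rim),
    ``boundary`` the rim tension, ``drop_total`` the centre-to-rim drop and
    ``drop_per_shell`` the (constant) per-shell drop.
    """

    P: np.ndarray
    boundary: float
    drop_total: float
    drop_per_shell: float


# ---------------------------------------------------------------------------
# Stable hyperbolic helpers


def _sech(x: float) -> float:
    """1/cosh(x) without overflow for large |x|."""
    e = math.exp(-abs(x))
    return 2.0 * e / (1.0 + e * e)


# ---------------------------------------------------------------------------
# Oxygen equations


def boundary_pressure(Pmax: float, VTo: float, VT: float) -> float:
    """Oxygen tension at the tumour rim, Pmax * (VTo/VT)^(2/3), mmHg.

    The boundary tension scales down with exposed surface area as the
    tumour outgrows its initial volume.
    """
    if Pmax <= 0:
        raise ValueError(f"Pmax must be > 0, got {Pmax}")
    if VTo <= 0 or VT <= 0:
        raise ValueError(f"volumes must be > 0, got VTo={VTo}, VT={VT}")
    return Pmax * (VTo / VT) ** (2.0 / 3.0)


def continuous_oxygen_profile(r: float, rT: float, kRp: float, P_boundary: float) -> float:
    """Continuous radial profile P_b * cosh(kRp*r)/cosh(kRp*rT), mmHg.

    Evaluated as exp(kRp*(r - rT)) * (1+e^{-2kRp r})/(1+e^{-2kRp rT}) so it
    stays finite for large kRp*rT.
    """
    if r < 0 or r > rT:
        raise ValueError(f"require 0 <= r <= rT, got r={r}, rT={rT}")
    if kRp == 0 or rT == 0:
        return P_boundary
    a = kRp * r
    b = kRp * rT
    ratio = math.exp(a - b) * (1.0 + math.exp(-2.0 * a)) / (1.0 + math.exp(-2.0 * b))
    return P_boundary * ratio


def shell_oxygen(i: int, n: int, state: ShellState, params: ModelParams) -> float:
    """Oxygen tension at shell boundary ``i`` (0 = centre, n = rim), mmHg.

    Implements the i-linear discretised profile
    P_i = Pb/(n cosh(kRp rT)) * (n - i + i cosh(kRp rT)) in the stable form
    Pb * (i/n + (1 - i/n) sech(kRp rT)).
    """
    if i < 0 or i > n:
        raise IndexError(f"shell index {i} outside 0..{n}")
    Pb = boundary_pressure(params.Pmax, state.VTo, state.VT)
    s = _sech(params.kRp * state.rT)
    f = i / n
    return Pb * (f + (1.0 - f) * s)


def shell_oxygen_vector(
    n: int, VT: float, VTo: float, kRp: float, Pmax: float
) -> np.ndarray:
    """Oxygen tensions at boundaries i = 0..n as a vector (stable form)."""
    Pb = boundary_pressure(Pmax, VTo, VT)
    s = _sech(kRp * VT ** (1.0 / 3.0))
    f = np.arange(n + 1) / n
    return Pb * (f + (1.0 - f) * s)


def shell_index_fractions(n: int, oxygen_index: str = "mid") -> np.ndarray:
    """Index fractions i/n assigning a driving oxygen value to shells 1..n.

    ``mid`` uses the shell-centre index (i - 1/2)/n; ``outer`` the outer
    boundary index i/n.  The profile is linear in the index, so either is a
    point on the same discretised profile; the centre value makes the
    scheme's growth curves converge quadratically in the shell count.
    """
    if oxygen_index not in OXYGEN_INDEX_MODES:
        raise ValueError(
            f"oxygen_index must be one of {OXYGEN_INDEX_MODES}, got {oxygen_index!r}"
        )
    i = np.arange(1, n + 1, dtype=float)
    return (i - 0.5) / n if oxygen_index == "mid" else i / n


def oxygen_drop_per_shell(n: int, state: ShellState, params: ModelParams) -> float:
    """Constant per-shell oxygen drop (Pb/n) * (1 - sech(kRp*rT)), mmHg."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    Pb = boundary_pressure(params.Pmax, state.VTo, state.VT)
    return Pb / n * (1.0 - _sech(params.kRp * state.rT))


def oxygen_profile(state: ShellState, params: ModelParams) -> OxygenProfile:
    """Full discretised profile for ``state`` under ``params``."""
    n = params.n_shells
    P = shell_oxygen_vector(n, state.VT, state.VTo, params.kRp, params.Pmax)
    boundary = float(P[-1])
    drop = float(P[-1] - P[0])
    return OxygenProfile(P=P, boundary=boundary, drop_total=drop, drop_per_shell=drop / n)


# ---------------------------------------------------------------------------
# Hypoxia / necrosis partitions


def partition_volume(P: float, K: float, V: float, orientation: str = "complement"):
    """Saturable hypoxic/necrotic partition of a volume ``V`` at oxygen ``P``.

    ``complement`` (default) returns V * K/(K+P): the affected fraction
    approaches 1 as oxygen vanishes, consistent with hypoxia/necrosis being
    consequences of insufficient oxygen.  ``as_printed`` returns the mirror
    form V * P/(K+P).
    """
    if K <= 0:
        raise ValueError(f"K must be > 0, got {K}")
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}, got {orientation!r}")
    P = np.asarray(P, dtype=float) if np.ndim(P) else float(P)
    if np.any(np.asarray(P) < 0):
        raise ValueError("oxygen tension must be >= 0")
    if np.any(np.asarray(V) < 0):
        raise ValueError("volume must be >= 0")
    if orientation == "complement":
        return V * K / (K + P)
    return V * P / (K + P)


# ---------------------------------------------------------------------------
# Growth right-hand sides


def _driving_oxygen(state: ShellState, kRp: float, Pmax: float, oxygen_index: str) -> np.ndarray:
    Pb = boundary_pressure(Pmax, state.VTo, state.VT)
    s = _sech(kRp * state.rT)
    f = shell_index_fractions(state.n, oxygen_index)
    return Pb * (f + (1.0 - f) * s)


def growth_rhs(
    state: ShellState, params: ModelParams, oxygen_index: str = "mid"
) -> np.ndarray:
    """Per-shell growth rates dVi/dt = kp * P_i * Vi, cm^3/day.

    Shell i (1..n) is driven by the oxygen of the discretised profile at
    its own index (shell-centre value by default, see
    :func:`shell_index_fractions`); shells are material — they keep their
    identity for all time and only the oxygen assignment is recomputed
    from the current total volume.
    """
    P = _driving_oxygen(state, params.kRp, params.Pmax, oxygen_index)
    return params.kp * P * state.Vi


def stroma_rhs(
    state: ShellState, params: StromaParams, oxygen_index: str = "mid"
) -> np.ndarray:
    """Rates of the stroma-extended model: n shell rates then dVS/dt.

    dVi/dt = kPG * P_i * Vi * VS;  dVS/dt = kS * sum(Vi).
    """
    P = _driving_oxygen(state, params.kRp, params.Pmax, oxygen_index)
    dVi = params.kPG * P * state.Vi * state.VS
    return np.append(dVi, params.kS * state.VT)


# ---------------------------------------------------------------------------
# Spatial discretisation


def shell_radii(n: int, rT: float, kRp: float) -> np.ndarray:
    """Shell boundary radii 0 = r_0 < ... < r_n = rT with equal oxygen drop.

    Boundaries are placed so the continuous profile takes equally spaced
    values at successive radii: r_i = arccosh(1 + (i/n)(cosh(kRp rT) - 1))/kRp.
    For kRp*rT below ``FLAT_PROFILE_THRESHOLD`` the profile is flat and the
    construction degenerates; equal-volume boundaries r_i = rT (i/n)^(1/3)
    are used instead.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if rT <= 0:
        raise ValueError(f"rT must be > 0, got {rT}")
    frac = np.arange(n + 1) / n
    x = kRp * rT
    if x < FLAT_PROFILE_THRESHOLD:
        return rT * frac ** (1.0 / 3.0)
    if x < 700.0:
        y = 1.0 + frac * (math.cosh(x) - 1.0)
        r = np.arccosh(y) / kRp
    else:
        # cosh(x) ~ e^x/2 overflows; arccosh(y) ~ log(2y) for the interior
        # boundaries, which all sit within a few 1/kRp of the rim.
        r = np.empty(n + 1)
        r[0] = 0.0
        r[1:] = (x + np.log(frac[1:])) / kRp
        np.clip(r, 0.0, None, out=r)
    r[-1] = rT
    return r


def initial_shell_volumes(n: int, VTo: float, kRp: float) -> np.ndarray:
    """Initial partition of VTo over shells from the equal-drop radii.

    Vi(0) = r_i^3 - r_{i-1}^3 under the rT = VT^(1/3) scaling (no 4pi/3
    factors anywhere in the shell geometry).
    """
    if VTo <= 0:
        raise ValueError(f"VTo must be > 0, got {VTo}")
    r = shell_radii(n, VTo ** (1.0 / 3.0), kRp)
    V = np.diff(r**3)
    # guard against rounding: renormalise exactly to VTo
    V *= VTo / V.sum()
    return V


# ---------------------------------------------------------------------------
# Parameter conversion


def kRp_from_physical(kR: float, D: float) -> float:
    """Apparent uptake rate kR' = sqrt(kR/D) * (3/(4 pi))^(1/3), cm^-1.

    ``kR`` is the first-order volumetric oxygen uptake rate (day/cm^3) and
    ``D`` the diffusion coefficient (cm^2/day); the geometric factor folds
    the sphere-volume prefactor into the rate so rT = VT^(1/3) can be used.
    """
    if D <= 0:
        raise ValueError(f"D must be > 0, got {D}")
    if kR < 0:
        raise ValueError(f"kR must be >= 0, got {kR}")
    return math.sqrt(kR / D) * (3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
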