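"""Synthetic xenograft-study generator with known ground truth.

Emulates the structure of subcutaneous xenograft efficacy studies: a cohort
of animals with lognormally distributed take volumes around ~0.1 cm^3,
calliper-derived total-volume measurements 1-3 times a week, multiplicative
(lognormal) measurement noise, and — optionally — hypoxic and necrotic
volume observations either weekly (sacrificial cohorts) or as a single
end-of-study endpoint (HIF1alpha-style readouts).

Every dataset is generated by forward-simulating the growth model at a
known parameter vector, so downstream estimation and identifiability code
can be tested by parameter recovery without any external data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import ModelParams, StromaParams
from .simulator import simulate, simulate_stroma
from .estimation import GrowthDataset

__all__ = [
    "StudyDesign",
    "generate_study",
    "measurement_days",
    "calliper_volume",
    "inverse_calliper",
]


def measurement_days(duration: int = 28, per_week: int = 3) -> tuple:
    """Measurement schedule: ``per_week`` calliper days a week (Mon/Wed/Fri
    pattern for 3, Mon/Thu for 2, Mon for 1) over ``duration`` days."""
    offsets = {1: (0,), 2: (0, 3), 3: (0, 2, 4)}[per_week]
    days = [w * 7 + o for w in range(duration // 7 + 1) for o in offsets if w * 7 + o <= duration]
    if days[-1] != duration:
        days.append(duration)
    return tuple(float(d) for d in days)


@dataclass(frozen=True)
class StudyDesign:
    """Design of a synthetic xenograft study.

    ``hn_schedule`` controls hypoxia/necrosis observations: ``"weekly"``
    (every 7 days, as for sacrificial IHC cohorts), ``"endpoint"`` (last
    day only) or ``"none"``.  Noise is multiplicative lognormal with the
    given coefficient of variation, mean-corrected so noisy observations
    are unbiased; initial volumes are lognormal around ``vto_mean``.
    """

    n_animals: int = 10
    days: tuple = measurement_days(28, 3)
    hn_schedule: str = "weekly"
    vto_mean: float = 0.1
    vto_cv: float = 0.2
    noise_cv: float = 0.15
    seed: int | None = None

    def __post_init__(self):
        if self.n_animals < 1:
            raise ValueError(f"n_animals must be >= 1, got {self.n_animals}")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if self.vto_cv < 0 or self.noise_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.hn_schedule not in ("weekly", "endpoint", "none"):
            raise ValueError(
                f"hn_schedule must be weekly/endpoint/none, got {self.hn_schedule!r}"
            )

    @property
    def hn_days(self) -> tuple:
        last = self.days[-1]
        if self.hn_schedule == "weekly":
            return tuple(float(d) for d in np.arange(7, last + 1, 7))
        if self.hn_schedule == "endpoint":
            return (float(last),)
        return ()


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Unbiased multiplicative noise: E[factor] = 1, sd/mean = cv."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def generate_study(
    truth: ModelParams | StromaParams,
    design: StudyDesign | None = None,
    seed: int | None = None,
) -> GrowthDataset:
    """Simulate a study at the ground-truth parameters ``truth``.

    Each animal gets its own sampled take volume and its own noisy
    observations; the result is fully reproducible from the seed (the
    ``seed`` argument overrides ``design.seed``).  For the stroma-extended
    model the measured "tumour" volume is tumour plus stroma, as callipers
    cannot separate the two.
    """
    design = design or StudyDesign()
    if seed is None:
        seed = design.seed
    rng = np.random.default_rng(seed)
    all_days = np.array(sorted({0.0} | set(design.days) | set(design.hn_days)))
    sigma_v = math.sqrt(math.log(1.0 + design.vto_cv**2))
    rows = []
    for a in range(design.n_animals):
        animal = f"animal_{a + 1:02d}"
        vto = float(
            rng.lognormal(math.log(design.vto_mean) - 0.5 * sigma_v**2, sigma_v)
        ) if design.vto_cv > 0 else design.vto_mean
        try:
            if isinstance(truth, StromaParams):
                traj = simulate_stroma(truth, vto, all_days)
                total = traj.VT + traj.VS
            else:
                traj = simulate(truth, vto, all_days)
                total = traj.VT
        except Exception as err:  # noqa: BLE001
            raise RuntimeError(
                f"simulation failed for {animal} (VTo={vto:.4g}) at {truth}: {err}"
            ) from err
        series = dict(zip(all_days, zip(total, traj.VH, traj.VN)))
        for d in design.days:
            v = series[d][0] * _lognormal_factor(rng, design.noise_cv, None)
            rows.append((animal, d, "T", float(v)))
        for d in design.hn_days:
            vh = series[d][1] * _lognormal_factor(rng, design.noise_cv, None)
            vn = series[d][2] * _lognormal_factor(rng, design.noise_cv, None)
            rows.append((animal, d, "H", float(vh)))
            rows.append((animal, d, "N", float(vn)))
    return GrowthDataset(
        pd.DataFrame(rows, columns=["animal_id", "day", "region", "volume_cm3"])
    )


def calliper_volume(length: float, width: float) -> float:
    """Prolate-spheroid calliper volume L * W^2 / 2, cm^3.

    The ubiquitous preclinical convention; ``pi/6 * L * W^2`` differs only
    by a constant factor.  Swaps the inputs (with a warning) if width
    exceeds length.
    """
    if width <= 0 or length <= 0:
        raise ValueError("calliper dimensions must be > 0")
    if width > length:
        warnings.warn("width > length; swapping calliper dimensions", stacklevel=2)
        length, width = width, length
    return length * width * width / 2.0


def inverse_calliper(volume: float, aspect_ratio: float = 1.0) -> tuple[float, float]:
    """(length, width) reproducing ``volume`` with length/width = aspect_ratio."""
    if volume <= 0:
        raise ValueError(f"volume must be > 0, got {volume}")
    if aspect_ratio < 1:
        raise ValueError(f"aspect_ratio must be >= 1, got {aspect_ratio}")
    width = (2.0 * volume / aspect_ratio) ** (1.0 / 3.0)
    return aspect_ratio * width, width
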