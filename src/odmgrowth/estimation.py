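"""Parameter estimation for the oxygen-driven model.

Fits are weighted least squares: the objective is

    OF(theta) = sum_r sum_t (Vhat_{t,r} - V_{t,r})^2 / N_r,

summing over the observed regions r in {T, H, N} (total, hypoxic, necrotic
volume) and time points t, with N_r the number of records for region r — the
per-region averaging makes sparsely observed regions commensurate with the
densely measured total volume.  The optimiser is multi-start: starting
points are drawn by latin-hypercube sampling over box bounds and a
derivative-based local least-squares minimiser (trust-region reflective)
is run from every start; the best objective wins.

Animals are pooled by fitting the per-time-point mean volume by default
(``pooling="mean"``); ``pooling="pooled"`` fits every record individually.
Standard errors come from the Fisher information of the raw sensitivity
matrix at the optimum, scaled by the residual variance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model_core import ModelParams
from .identifiability import ObservationDesign, predictions, sensitivity_matrix

__all__ = [
    "GrowthDataset",
    "FitConfig",
    "FitResult",
    "objective",
    "latin_hypercube_starts",
    "fit",
    "standard_errors",
    "DEFAULT_BOUNDS",
]

logger = logging.getLogger(__name__)

REGIONS = ("T", "H", "N")

REQUIRED_COLUMNS = ("animal_id", "day", "region", "volume_cm3")

#: Box bounds for latin-hypercube starts, spanning the fitted ranges
#: reported across xenograft and explant studies with margin.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "kp": (1e-5, 0.1),
    "kRp": (0.1, 100.0),
    "KH": (0.1, 200.0),
    "KN": (0.1, 200.0),
}

#: Objective value returned when a simulation fails at a trial point.
DEFAULT_PENALTY = 1e6


@dataclass
class GrowthDataset:
    """Observed longitudinal study in long format.

    One row per measurement: ``animal_id``, ``day`` (days from first
    measurement), ``region`` in {T, H, N} and ``volume_cm3``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset missing required columns: {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
        df["day"] = df["day"].astype(float)
        df["volume_cm3"] = df["volume_cm3"].astype(float)
        bad_region = ~df["region"].isin(REGIONS)
        if bad_region.any():
            raise ValueError(
                f"unknown region codes: {sorted(df.loc[bad_region, 'region'].unique())}"
            )
        if (df["volume_cm3"] < 0).any():
            raise ValueError("negative volumes in dataset")
        if (df["day"] < 0).any():
            raise ValueError("negative days in dataset")
        if not (df["region"] == "T").any():
            raise ValueError("dataset must contain at least one total-volume (T) record")
        self.data = df.sort_values(["animal_id", "region", "day"]).reset_index(drop=True)

    @property
    def region_counts(self) -> dict[str, int]:
        """Number of records N_r per observed region."""
        return self.data["region"].value_counts().to_dict()

    @property
    def animals(self) -> list:
        return sorted(self.data["animal_id"].unique().tolist())

    def vto(self, animal_id=None) -> float:
        """Initial volume: first total-volume record (per animal, or the
        mean over animals at the earliest day)."""
        t = self.data[self.data["region"] == "T"]
        if animal_id is not None:
            t = t[t["animal_id"] == animal_id]
            if t.empty:
                raise KeyError(f"no T records for animal {animal_id!r}")
        first_day = t["day"].min()
        return float(t.loc[t["day"] == first_day, "volume_cm3"].mean())

    def mean_curve(self) -> pd.DataFrame:
        """Per-(day, region) mean volume across animals."""
        g = self.data.groupby(["day", "region"], as_index=False)["volume_cm3"].mean()
        return g.sort_values(["region", "day"]).reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "GrowthDataset":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Objective


def _fit_table(dataset: GrowthDataset, pooling: str) -> pd.DataFrame:
    if pooling == "mean":
        return dataset.mean_curve()
    if pooling == "pooled":
        return dataset.data[["day", "region", "volume_cm3"]].copy()
    raise ValueError(f"pooling must be 'mean' or 'pooled', got {pooling!r}")


def _weighted_residuals(
    params: ModelParams,
    table: pd.DataFrame,
    vto: float,
    *,
    rtol: float,
    atol: float,
    orientation: str,
) -> np.ndarray:
    """Residuals scaled by 1/sqrt(N_r) so their squared sum is the objective."""
    design = ObservationDesign(
        points=tuple(zip(table["day"], table["region"])), VTo=vto
    )
    pred = predictions(params, design, rtol=rtol, atol=atol, orientation=orientation)
    counts = table["region"].map(table["region"].value_counts())
    return (pred - table["volume_cm3"].to_numpy()) / np.sqrt(counts.to_numpy(float))


def objective(
    params: ModelParams,
    dataset: GrowthDataset,
    *,
    pooling: str = "mean",
    vto: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    orientation: str = "complement",
    penalty: float = DEFAULT_PENALTY,
) -> float:
    """Weighted least-squares objective of ``params`` against ``dataset``.

    Regions absent from the dataset contribute nothing.  A failed
    simulation returns the finite ``penalty`` value (and logs it) so that
    optimisation can continue past pathological trial points.
    """
    table = _fit_table(dataset, pooling)
    if vto is None:
        vto = dataset.vto()
    try:
        res = _weighted_residuals(
            params, table, vto, rtol=rtol, atol=atol, orientation=orientation
        )
    except Exception as err:  # noqa: BLE001
        logger.warning("simulation failed at %s: %s; returning penalty", params, err)
        return float(penalty)
    return float(np.sum(res**2))


# ---------------------------------------------------------------------------
# Multi-start machinery


def latin_hypercube_starts(
    bounds: Mapping[str, tuple[float, float]],
    n_starts: int = 150,
    seed: int | None = None,
) -> pd.DataFrame:
    """Latin-hypercube starting points over box ``bounds``.

    Each parameter axis is stratified into ``n_starts`` equal-probability
    bins with exactly one sample per bin; reproducible given ``seed``.
    """
    if n_starts < 1:
        raise ValueError(f"n_starts must be >= 1, got {n_starts}")
    names = list(bounds)
    lo = np.array([bounds[k][0] for k in names], dtype=float)
    hi = np.array([bounds[k][1] for k in names], dtype=float)
    if not np.all(np.isfinite(lo) & np.isfinite(hi)) or np.any(lo >= hi):
        raise ValueError(f"bounds must be finite with lo < hi, got {dict(bounds)}")
    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    u = sampler.random(n_starts)
    return pd.DataFrame(qmc.scale(u, lo, hi), columns=names)


@dataclass
class FitConfig:
    """Configuration of a multi-start fit.

    ``free`` names the fitted parameters; every other model parameter takes
    its value from ``fixed`` (volume-only studies typically fix KH and KN,
    to which the data are then insensitive).  Simulation tolerances during
    fitting default slightly looser than the forward-simulation defaults;
    the best fit is always re-evaluated at tight tolerance.
    """

    free: tuple[str, ...] = ("kp", "kRp", "KH", "KN")
    fixed: dict[str, float] = field(default_factory=dict)
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    n_starts: int = 150
    seed: int | None = None
    pooling: str = "mean"
    vto: float | None = None
    n_shells: int = 5
    Pmax: float = 60.0
    orientation: str = "complement"
    max_nfev: int = 500
    ftol: float = 1e-10
    rtol: float = 1e-7
    atol: float = 1e-9
    penalty: float = DEFAULT_PENALTY
    #: Measurement-error model for standard errors: "proportional"
    #: (multiplicative calliper noise, residual sd grows with volume — the
    #: realistic model for calliper data) or "additive" (homoscedastic).
    error_model: str = "proportional"

    def __post_init__(self) -> None:
        valid = {"kp", "kRp", "KH", "KN"}
        unknown = set(self.free) - valid
        if unknown:
            raise ValueError(f"unknown free parameters: {sorted(unknown)}")
        if not self.free:
            raise ValueError("at least one parameter must be free")
        if self.error_model not in ("proportional", "additive"):
            raise ValueError(
                f"error_model must be 'proportional' or 'additive', got {self.error_model!r}"
            )
        for name in valid - set(self.free):
            if name not in self.fixed:
                raise ValueError(f"parameter {name!r} is neither free nor fixed")

    def make_params(self, values: Mapping[str, float]) -> ModelParams:
        kw = dict(self.fixed)
        kw.update({k: float(values[k]) for k in self.free})
        return ModelParams(
            kp=kw["kp"], kRp=kw["kRp"], KH=kw["KH"], KN=kw["KN"],
            Pmax=self.Pmax, n_shells=self.n_shells,
        )


@dataclass
class FitResult:
    """Best-of-multi-start estimate with diagnostics.

    ``objective`` is the value of the weighted least-squares objective at
    the optimum (the quantity reported as "Residual").
    """

    estimates: dict[str, float]
    fixed: dict[str, float]
    se: dict[str, float]
    objective: float
    n_starts: int
    best_start: int
    starts: pd.DataFrame
    n_obs: int
    config: FitConfig

    @property
    def params(self) -> ModelParams:
        return self.config.make_params(self.estimates)

    def to_dict(self) -> dict:
        return {
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "fixed": {k: float(v) for k, v in self.fixed.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "objective": float(self.objective),
            "n_starts": self.n_starts,
            "best_start": self.best_start,
            "n_obs": self.n_obs,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class EstimationError(RuntimeError):
    """Raised when every start of a multi-start fit fails."""


def fit(dataset: GrowthDataset, config: FitConfig | None = None) -> FitResult:
    """Multi-start weighted least-squares fit of the model to ``dataset``.

    Runs a bounded trust-region-reflective least-squares minimiser from
    each latin-hypercube start and returns the best-objective result with
    per-start diagnostics and standard errors.
    """
    config = config or FitConfig()
    table = _fit_table(dataset, config.pooling)
    vto = config.vto if config.vto is not None else dataset.vto()
    free = list(config.free)
    bounds = {k: config.bounds[k] for k in free}
    starts = latin_hypercube_starts(bounds, config.n_starts, config.seed)
    lo = np.array([bounds[k][0] for k in free])
    hi = np.array([bounds[k][1] for k in free])

    def residuals(x: np.ndarray) -> np.ndarray:
        params = config.make_params(dict(zip(free, x)))
        try:
            return _weighted_residuals(
                params, table, vto,
                rtol=config.rtol, atol=config.atol, orientation=config.orientation,
            )
        except Exception as err:  # noqa: BLE001
            logger.warning("simulation failed at %s: %s", dict(zip(free, x)), err)
            return np.full(len(table), np.sqrt(config.penalty / len(table)))

    records = []
    best = None
    for idx, row in starts.iterrows():
        x0 = row.to_numpy(float)
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                ftol=config.ftol, xtol=1e-10, gtol=1e-10,
                max_nfev=config.max_nfev, x_scale="jac",
            )
            obj = float(2.0 * sol.cost)  # cost = 0.5 * sum(res^2)
            records.append(
                {"start": idx, **{f"x0_{k}": v for k, v in zip(free, x0)},
                 **dict(zip(free, sol.x)), "objective": obj,
                 "nfev": sol.nfev, "status": sol.status, "success": bool(sol.success)}
            )
            if sol.success and (best is None or obj < best[1]):
                best = (idx, obj, sol.x)
        except Exception as err:  # noqa: BLE001
            records.append(
                {"start": idx, **{f"x0_{k}": v for k, v in zip(free, x0)},
                 "objective": np.inf, "nfev": 0, "status": -99, "success": False}
            )
            logger.warning("start %d failed: %s", idx, err)
    starts_log = pd.DataFrame(records)
    if best is None:
        raise EstimationError(
            f"all {config.n_starts} starts failed; per-start log:\n{starts_log}"
        )
    best_idx, _, xhat = best
    estimates = dict(zip(free, map(float, xhat)))
    best_params = config.make_params(estimates)
    # re-evaluate the optimum at tight tolerance for the reported residual
    obj = objective(
        best_params, dataset, pooling=config.pooling, vto=vto,
        orientation=config.orientation, penalty=config.penalty,
    )
    design = ObservationDesign(points=tuple(zip(table["day"], table["region"])), VTo=vto)
    S = sensitivity_matrix(
        best_params, design, free, orientation=config.orientation
    )
    counts = table["region"].map(table["region"].value_counts()).to_numpy(float)
    if config.error_model == "proportional":
        resid = _weighted_residuals(
            best_params, table, vto, rtol=1e-8, atol=1e-10,
            orientation=config.orientation,
        ) * np.sqrt(counts)
        Y = predictions(best_params, design, orientation=config.orientation)
        se = proportional_noise_errors(S, resid, Y, counts)
    else:
        # weight S rows by the same 1/sqrt(N_r) as the residuals so that
        # sigma2 = objective/dof and the FIM refer to the same scale
        se = standard_errors(S / np.sqrt(counts)[:, None], obj, len(table))
    logger.info(
        "fit finished: best start %d, objective %.4g, estimates %s",
        best_idx, obj, estimates,
    )
    return FitResult(
        estimates=estimates,
        fixed=dict(config.fixed),
        se=dict(zip(free, map(float, se))),
        objective=obj,
        n_starts=config.n_starts,
        best_start=int(best_idx),
        starts=starts_log,
        n_obs=len(table),
        config=config,
    )


def proportional_noise_errors(
    S: np.ndarray, residuals: np.ndarray, Y: np.ndarray, counts: np.ndarray
) -> np.ndarray:
    """Standard errors under multiplicative (proportional) measurement error.

    Calliper volumes carry noise whose standard deviation scales with the
    measured volume, sd_m = c * Y_m.  The fit minimises the region-weighted
    objective with weights w_m^2 = 1/N_r, so the estimator covariance is
    the weighted-least-squares sandwich

        Cov = G^-1 [c^2 sum_m w_m^4 Y_m^2 S_m S_m^T] G^-1,
        G = sum_m w_m^2 S_m S_m^T,

    with the relative noise level c^2 estimated from the relative
    residuals, c^2 = sum_m (e_m/Y_m)^2 / (n - p).  Degenerate inputs
    (no residual degrees of freedom, singular G) yield infinite SEs.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    n, p = S.shape
    dof = n - p
    if dof <= 0:
        return np.full(p, np.inf)
    Y = np.asarray(Y, dtype=float)
    w2 = 1.0 / np.asarray(counts, dtype=float)
    G = S.T @ (S * w2[:, None])
    eig = np.linalg.eigvalsh(G)
    if eig[-1] <= 0 or eig[0] <= 1e-12 * eig[-1]:
        return np.full(p, np.inf)
    c2 = float(np.sum((np.asarray(residuals, dtype=float) / Y) ** 2)) / dof
    M = c2 * (S.T @ (S * (w2**2 * Y**2)[:, None]))
    Gi = np.linalg.inv(G)
    return np.sqrt(np.diag(Gi @ M @ Gi))


def standard_errors(S: np.ndarray, objective_value: float, n_obs: int) -> np.ndarray:
    """Asymptotic standard errors from the Fisher information S^T S.

    SE_j = sqrt(sigma2 * [FIM^-1]_jj) with sigma2 = objective/(n_obs - p),
    the usual residual-variance estimator.  A numerically singular FIM (or
    nonpositive degrees of freedom) yields infinite SEs rather than an
    exception — degeneracy is reported, not raised.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    p = S.shape[1]
    FIM = S.T @ S
    eig = np.linalg.eigvalsh(FIM)
    dof = n_obs - p
    if dof <= 0 or eig[-1] <= 0 or eig[0] <= 1e-12 * eig[-1]:
        return np.full(p, np.inf)
    sigma2 = max(objective_value, 0.0) / dof
    cov = sigma2 * np.linalg.inv(FIM)
    return np.sqrt(np.diag(cov))
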