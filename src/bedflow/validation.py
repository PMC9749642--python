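"""Model testing: historical fit, extreme conditions, equilibrium, and
lookup-table recovery from data.

The validity program mirrors standard system-dynamics practice:

* historical fit — simulate the observed window and compare annual
  values against the recorded series (MAPE and RMSE per variable);
* extreme-condition (marginal-limit) tests — drive inputs to their
  limits (no population, no demand, vast bed supply, zero stay) and
  check the model's behavior stays sensible;
* equilibrium — with all growth shut off, every stock must hold its
  initial value indefinitely;
* lookup-slope recovery — a data-driven route to the rate-effect
  tables: fit a table's free y-values by nested simulation so the
  simulated trajectories match observations, with monotonicity
  enforced by reparameterization.

All checks are pure: they never mutate the input configuration.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .bed_model import RateEffectTables
from .config import BedModelConfig, PolicySpec, ScenarioSpec
from .engine import ConfigurationError, LookupTable, RunResult

__all__ = [
    "HistoricalSeries",
    "FitMetrics",
    "ValidityCheck",
    "ValidityReport",
    "LookupFit",
    "compare_to_history",
    "extreme_condition_suite",
    "equilibrium_test",
    "recover_lookup_slopes",
]

HISTORY_VARIABLES = (
    "number_of_bed",
    "number_of_specialist_physicians",
    "bed_occupancy_rate",
    "total_patient",
    "capacity_of_home_care_services",
)


@dataclass(frozen=True)
class HistoricalSeries:
    """Annual observations: a year column plus one column per variable."""

    years: tuple[int, ...]
    observed: Mapping[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        years = tuple(int(y) for y in self.years)
        object.__setattr__(self, "years", years)
        object.__setattr__(
            self,
            "observed",
            {k: tuple(float(x) for x in v) for k, v in self.observed.items()},
        )
        if len(years) < 2:
            raise ConfigurationError("a historical series needs at least 2 years")
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ConfigurationError(f"years must be strictly increasing: {years}")
        for name, vals in self.observed.items():
            if len(vals) != len(years):
                raise ConfigurationError(
                    f"series {name!r} has {len(vals)} values for {len(years)} years"
                )
            if any(v < 0 for v in vals):
                raise ConfigurationError(f"series {name!r} has negative values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, **self.observed})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "HistoricalSeries":
        if "year" not in frame.columns:
            raise ConfigurationError("history table needs a 'year' column")
        obs = {
            c: tuple(frame[c].astype(float)) for c in frame.columns if c != "year"
        }
        return cls(tuple(frame["year"].astype(int)), obs)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "HistoricalSeries":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class FitMetrics:
    """Per-variable fit errors between a run and a historical series."""

    mape: Mapping[str, float]  # percent
    rmse: Mapping[str, float]  # variable units

    @property
    def worst_mape(self) -> float:
        return max(self.mape.values()) if self.mape else 0.0


def compare_to_history(run: RunResult, hist: HistoricalSeries) -> FitMetrics:
    """Align annual saved values to observations and compute MAPE/RMSE.

    Zero observed values are excluded from MAPE (with a warning); RMSE
    always uses every observation.
    """
    mape: dict[str, float] = {}
    rmse: dict[str, float] = {}
    missing = [v for v in hist.observed if v not in run]
    if missing:
        raise KeyError(f"run lacks historical variable(s): {missing}")
    for name, obs in hist.observed.items():
        obs_arr = np.asarray(obs, dtype=float)
        sim = np.array([run.at_time(float(y), name) for y in hist.years])
        rmse[name] = float(np.sqrt(np.mean((sim - obs_arr) ** 2)))
        nz = obs_arr != 0.0
        if not np.all(nz):
            warnings.warn(
                f"{int((~nz).sum())} zero observation(s) of {name!r} excluded from MAPE",
                stacklevel=2,
            )
        if np.any(nz):
            mape[name] = float(
                100.0 * np.mean(np.abs(sim[nz] - obs_arr[nz]) / np.abs(obs_arr[nz]))
            )
    return FitMetrics(mape=mape, rmse=rmse)


# ---------------------------------------------------------------------------
# Extreme-condition and equilibrium tests


@dataclass(frozen=True)
class ValidityCheck:
    name: str
    passed: bool
    detail: str


@dataclass(frozen=True)
class ValidityReport:
    checks: tuple[ValidityCheck, ...]

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def failed(self) -> tuple[ValidityCheck, ...]:
        return tuple(c for c in self.checks if not c.passed)


def _excerpt(arr: np.ndarray) -> str:
    head = ", ".join(f"{v:.6g}" for v in arr[:4])
    return f"[{head}, ... max={np.max(arr):.6g}]"


def extreme_condition_suite(config: BedModelConfig) -> ValidityReport:
    """Marginal-limit tests of behavioral validity.

    Runs the model under four extreme inputs and checks the expected
    degenerate behavior. Returns a report; never raises for a failed
    check.
    """
    checks: list[ValidityCheck] = []

    # 1. no population: patients come from travelers only
    cfg = config.replace(
        initial_stocks=dataclasses.replace(config.initial_stocks, population=0.0)
    )
    run = cfg.run()
    travelers_only = np.allclose(run["total_patient"], run["flow_of_travelers"], rtol=1e-12)
    checks.append(
        ValidityCheck(
            "zero_population_patients_are_travelers",
            travelers_only,
            f"total_patient {_excerpt(run['total_patient'])} vs "
            f"flow_of_travelers {_excerpt(run['flow_of_travelers'])}",
        )
    )

    # 2. no demand at all: shortage identically zero
    cfg = config.replace(
        parameters=dataclasses.replace(
            config.parameters,
            patient_to_population_ratio=0.0,
            travelers_to_specialists_ratio=0.0,
        ),
        scenario=ScenarioSpec.baseline(),
    )
    run = cfg.run()
    no_shortage = bool(np.all(run["shortage_bed_day"] == 0.0))
    checks.append(
        ValidityCheck(
            "zero_demand_no_shortage",
            no_shortage,
            f"shortage {_excerpt(run['shortage_bed_day'])}",
        )
    )

    # 3. vast bed supply: occupancy collapses, shortage vanishes
    cfg = config.replace(
        initial_stocks=dataclasses.replace(
            config.initial_stocks,
            number_of_bed=config.initial_stocks.number_of_bed * 1000.0,
        )
    )
    run = cfg.run()
    low_occ = float(run["bed_occupancy_rate"][0]) < 0.01
    no_shortage = bool(np.all(run["shortage_bed_day"] == 0.0))
    checks.append(
        ValidityCheck(
            "vast_beds_low_occupancy_no_shortage",
            low_occ and no_shortage,
            f"occupancy(t0)={run['bed_occupancy_rate'][0]:.6g}, "
            f"shortage {_excerpt(run['shortage_bed_day'])}",
        )
    )

    # 4. zero length of stay: no bed-days required
    cfg = config.replace(
        parameters=dataclasses.replace(config.parameters, base_length_of_stay=0.0),
        scenario=ScenarioSpec.baseline(),
    )
    run = cfg.run()
    no_required = bool(np.all(run["total_bed_day_required"] == 0.0))
    checks.append(
        ValidityCheck(
            "zero_stay_no_required_bed_days",
            no_required,
            f"required {_excerpt(run['total_bed_day_required'])}",
        )
    )

    return ValidityReport(tuple(checks))


def equilibrium_test(config: BedModelConfig, tol: float = 1e-9) -> ValidityReport:
    """With growth shut off and all feedback inert, stocks must not move.

    Sets the population growth proportion to zero, replaces all four
    lookup tables by inert ones (F1–F3 ≡ 0, F4 ≡ 1), removes any
    policy additions and scenario ramps, and checks that every stock's
    maximum relative drift over the horizon is below ``tol``.
    """
    cfg = config.replace(
        parameters=dataclasses.replace(config.parameters, growth_proportion=0.0),
        lookups=RateEffectTables.inert(),
        scenario=ScenarioSpec.baseline(),
        policy=PolicySpec.none(),
    )
    run = cfg.run()
    checks = []
    for stock in cfg.build().stocks():
        traj = run[stock.name]
        base = abs(traj[0]) if traj[0] != 0 else 1.0
        drift = float(np.max(np.abs(traj - traj[0])) / base)
        checks.append(
            ValidityCheck(
                f"equilibrium_{stock.name}",
                drift < tol,
                f"max relative drift {drift:.3e} (tol {tol:.0e})",
            )
        )
    return ValidityReport(tuple(checks))


# ---------------------------------------------------------------------------
# Lookup-slope recovery


@dataclass(frozen=True)
class LookupFit:
    """Result of fitting a lookup table's y-values to observations."""

    table: LookupTable
    residual_norm: float
    n_obs: int
    n_free: int
    underdetermined: bool
    insensitive: tuple[int, ...] = ()
    message: str = ""
    n_evals: int = 0


_DIRECTIONS = {"F1": +1, "F2": -1, "F3": -1, "F4": -1}


def _ys_from_theta(theta: np.ndarray, fixed_head: tuple[float, ...], sign: int) -> np.ndarray:
    """Monotone y-values from unconstrained parameters.

    The first free y is the anchor (or the last fixed y if any are
    fixed); each further y differs by ``sign * increment**2``, so the
    fitted table is monotone by construction.
    """
    if fixed_head:
        anchor = fixed_head[-1]
        incr = theta
    else:
        anchor = theta[0]
        incr = theta[1:]
    ys = [*fixed_head] if fixed_head else [anchor]
    cur = anchor
    for d in incr:
        cur = cur + sign * d * d
        ys.append(cur)
    return np.asarray(ys)


def _theta_from_ys(ys: Sequence[float], fixed_head_n: int, sign: int) -> np.ndarray:
    ys = np.asarray(ys, dtype=float)
    diffs = sign * np.diff(ys)
    if np.any(diffs < -1e-12):
        raise ConfigurationError("initial skeleton y-values violate monotonicity")
    incr = np.sqrt(np.clip(diffs, 0.0, None))
    if fixed_head_n:
        return incr[fixed_head_n - 1 :]
    return np.concatenate([[ys[0]], incr])


def recover_lookup_slopes(
    config: BedModelConfig,
    hist: HistoricalSeries,
    table_name: str,
    skeleton: LookupTable | None = None,
    fixed_head: int = 0,
    maxfev: int = 800,
) -> LookupFit:
    """Fit a rate-effect table's free y-values to observed trajectories.

    The x-grid is fixed (``skeleton``'s, defaulting to the config's
    current table); the free y-values minimize the summed squared
    *relative* residual between simulated and observed values at the
    historical years, by nested simulation per candidate under a
    bounded derivative-free simplex search. Monotonicity (the table's
    loop polarity) is enforced by reparameterization as cumulative
    signed squared increments. ``fixed_head`` pins that many leading
    y-values at their skeleton values (used for F4's F4(0) = 1 anchor).

    A fit is flagged under-determined — and not optimized — when there
    are fewer observations than free y-values or when some free
    y-value has (numerically) no influence on the simulated residuals,
    i.e. its breakpoint region is never visited by the driver.
    """
    if table_name not in _DIRECTIONS:
        raise ConfigurationError(f"unknown rate-effect table {table_name!r}")
    sign = _DIRECTIONS[table_name]
    base_table = config.lookups.as_dict()[table_name]
    skeleton = skeleton or base_table
    n_points = len(skeleton.points)
    n_free = n_points - fixed_head
    fixed_ys = tuple(skeleton.ys[:fixed_head])

    years = hist.years
    n_obs = sum(len(v) for v in hist.observed.values())
    obs = {
        name: np.asarray(vals, dtype=float) for name, vals in hist.observed.items()
    }
    scale = {name: np.where(v == 0.0, 1.0, np.abs(v)) for name, v in obs.items()}

    attr = {"F1": "f1", "F2": "f2", "F3": "f3", "F4": "f4"}[table_name]
    n_evals = 0

    def residuals(ys: np.ndarray) -> np.ndarray:
        nonlocal n_evals
        n_evals += 1
        candidate = skeleton.with_ys(ys)
        cfg = config.replace(lookups=config.lookups.replace(**{attr: candidate}))
        run = cfg.run()
        res = []
        for name, ob in obs.items():
            sim = np.array([run.at_time(float(y), name) for y in years])
            res.append((sim - ob) / scale[name])
        return np.concatenate(res)

    theta0 = _theta_from_ys(skeleton.ys, fixed_head, sign)

    # sensitivity screen: a free y with no effect on the residuals is
    # unidentifiable (its breakpoint region is never visited)
    base_res = residuals(_ys_from_theta(theta0, fixed_ys, sign))
    sens = np.zeros(len(theta0))
    for j in range(len(theta0)):
        tp = theta0.copy()
        eps = 0.05 * max(1.0, abs(tp[j]))
        tp[j] += eps
        sens[j] = np.max(np.abs(residuals(_ys_from_theta(tp, fixed_ys, sign)) - base_res)) / eps
    sens_scale = max(float(np.max(sens)), 1e-300)
    insensitive = tuple(int(j) for j in np.nonzero(sens / sens_scale < 1e-9)[0])

    if n_obs < n_free or insensitive:
        why = (
            f"{n_obs} observations for {n_free} free y-values"
            if n_obs < n_free
            else f"free parameter(s) {list(insensitive)} have no influence on the data"
        )
        return LookupFit(
            table=skeleton,
            residual_norm=float(np.linalg.norm(base_res)),
            n_obs=n_obs,
            n_free=n_free,
            underdetermined=True,
            insensitive=insensitive,
            message=f"under-determined fit: {why}",
            n_evals=n_evals,
        )

    def objective(theta: np.ndarray) -> float:
        r = residuals(_ys_from_theta(theta, fixed_ys, sign))
        return float(r @ r)

    result = minimize(
        objective,
        theta0,
        method="Nelder-Mead",
        options={"maxfev": maxfev, "xatol": 1e-7, "fatol": 1e-14},
    )
    ys_fit = _ys_from_theta(result.x, fixed_ys, sign)
    final_res = residuals(ys_fit)
    return LookupFit(
        table=skeleton.with_ys(ys_fit),
        residual_norm=float(np.linalg.norm(final_res)),
        n_obs=n_obs,
        n_free=n_free,
        underdetermined=False,
        message=result.message,
        n_evals=n_evals,
    )
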