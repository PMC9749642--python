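"""Deterministic stock-flow simulation core.

The engine is a generic system-dynamics simulator: a model is a registry
of variables (stocks, flows, auxiliaries, parameters) whose equations
are expression trees over each other, plus named piecewise-linear
lookup tables. Non-stock variables are evaluated in dependency
(topological) order at every time step; stocks are advanced by explicit
fixed-step Euler integration,

    stock(t + dt) = stock(t) + dt * net_flow(t),

which makes the simulation the literal difference equation of the
model — a one-stock linear model reproduces its geometric closed form
exactly. Stocks break dependency cycles: feedback loops are legal
exactly when every cycle passes through a stock.

All computation is pure float arithmetic with no hidden state, so two
runs of the same model and settings are bit-identical.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expressions import (
    Node,
    compile_expression,
    parse,
    references,
)

__all__ = [
    "ConfigurationError",
    "NumericalError",
    "LookupTable",
    "VariableDef",
    "ModelSpec",
    "SimulationSettings",
    "Defect",
    "ModelDiagnostics",
    "RunResult",
    "lookup_eval",
    "validate_model",
    "step",
    "simulate",
    "replay_stock",
]

TIME = "TIME"

_REL_TOL = 1e-9  # grid-commensurability tolerance for saveper vs dt


class ConfigurationError(ValueError):
    """A model spec, lookup table or settings object violates its contract."""


class NumericalError(ArithmeticError):
    """A non-finite value appeared during simulation."""


# ---------------------------------------------------------------------------
# Lookup tables


@dataclass(frozen=True)
class LookupTable:
    """A graphical function: ordered (x, y) breakpoints, evaluated by
    clamped piecewise-linear interpolation.

    Outside the breakpoint domain the nearest endpoint y is returned, so
    evaluation is total and finite for any real x.
    """

    name: str
    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        pts = tuple((float(x), float(y)) for x, y in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 2:
            raise ConfigurationError(
                f"lookup {self.name!r} needs at least 2 points, got {len(pts)}"
            )
        xs = [p[0] for p in pts]
        if any(b <= a for a, b in zip(xs, xs[1:])):
            raise ConfigurationError(
                f"lookup {self.name!r} x values must be strictly increasing: {xs}"
            )
        if not all(math.isfinite(x) and math.isfinite(y) for x, y in pts):
            raise ConfigurationError(f"lookup {self.name!r} has non-finite breakpoints")

    @property
    def xs(self) -> tuple[float, ...]:
        return tuple(p[0] for p in self.points)

    @property
    def ys(self) -> tuple[float, ...]:
        return tuple(p[1] for p in self.points)

    def __call__(self, x: float) -> float:
        pts = self.points
        if x <= pts[0][0]:
            return pts[0][1]
        if x >= pts[-1][0]:
            return pts[-1][1]
        # rightmost segment whose left breakpoint is <= x
        i = bisect_right([p[0] for p in pts], x) - 1
        x0, y0 = pts[i]
        x1, y1 = pts[i + 1]
        return y0 + (y1 - y0) * (x - x0) / (x1 - x0)

    def with_ys(self, ys: Sequence[float]) -> "LookupTable":
        """A copy of the table with the same x-grid and new y values."""
        if len(ys) != len(self.points):
            raise ConfigurationError("y-value count must match breakpoint count")
        return LookupTable(self.name, tuple((x, float(y)) for (x, _), y in zip(self.points, ys)))


def lookup_eval(table: LookupTable, x: float) -> float:
    """Clamped piecewise-linear evaluation of ``table`` at ``x``."""
    return table(float(x))


# ---------------------------------------------------------------------------
# Model specification


VARIABLE_KINDS = ("stock", "flow", "auxiliary", "parameter")


@dataclass(frozen=True)
class VariableDef:
    """One model variable.

    For stocks, ``equation`` is the net-flow expression (inflows minus
    outflows) and ``initial_value`` the value at start time. Parameters
    carry a constant ``value``. Flows and auxiliaries are algebraic
    equations over other variables; the distinction between the two is
    purely semantic (flows are the rates that drive stocks).
    """

    name: str
    kind: str
    equation: str | None = None
    initial_value: float | None = None
    value: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.kind not in VARIABLE_KINDS:
            raise ConfigurationError(
                f"variable {self.name!r}: unknown kind {self.kind!r}"
            )
        if self.kind == "parameter":
            if self.value is None:
                raise ConfigurationError(f"parameter {self.name!r} needs a value")
        elif self.kind == "stock":
            if self.initial_value is None:
                raise ConfigurationError(f"stock {self.name!r} needs an initial value")
            if self.equation is None:
                raise ConfigurationError(
                    f"stock {self.name!r} needs a net-flow equation"
                )
        elif self.equation is None:
            raise ConfigurationError(f"{self.kind} {self.name!r} needs an equation")


@dataclass(frozen=True)
class ModelSpec:
    """A complete equation system: variables plus lookup tables."""

    variables: Mapping[str, VariableDef]
    lookups: Mapping[str, LookupTable] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", dict(self.variables))
        object.__setattr__(self, "lookups", dict(self.lookups))

    @classmethod
    def from_definitions(
        cls, defs: Iterable[VariableDef], lookups: Iterable[LookupTable] = ()
    ) -> "ModelSpec":
        variables: dict[str, VariableDef] = {}
        for d in defs:
            if d.name in variables:
                raise ConfigurationError(f"duplicate variable {d.name!r}")
            variables[d.name] = d
        return cls(variables, {t.name: t for t in lookups})

    def stocks(self) -> list[VariableDef]:
        return [v for v in self.variables.values() if v.kind == "stock"]

    def parameters(self) -> list[VariableDef]:
        return [v for v in self.variables.values() if v.kind == "parameter"]


@dataclass(frozen=True)
class SimulationSettings:
    """Time grid: [start_time, stop_time] stepped by dt, saved every saveper.

    Times are calendar years as reals. ``saveper`` must be an integer
    multiple of ``dt`` (relative tolerance 1e-9) and the horizon an
    integer number of steps.
    """

    start_time: float = 2015.0
    stop_time: float = 2035.0
    dt: float = 1.0 / 12.0
    saveper: float | None = None

    def __post_init__(self) -> None:
        if self.saveper is None:
            object.__setattr__(self, "saveper", self.dt)
        if self.dt <= 0:
            raise ConfigurationError(f"dt must be > 0, got {self.dt}")
        if self.start_time >= self.stop_time:
            raise ConfigurationError("start_time must be < stop_time")
        for name, span in (("saveper", self.saveper), ("horizon", self.stop_time - self.start_time)):
            ratio = span / self.dt
            if abs(ratio - round(ratio)) > _REL_TOL * max(1.0, abs(ratio)):
                raise ConfigurationError(
                    f"{name} ({span}) must be an integer multiple of dt ({self.dt})"
                )

    @property
    def n_steps(self) -> int:
        return int(round((self.stop_time - self.start_time) / self.dt))

    @property
    def save_stride(self) -> int:
        return int(round(self.saveper / self.dt))


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class Defect:
    kind: str  # 'undefined-reference' | 'cycle' | 'missing-initial' | ...
    message: str
    names: tuple[str, ...] = ()


@dataclass(frozen=True)
class ModelDiagnostics:
    defects: tuple[Defect, ...]
    order: tuple[str, ...]  # topological order of non-stock, non-parameter variables

    @property
    def ok(self) -> bool:
        return not self.defects


def _parsed(var: VariableDef) -> Node:
    assert var.equation is not None
    return parse(var.equation)


def validate_model(spec: ModelSpec) -> ModelDiagnostics:
    """Check a model spec for defects and derive an evaluation order.

    Returns diagnostics, never raises: defects cover undefined
    references, malformed equations, and cycles among non-stock
    variables (stocks legally break cycles). The returned order lists
    flows and auxiliaries in a dependency-respecting sequence.
    """
    defects: list[Defect] = []
    parsed: dict[str, Node] = {}
    for name, var in spec.variables.items():
        if var.equation is not None:
            try:
                parsed[name] = _parsed(var)
            except ValueError as exc:
                defects.append(Defect("malformed-equation", f"{name}: {exc}", (name,)))

    known = set(spec.variables) | {TIME}
    for name, node in parsed.items():
        for ref in sorted(references(node)):
            if ref not in known and ref not in spec.lookups:
                defects.append(
                    Defect(
                        "undefined-reference",
                        f"equation of {name!r} references undefined {ref!r}",
                        (name, ref),
                    )
                )

    algebraic = {
        n for n, v in spec.variables.items() if v.kind in ("flow", "auxiliary")
    }
    # Kahn's algorithm on the dependency graph restricted to algebraic vars
    deps: dict[str, set[str]] = {}
    for n in algebraic:
        node = parsed.get(n)
        refs = references(node) if node is not None else set()
        deps[n] = {r for r in refs if r in algebraic}
    indeg = {n: len(d) for n, d in deps.items()}
    rdeps: dict[str, set[str]] = {n: set() for n in algebraic}
    for n, d in deps.items():
        for r in d:
            rdeps[r].add(n)
    ready = sorted(n for n, k in indeg.items() if k == 0)
    order: list[str] = []
    while ready:
        n = ready.pop(0)
        order.append(n)
        for m in sorted(rdeps[n]):
            indeg[m] -= 1
            if indeg[m] == 0:
                ready.append(m)
        ready.sort()
    if len(order) < len(algebraic):
        cyclic = tuple(sorted(n for n in algebraic if indeg[n] > 0))
        defects.append(
            Defect(
                "cycle",
                "cyclic dependency among non-stock variables: " + ", ".join(cyclic),
                cyclic,
            )
        )
    return ModelDiagnostics(tuple(defects), tuple(order))


# ---------------------------------------------------------------------------
# Compiled model & integration


class _CompiledModel:
    """Equation system compiled to closures in topological order."""

    def __init__(self, spec: ModelSpec):
        diag = validate_model(spec)
        if not diag.ok:
            msgs = "; ".join(d.message for d in diag.defects)
            raise ConfigurationError(f"model spec is not runnable: {msgs}")
        self.spec = spec
        self.param_values = {
            v.name: float(v.value) for v in spec.variables.values() if v.kind == "parameter"
        }
        self.algebraic = [
            (n, compile_expression(_parsed(spec.variables[n]), spec.lookups, n))
            for n in diag.order
        ]
        self.stock_names = [v.name for v in spec.stocks()]
        self.stock_netflows = {
            v.name: compile_expression(_parsed(v), spec.lookups, v.name)
            for v in spec.stocks()
        }
        self.stock_initials = {v.name: float(v.initial_value) for v in spec.stocks()}

    def eval_algebraic(self, env: dict, t: float) -> None:
        env[TIME] = t
        for name, fn in self.algebraic:
            v = fn(env)
            if not math.isfinite(v):
                raise NumericalError(
                    f"non-finite value for {name!r} at TIME={t}"
                )
            env[name] = v


def step(
    state: Mapping[str, float],
    spec: ModelSpec,
    t: float,
    dt: float,
) -> dict[str, float]:
    """One explicit Euler step: evaluate the algebra at ``t``, then
    advance every stock by ``dt`` times its net flow.

    ``state`` maps stock names to values (parameter overrides may be
    included and take precedence over spec values). Returns the next
    stock values. For repeated stepping use :func:`simulate`, which
    compiles the model once.
    """
    if dt <= 0:
        raise ConfigurationError(f"dt must be > 0, got {dt}")
    model = _CompiledModel(spec)
    env = dict(model.param_values)
    env.update(state)
    model.eval_algebraic(env, t)
    out = {}
    for name in model.stock_names:
        flow = model.stock_netflows[name](env)
        if not math.isfinite(flow):
            raise NumericalError(f"non-finite net flow for stock {name!r} at TIME={t}")
        out[name] = env[name] + dt * flow
    return out


@dataclass(frozen=True)
class RunResult:
    """Saved trajectories of every model variable on an even time grid."""

    times: np.ndarray
    values: dict[str, np.ndarray]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.values[name]

    def __contains__(self, name: str) -> bool:
        return name in self.values

    def at_time(self, t: float, name: str) -> float:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-6:
            raise KeyError(f"time {t} not on the saved grid")
        return float(self.values[name][i])

    def final(self, name: str) -> float:
        return float(self.values[name][-1])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table with columns time, variable, value."""
        frames = [
            pd.DataFrame({"time": self.times, "variable": name, "value": vals})
            for name, vals in self.values.items()
        ]
        return pd.concat(frames, ignore_index=True)


def simulate(spec: ModelSpec, settings: SimulationSettings) -> RunResult:
    """Integrate the model over the settings' horizon.

    Stocks start at their initial values at ``start_time``; algebra is
    evaluated at every step and all variables (stocks, flows,
    auxiliaries, parameters) are saved every ``saveper``. The final
    saved point is at ``stop_time``.
    """
    model = _CompiledModel(spec)
    n, k = settings.n_steps, settings.save_stride
    env: dict[str, float] = dict(model.param_values)
    env.update(model.stock_initials)

    names = list(spec.variables)
    saved: dict[str, list[float]] = {name: [] for name in names}
    times: list[float] = []
    start, dt = settings.start_time, settings.dt

    for i in range(n + 1):
        t = start + i * dt
        try:
            model.eval_algebraic(env, t)
        except NumericalError as exc:
            raise NumericalError(f"{exc} (step {i})") from None
        if i % k == 0 or i == n:
            times.append(t)
            for name in names:
                saved[name].append(env[name])
        if i < n:
            for name in model.stock_names:
                flow = model.stock_netflows[name](env)
                if not math.isfinite(flow):
                    raise NumericalError(
                        f"non-finite net flow for stock {name!r} at TIME={t}"
                    )
                env[name] = env[name] + dt * flow
    return RunResult(
        np.asarray(times, dtype=float),
        {name: np.asarray(vals, dtype=float) for name, vals in saved.items()},
    )


def replay_stock(spec: ModelSpec, run: RunResult, stock: str, dt: float) -> np.ndarray:
    """Reconstruct a stock trajectory from the saved algebra.

    With ``saveper == dt`` this replays the Euler recurrence exactly
    from the saved net-flow inputs, so it equals the simulated stock
    trajectory bit-for-bit — the conservation identity.
    """
    var = spec.variables[stock]
    if var.kind != "stock":
        raise ConfigurationError(f"{stock!r} is not a stock")
    fn = compile_expression(_parsed(var), spec.lookups, stock)
    n = len(run.times)
    out = np.empty(n)
    out[0] = float(var.initial_value)
    env: dict[str, float] = {}
    for i in range(n - 1):
        env.update({name: float(vals[i]) for name, vals in run.values.items()})
        env[TIME] = float(run.times[i])
        out[i + 1] = out[i] + dt * fn(env)
    return out
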