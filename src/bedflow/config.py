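"""Canonical configuration document for the bed model.

One structured YAML document fully determines a model: scalar
parameters, initial stocks, the four rate-effect lookup tables,
scenario and policy presets, simulation settings and (optionally)
synthetic-data settings. Configs are data, not code — equations are
fixed by the model structure; the document only supplies numbers.
Unknown keys are errors (fail-fast), reported with their key path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .bed_model import (
    InitialStocks,
    ModelParameters,
    RateEffectTables,
    build_bed_model,
)
from .engine import (
    ConfigurationError,
    LookupTable,
    ModelSpec,
    RunResult,
    SimulationSettings,
    simulate,
)

__all__ = [
    "ScenarioSpec",
    "PolicySpec",
    "SynthesisSettings",
    "BedModelConfig",
    "load_config",
    "save_config",
    "config_digest",
]

SCENARIO_IDS = ("S1", "S2", "S3", "S4")
POLICY_IDS = ("P1", "P2", "P3", "P4")
ARCHETYPES = ("inert", "baseline_shortage", "early_shortage")


@dataclass(frozen=True)
class ScenarioSpec:
    """An environmental-assumption set applied from the intervention
    start year: a population growth-proportion override and linear
    ramps on the aging-sensitive demand parameters.

    S1 is the status quo (no override, all ramps zero).
    """

    id: str
    growth_proportion: float | None = None  # /yr, constant from start (None = unchanged)
    patient_ratio_ramp: float = 0.0  # (patients/person/yr) per yr
    los_ramp: float = 0.0  # days per yr
    travelers_ratio_ramp: float = 0.0  # (patients/specialist/yr) per yr, may be < 0

    def __post_init__(self) -> None:
        if self.id == "S1" and (
            self.growth_proportion is not None
            or self.patient_ratio_ramp
            or self.los_ramp
            or self.travelers_ratio_ramp
        ):
            raise ConfigurationError("S1 is the baseline: no overrides or ramps allowed")

    @classmethod
    def baseline(cls) -> "ScenarioSpec":
        return cls(id="S1")


@dataclass(frozen=True)
class PolicySpec:
    """A decision-lever setting: constant extra annual inflows of beds
    and/or home-care capacity from the intervention start year.

    P1 adds nothing; P2 adds beds only; P3 adds home care only; P4 may
    add both.
    """

    id: str
    bed_addition: float = 0.0  # beds/yr
    home_care_addition: float = 0.0  # service-days/yr per yr

    def __post_init__(self) -> None:
        if self.bed_addition < 0 or self.home_care_addition < 0:
            raise ConfigurationError(
                f"policy {self.id}: negative additions are rejected "
                f"({self.bed_addition}, {self.home_care_addition})"
            )
        if self.id == "P1" and (self.bed_addition or self.home_care_addition):
            raise ConfigurationError("P1 is no-intervention: additions must be 0")
        if self.id == "P2" and self.home_care_addition:
            raise ConfigurationError("P2 adds beds only: home_care_addition must be 0")
        if self.id == "P3" and self.bed_addition:
            raise ConfigurationError("P3 adds home care only: bed_addition must be 0")

    @classmethod
    def none(cls) -> "PolicySpec":
        return cls(id="P1")


@dataclass(frozen=True)
class SynthesisSettings:
    """Controls for the synthetic-data generator."""

    seed: int = 0
    noise_sd: float = 0.05  # lognormal sigma of multiplicative observation noise
    archetype: str = "baseline_shortage"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.archetype not in ARCHETYPES:
            raise ConfigurationError(
                f"unknown archetype {self.archetype!r}; choose from {ARCHETYPES}"
            )


@dataclass(frozen=True)
class BedModelConfig:
    """Everything needed to build and run the model."""

    parameters: ModelParameters
    initial_stocks: InitialStocks
    lookups: RateEffectTables
    simulation: SimulationSettings = SimulationSettings()
    intervention_start: float = 2020.0
    scenario: ScenarioSpec = field(default_factory=ScenarioSpec.baseline)
    policy: PolicySpec = field(default_factory=PolicySpec.none)
    scenarios: Mapping[str, ScenarioSpec] = field(default_factory=dict)
    policies: Mapping[str, PolicySpec] = field(default_factory=dict)
    synthesis: SynthesisSettings | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "scenarios", dict(self.scenarios))
        object.__setattr__(self, "policies", dict(self.policies))

    # -- model construction -------------------------------------------------
    def build(self) -> ModelSpec:
        return build_bed_model(
            self.parameters,
            self.initial_stocks,
            self.lookups,
            scenario=self.scenario,
            policy=self.policy,
            intervention_start=self.intervention_start,
        )

    def run(self) -> RunResult:
        return simulate(self.build(), self.simulation)

    def replace(self, **changes: Any) -> "BedModelConfig":
        return dataclasses.replace(self, **changes)

    def resolve_scenario(self, scenario_id: str) -> ScenarioSpec:
        if scenario_id == "S1" and "S1" not in self.scenarios:
            return ScenarioSpec.baseline()
        try:
            return self.scenarios[scenario_id]
        except KeyError:
            raise ConfigurationError(
                f"unknown scenario {scenario_id!r}; defined: {sorted(self.scenarios)}"
            ) from None

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "parameters": dataclasses.asdict(self.parameters),
            "initial_stocks": dataclasses.asdict(self.initial_stocks),
            "lookups": {
                name: [[x, y] for x, y in table.points]
                for name, table in self.lookups.as_dict().items()
            },
            "simulation": dataclasses.asdict(self.simulation),
            "intervention_start": self.intervention_start,
            "scenario": dataclasses.asdict(self.scenario),
            "policy": dataclasses.asdict(self.policy),
            "scenarios": {k: dataclasses.asdict(v) for k, v in self.scenarios.items()},
            "policies": {k: dataclasses.asdict(v) for k, v in self.policies.items()},
        }
        if self.synthesis is not None:
            d["synthesis"] = dataclasses.asdict(self.synthesis)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "BedModelConfig":
        _strict(
            data,
            {
                "parameters", "initial_stocks", "lookups", "simulation",
                "intervention_start", "scenario", "policy", "scenarios",
                "policies", "synthesis",
            },
            path="",
        )
        params = _build_dataclass(ModelParameters, data.get("parameters", {}), "parameters")
        init = _build_dataclass(InitialStocks, data.get("initial_stocks", {}), "initial_stocks")
        lookups = _lookups_from_dict(_require(data, "lookups"))
        sim = _build_dataclass(SimulationSettings, data.get("simulation", {}), "simulation")
        scenario = (
            _build_dataclass(ScenarioSpec, data["scenario"], "scenario")
            if "scenario" in data
            else ScenarioSpec.baseline()
        )
        policy = (
            _build_dataclass(PolicySpec, data["policy"], "policy")
            if "policy" in data
            else PolicySpec.none()
        )
        scenarios = {
            k: _build_dataclass(ScenarioSpec, v, f"scenarios.{k}")
            for k, v in data.get("scenarios", {}).items()
        }
        policies = {
            k: _build_dataclass(PolicySpec, v, f"policies.{k}")
            for k, v in data.get("policies", {}).items()
        }
        synthesis = (
            _build_dataclass(SynthesisSettings, data["synthesis"], "synthesis")
            if "synthesis" in data
            else None
        )
        return cls(
            parameters=params,
            initial_stocks=init,
            lookups=lookups,
            simulation=sim,
            intervention_start=float(data.get("intervention_start", 2020.0)),
            scenario=scenario,
            policy=policy,
            scenarios=scenarios,
            policies=policies,
            synthesis=synthesis,
        )


def _require(data: Mapping[str, Any], key: str) -> Any:
    if key not in data:
        raise ConfigurationError(f"missing required config section {key!r}")
    return data[key]


def _strict(data: Mapping[str, Any], allowed: set[str], path: str) -> None:
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"config section {path or '<root>'!r} must be a mapping")
    unknown = set(data) - allowed
    if unknown:
        where = path or "<root>"
        raise ConfigurationError(
            f"unknown config key(s) {sorted(unknown)} under {where!r}; "
            f"allowed: {sorted(allowed)}"
        )


def _build_dataclass(cls: type, data: Mapping[str, Any], path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    _strict(data, names, path)
    required = {
        f.name
        for f in dataclasses.fields(cls)
        if f.default is dataclasses.MISSING and f.default_factory is dataclasses.MISSING
    }
    missing = required - set(data)
    if missing:
        raise ConfigurationError(f"missing required key(s) {sorted(missing)} under {path!r}")
    try:
        return cls(**data)
    except TypeError as exc:
        raise ConfigurationError(f"bad value under {path!r}: {exc}") from None


def _lookups_from_dict(data: Mapping[str, Any]) -> RateEffectTables:
    _strict(data, {"F1", "F2", "F3", "F4"}, "lookups")
    tables = {}
    for name in ("F1", "F2", "F3", "F4"):
        pts = _require(data, name)
        tables[name] = LookupTable(name, tuple((float(x), float(y)) for x, y in pts))
    return RateEffectTables(f1=tables["F1"], f2=tables["F2"], f3=tables["F3"], f4=tables["F4"])


def load_config(path: str | Path) -> BedModelConfig:
    """Read a configuration document from YAML."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        raise ConfigurationError(f"empty config file {path}")
    return BedModelConfig.from_dict(data)


def save_config(config: BedModelConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_digest(config: BedModelConfig) -> str:
    """Content hash of a config, stable under key reordering."""
    canonical = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()
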