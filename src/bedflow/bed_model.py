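"""The hospital-bed distribution model.

Four stocks — population, hospital beds, specialist physicians and
home-care capacity — are coupled through demand-side accounting
(bed-days required vs. bed-days supplied, with effective occupancy
capped at an optimal rate) and four nonlinear "rate effects", each a
piecewise-linear lookup table:

* F1: bed occupancy rate → fractional growth of home-care capacity
  (non-decreasing: full hospitals motivate home-care providers);
* F2: specialist-to-bed ratio → fractional growth of specialists
  (non-increasing: scarce specialists per bed attract more);
* F3: bed-to-patient ratio → fractional growth of beds
  (non-increasing: few beds per patient accelerate construction);
* F4: home-care-day to bed-day ratio → multiplier on the base length
  of stay (non-increasing with F4(0) = 1: home care substitutes for
  hospital days and shortens stays).

Stock inflows close as ``stock × rate_effect`` (fractional growth per
year), the standard stock-flow growth pattern; the population is
exogenous with a constant growth proportion. The model's headline
output is ``shortage_bed_day``: annual bed-day demand in excess of the
optimal-occupancy share of supply.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Mapping, NamedTuple

from .engine import (
    ConfigurationError,
    LookupTable,
    ModelSpec,
    VariableDef,
    lookup_eval,
)

__all__ = [
    "DAYS_PER_YEAR",
    "ModelParameters",
    "InitialStocks",
    "RateEffectTables",
    "DemandBlock",
    "GrowthBlock",
    "build_bed_model",
    "eval_demand_block",
    "eval_growth_block",
]

DAYS_PER_YEAR = 365.0


@dataclass(frozen=True)
class ModelParameters:
    """Scalar parameters of the bed model.

    ``travelers_to_specialists_ratio`` (patients drawn to the city per
    specialist per year) and ``base_length_of_stay`` (days per patient
    before home-care substitution) have no published city values and
    must be supplied by configuration; the synthetic fixture ships
    placeholder values.
    """

    travelers_to_specialists_ratio: float
    base_length_of_stay: float
    growth_proportion: float = 0.014  # fraction of population per year
    patient_to_population_ratio: float = 0.129  # patients per person per year
    optimal_occupancy: float = 0.85  # fraction
    days_per_year: float = DAYS_PER_YEAR

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ConfigurationError(f"parameter {f.name} must be nonnegative, got {v}")
        if not (0.0 < self.optimal_occupancy <= 1.0):
            raise ConfigurationError(
                f"optimal_occupancy must be in (0, 1], got {self.optimal_occupancy}"
            )
        if self.days_per_year != DAYS_PER_YEAR:
            raise ConfigurationError("days_per_year is fixed at 365")


@dataclass(frozen=True)
class InitialStocks:
    """Initial stock levels (defaults: the study city's 2015 values)."""

    population: float = 1_557_600.0  # persons
    number_of_bed: float = 3560.0  # beds
    number_of_specialist_physicians: float = 690.0  # specialists
    capacity_of_home_care_services: float = 76_650.0  # service-days / year

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ConfigurationError(f"initial {f.name} must be nonnegative, got {v}")


@dataclass(frozen=True)
class RateEffectTables:
    """The four rate-effect lookup tables, with their loop-polarity
    monotonicity invariants enforced at construction."""

    f1: LookupTable  # occupancy rate -> home-care growth /yr (non-decreasing)
    f2: LookupTable  # specialist/bed -> specialist growth /yr (non-increasing)
    f3: LookupTable  # bed/patient -> bed growth /yr (non-increasing)
    f4: LookupTable  # home-care share -> LOS multiplier (non-increasing, F4(0)=1)

    def __post_init__(self) -> None:
        _check_monotone(self.f1, increasing=True, label="F1")
        _check_monotone(self.f2, increasing=False, label="F2")
        _check_monotone(self.f3, increasing=False, label="F3")
        _check_monotone(self.f4, increasing=False, label="F4")
        if abs(lookup_eval(self.f4, 0.0) - 1.0) > 1e-12:
            raise ConfigurationError(
                f"F4(0) must equal 1 (no home care leaves length of stay unadjusted), "
                f"got {lookup_eval(self.f4, 0.0)}"
            )

    def as_dict(self) -> dict[str, LookupTable]:
        return {"F1": self.f1, "F2": self.f2, "F3": self.f3, "F4": self.f4}

    def replace(self, **tables: LookupTable) -> "RateEffectTables":
        from dataclasses import replace as _replace

        return _replace(self, **tables)

    @classmethod
    def inert(cls) -> "RateEffectTables":
        """Feedback-free tables: zero growth everywhere, unadjusted stay."""
        flat0 = ((0.0, 0.0), (1.0, 0.0))
        return cls(
            f1=LookupTable("F1", flat0),
            f2=LookupTable("F2", flat0),
            f3=LookupTable("F3", flat0),
            f4=LookupTable("F4", ((0.0, 1.0), (1.0, 1.0))),
        )


def _check_monotone(table: LookupTable, *, increasing: bool, label: str) -> None:
    ys = table.ys
    pairs = zip(ys, ys[1:])
    ok = all(b >= a for a, b in pairs) if increasing else all(b <= a for a, b in zip(ys, ys[1:]))
    if not ok:
        direction = "non-decreasing" if increasing else "non-increasing"
        raise ConfigurationError(f"{label} ({table.name!r}) must be {direction}: ys={ys}")


def _num(x: float) -> str:
    return repr(float(x))


def build_bed_model(
    params: ModelParameters,
    init: InitialStocks,
    lookups: RateEffectTables,
    *,
    scenario=None,
    policy=None,
    intervention_start: float = 2020.0,
) -> ModelSpec:
    """Assemble the full equation system as a :class:`ModelSpec`.

    ``scenario`` (environmental ramps on the exogenous parameters) and
    ``policy`` (constant exogenous capacity additions from
    ``intervention_start`` on) are optional duck-typed objects; omitted,
    the baseline model is returned. When a scenario ramps a parameter,
    that parameter becomes a time-varying auxiliary.
    """
    t0 = _num(intervention_start)
    defs: list[VariableDef] = []

    # --- exogenous parameters, possibly promoted to ramped auxiliaries
    def param_or_ramp(name: str, base: float, ramp: float, clamp: bool = False) -> None:
        if scenario is None or ramp == 0.0:
            defs.append(VariableDef(name, "parameter", value=base))
            return
        eq = f"{_num(base)} + {_num(ramp)} * MAX(0, TIME - {t0})"
        if clamp:
            eq = f"MAX(0, {eq})"
        defs.append(VariableDef(name, "auxiliary", equation=eq))

    param_or_ramp(
        "patient_to_population_ratio",
        params.patient_to_population_ratio,
        getattr(scenario, "patient_ratio_ramp", 0.0) if scenario else 0.0,
    )
    param_or_ramp(
        "base_length_of_stay",
        params.base_length_of_stay,
        getattr(scenario, "los_ramp", 0.0) if scenario else 0.0,
    )
    param_or_ramp(
        "travelers_to_specialists_ratio",
        params.travelers_to_specialists_ratio,
        getattr(scenario, "travelers_ratio_ramp", 0.0) if scenario else 0.0,
        clamp=True,
    )
    growth_override = getattr(scenario, "growth_proportion", None) if scenario else None
    if growth_override is None or growth_override == params.growth_proportion:
        defs.append(VariableDef("growth_proportion", "parameter", value=params.growth_proportion))
    else:
        defs.append(
            VariableDef(
                "growth_proportion",
                "auxiliary",
                equation=(
                    f"IF_THEN_ELSE(TIME < {t0}, "
                    f"{_num(params.growth_proportion)}, {_num(growth_override)})"
                ),
            )
        )
    defs.append(VariableDef("optimal_occupancy", "parameter", value=params.optimal_occupancy))
    defs.append(VariableDef("days_per_year", "parameter", value=params.days_per_year))

    # --- policy levers: constant extra inflow once the policy starts
    bed_add = float(getattr(policy, "bed_addition", 0.0) or 0.0) if policy else 0.0
    hc_add = float(getattr(policy, "home_care_addition", 0.0) or 0.0) if policy else 0.0
    defs.append(
        VariableDef(
            "bed_policy_inflow",
            "auxiliary",
            equation=f"IF_THEN_ELSE(TIME >= {t0}, {_num(bed_add)}, 0)",
            units="beds/year",
        )
    )
    defs.append(
        VariableDef(
            "home_care_policy_inflow",
            "auxiliary",
            equation=f"IF_THEN_ELSE(TIME >= {t0}, {_num(hc_add)}, 0)",
            units="service-days/year/year",
        )
    )

    # --- stocks
    defs += [
        VariableDef("population", "stock", equation="growth_rate",
                    initial_value=init.population, units="persons"),
        VariableDef("number_of_bed", "stock", equation="bed_increase_rate",
                    initial_value=init.number_of_bed, units="beds"),
        VariableDef("number_of_specialist_physicians", "stock",
                    equation="specialist_increase_rate",
                    initial_value=init.number_of_specialist_physicians,
                    units="specialists"),
        VariableDef("capacity_of_home_care_services", "stock",
                    equation="home_care_increase_rate",
                    initial_value=init.capacity_of_home_care_services,
                    units="service-days/year"),
    ]

    # --- demand-side auxiliaries
    defs += [
        VariableDef("flow_of_travelers", "auxiliary",
                    equation="number_of_specialist_physicians * travelers_to_specialists_ratio",
                    units="patients/year"),
        VariableDef("total_patient", "auxiliary",
                    equation="flow_of_travelers + population * patient_to_population_ratio",
                    units="patients/year"),
        VariableDef("total_bed_day", "auxiliary",
                    equation="number_of_bed * days_per_year", units="bed-days/year"),
        VariableDef("home_care_share", "auxiliary",
                    equation="capacity_of_home_care_services / total_bed_day",
                    units="fraction"),
        VariableDef("rate_effect_4", "auxiliary", equation="F4(home_care_share)"),
        VariableDef("length_of_stay", "auxiliary",
                    equation="base_length_of_stay * rate_effect_4", units="days"),
        VariableDef("total_bed_day_required", "auxiliary",
                    equation="total_patient * length_of_stay", units="bed-days/year"),
        VariableDef(
            "bed_occupancy_day", "auxiliary",
            equation=(
                "IF_THEN_ELSE(total_bed_day_required <= total_bed_day * optimal_occupancy, "
                "total_bed_day_required, total_bed_day * optimal_occupancy)"
            ),
            units="bed-days/year",
        ),
        VariableDef("bed_occupancy_rate", "auxiliary",
                    equation="bed_occupancy_day / total_bed_day", units="fraction"),
        VariableDef("shortage_bed_day", "auxiliary",
                    equation="MAX(0, total_bed_day_required - optimal_occupancy * total_bed_day)",
                    units="bed-days/year"),
        VariableDef("specialist_to_bed_ratio", "auxiliary",
                    equation="number_of_specialist_physicians / number_of_bed",
                    units="specialists/bed"),
        VariableDef("bed_to_patient_ratio", "auxiliary",
                    equation="number_of_bed / total_patient", units="beds/patient"),
    ]

    # --- rate effects and the flows they drive
    defs += [
        VariableDef("rate_effect_1", "auxiliary", equation="F1(bed_occupancy_rate)",
                    units="/year"),
        VariableDef("rate_effect_2", "auxiliary", equation="F2(specialist_to_bed_ratio)",
                    units="/year"),
        VariableDef("rate_effect_3", "auxiliary", equation="F3(bed_to_patient_ratio)",
                    units="/year"),
        VariableDef("growth_rate", "flow", equation="growth_proportion * population",
                    units="persons/year"),
        VariableDef("bed_increase_rate", "flow",
                    equation="number_of_bed * rate_effect_3 + bed_policy_inflow",
                    units="beds/year"),
        VariableDef("specialist_increase_rate", "flow",
                    equation="number_of_specialist_physicians * rate_effect_2",
                    units="specialists/year"),
        VariableDef("home_care_increase_rate", "flow",
                    equation="capacity_of_home_care_services * rate_effect_1 "
                             "+ home_care_policy_inflow",
                    units="service-days/year/year"),
    ]

    return ModelSpec.from_definitions(defs, lookups.as_dict().values())


class DemandBlock(NamedTuple):
    total_patient: float
    total_bed_day: float
    total_bed_day_required: float
    bed_occupancy_day: float
    bed_occupancy_rate: float
    shortage_bed_day: float


def eval_demand_block(
    population: float,
    specialists: float,
    beds: float,
    length_of_stay: float,
    params: ModelParameters,
) -> DemandBlock:
    """Demand-side accounting for a single instant.

    total patients = travelers (specialists × travel ratio) plus the
    population-sourced term; bed-day demand = patients × length of
    stay; occupied bed-days are capped at the optimal-occupancy share
    of supply, and any excess demand is the bed-day shortage. A zero
    bed stock yields zero occupancy rate (division guard).
    """
    flow_of_travelers = specialists * params.travelers_to_specialists_ratio
    total_patient = flow_of_travelers + population * params.patient_to_population_ratio
    total_bed_day = beds * params.days_per_year
    required = total_patient * length_of_stay
    cap = total_bed_day * params.optimal_occupancy
    occupancy_day = required if required <= cap else cap
    occupancy_rate = occupancy_day / total_bed_day if total_bed_day != 0.0 else 0.0
    shortage = max(0.0, required - cap)
    return DemandBlock(total_patient, total_bed_day, required,
                       occupancy_day, occupancy_rate, shortage)


class GrowthBlock(NamedTuple):
    rate_effect_1: float
    rate_effect_2: float
    rate_effect_3: float
    rate_effect_4: float
    bed_increase_rate: float
    specialist_increase_rate: float
    home_care_increase_rate: float
    length_of_stay: float


def eval_growth_block(
    stocks: Mapping[str, float],
    drivers: Mapping[str, float],
    lookups: RateEffectTables,
    params: ModelParameters,
) -> GrowthBlock:
    """Supply-side feedback for a single instant.

    ``drivers`` must provide ``bed_occupancy_rate``,
    ``specialist_to_bed_ratio``, ``bed_to_patient_ratio`` and
    ``home_care_share``. Each inflow closes as stock × fractional rate
    from its lookup; the length of stay is the base value scaled by F4.
    """
    r1 = lookup_eval(lookups.f1, drivers["bed_occupancy_rate"])
    r2 = lookup_eval(lookups.f2, drivers["specialist_to_bed_ratio"])
    r3 = lookup_eval(lookups.f3, drivers["bed_to_patient_ratio"])
    r4 = lookup_eval(lookups.f4, drivers["home_care_share"])
    return GrowthBlock(
        rate_effect_1=r1,
        rate_effect_2=r2,
        rate_effect_3=r3,
        rate_effect_4=r4,
        bed_increase_rate=stocks["number_of_bed"] * r3,
        specialist_increase_rate=stocks["number_of_specialist_physicians"] * r2,
        home_care_increase_rate=stocks["capacity_of_home_care_services"] * r1,
        length_of_stay=params.base_length_of_stay * r4,
    )
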