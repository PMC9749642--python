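"""Simulation core: validation diagnostics, Euler stepping, determinism."""

import numpy as np
import pytest

from bedflow.engine import (
    ConfigurationError,
    ModelSpec,
    SimulationSettings,
    VariableDef,
    replay_stock,
    simulate,
    step,
    validate_model,
)
from bedflow.expressions import DivisionByZeroWarning, compile_expression, parse
from bedflow.synth import random_config


def population_spec(growth=0.014, initial=1_557_600.0):
    return ModelSpec.from_definitions(
        [
            VariableDef("growth_proportion", "parameter", value=growth),
            VariableDef("population", "stock", equation="growth_rate", initial_value=initial),
            VariableDef("growth_rate", "flow", equation="growth_proportion * population"),
        ]
    )


class TestValidateModel:
    def test_well_formed_spec_is_clean(self, fixture_config):
        diag = validate_model(fixture_config.build())
        assert diag.ok
        assert diag.defects == ()
        assert len(diag.order) > 0

    def test_cycle_between_auxiliaries_is_reported(self):
        spec = ModelSpec.from_definitions(
            [
                VariableDef("A", "auxiliary", equation="B"),
                VariableDef("B", "auxiliary", equation="A"),
            ]
        )
        diag = validate_model(spec)
        assert not diag.ok
        (defect,) = [d for d in diag.defects if d.kind == "cycle"]
        assert set(defect.names) == {"A", "B"}

    def test_stock_breaks_cycles(self):
        # flow depends on the stock it drives: legal feedback
        diag = validate_model(population_spec())
        assert diag.ok

    def test_undefined_reference_is_reported(self):
        spec = ModelSpec.from_definitions(
            [VariableDef("A", "auxiliary", equation="LengthOfStay2 * 2")]
        )
        diag = validate_model(spec)
        kinds = {d.kind for d in diag.defects}
        assert "undefined-reference" in kinds
        assert any("LengthOfStay2" in d.names for d in diag.defects)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ConfigurationError, match="duplicate"):
            ModelSpec.from_definitions(
                [
                    VariableDef("A", "parameter", value=1.0),
                    VariableDef("A", "parameter", value=2.0),
                ]
            )


class TestStep:
    def test_one_euler_step_of_population_growth(self):
        nxt = step({"population": 1_557_600.0}, population_spec(), t=2015.0, dt=1.0)
        assert nxt["population"] == pytest.approx(1_579_406.4, rel=1e-12)

    def test_zero_dt_rejected(self):
        with pytest.raises(ConfigurationError):
            step({"population": 1.0}, population_spec(), t=2015.0, dt=0.0)

    def test_zero_flows_leave_stocks_unchanged(self):
        spec = ModelSpec.from_definitions(
            [
                VariableDef("S", "stock", equation="F", initial_value=42.0),
                VariableDef("F", "flow", equation="0 * S"),
            ]
        )
        assert step({"S": 42.0}, spec, t=0.0, dt=1.0) == {"S": 42.0}


class TestSimulate:
    def test_compound_growth_matches_closed_form(self):
        """An isolated stock with fractional growth IS the geometric
        difference equation: x(t) = x0 * (1 + r*dt)^(t/dt)."""
        settings = SimulationSettings(start_time=0.0, stop_time=20.0, dt=1.0)
        run = simulate(population_spec(), settings)
        expected = 1_557_600.0 * (1.014 ** np.arange(21))
        np.testing.assert_allclose(run["population"], expected, rtol=1e-12)
        assert run.final("population") == pytest.approx(1_557_600.0 * 1.014**20, rel=1e-12)

    def test_parameter_only_model_is_constant(self):
        spec = ModelSpec.from_definitions(
            [
                VariableDef("p", "parameter", value=3.5),
                VariableDef("q", "auxiliary", equation="p * 2"),
            ]
        )
        run = simulate(spec, SimulationSettings(start_time=0.0, stop_time=5.0, dt=0.25))
        assert np.all(run["p"] == 3.5)
        assert np.all(run["q"] == 7.0)

    def test_algebraic_trajectory_independent_of_dt(self):
        spec = ModelSpec.from_definitions(
            [
                VariableDef("p", "parameter", value=2.0),
                VariableDef("q", "auxiliary", equation="p * TIME"),
            ]
        )
        coarse = simulate(spec, SimulationSettings(0.0, 4.0, dt=1.0, saveper=1.0))
        fine = simulate(spec, SimulationSettings(0.0, 4.0, dt=0.5, saveper=1.0))
        np.testing.assert_array_equal(coarse["q"], fine["q"])

    def test_determinism_bit_identical(self, fixture_config):
        a = fixture_config.run()
        b = fixture_config.run()
        assert np.array_equal(a.times, b.times)
        for name in a.values:
            assert np.array_equal(a[name], b[name]), name

    def test_conservation_replay_exact(self):
        """stock(t+dt) - stock(t) equals dt x net flow, replayable
        bit-exactly from the saved trajectories when saveper = dt."""
        rng = np.random.default_rng(7)
        cfg = random_config(rng)
        run = cfg.run()
        spec = cfg.build()
        for stock in spec.stocks():
            replayed = replay_stock(spec, run, stock.name, cfg.simulation.dt)
            assert np.array_equal(replayed, run[stock.name]), stock.name


class TestSettings:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(dt=0.0),
            dict(dt=-1.0),
            dict(start_time=2020.0, stop_time=2015.0),
            dict(dt=1.0, saveper=2.5),  # not an integer multiple
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationSettings(**{"start_time": 2015.0, "stop_time": 2035.0, **kwargs})


class TestExpressions:
    def test_division_by_zero_guard_warns_and_returns_zero(self):
        fn = compile_expression(parse("a / b"), {}, context="ratio")
        with pytest.warns(DivisionByZeroWarning, match="ratio"):
            assert fn({"a": 1.0, "b": 0.0, "TIME": 0.0}) == 0.0
        assert fn({"a": 6.0, "b": 3.0, "TIME": 0.0}) == 2.0

    def test_if_then_else_and_min_max(self):
        fn = compile_expression(parse("IF_THEN_ELSE(a <= b, MIN(a, b), MAX(a, b))"), {})
        assert fn({"a": 1.0, "b": 2.0}) == 1.0
        assert fn({"a": 5.0, "b": 2.0}) == 5.0

    def test_operator_precedence(self):
        fn = compile_expression(parse("1 + 2 * 3 - 4 / 2"), {})
        assert fn({}) == 5.0

    def test_malformed_equations_rejected(self):
        for bad in ["", "1 +", "foo(", "a @ b", "IF_THEN_ELSE(1, 2)"]:
            with pytest.raises(ValueError):
                compile_expression(parse(bad), {})
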