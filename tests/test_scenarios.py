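"""Scenario application, policy levers, shortage detection, solver."""

import dataclasses

import numpy as np
import pytest

from bedflow.config import PolicySpec, ScenarioSpec
from bedflow.engine import ConfigurationError, RunResult
from bedflow.scenarios import (
    apply_policy,
    apply_scenario,
    first_shortage_time,
    peak_shortage,
    scenario_policy_sweep,
    solve_min_intervention,
)


def shortage_run(values):
    values = np.asarray(values, dtype=float)
    times = 2015.0 + np.arange(values.size) / 12.0
    return RunResult(times, {"shortage_bed_day": values})


class TestApplyScenario:
    def test_baseline_scenario_is_identity(self, fixture_config):
        assert apply_scenario(fixture_config, "S1") == fixture_config

    def test_input_config_is_not_mutated(self, fixture_config):
        before = fixture_config.scenario
        apply_scenario(fixture_config, "S2")
        assert fixture_config.scenario == before

    def test_unknown_scenario_id_rejected(self, fixture_config):
        with pytest.raises(ConfigurationError, match="S9"):
            apply_scenario(fixture_config, "S9")

    def test_patient_ratio_ramp_starts_flat_then_rises(self, fixture_config):
        run = apply_scenario(fixture_config, "S2").run()
        ratio = run["patient_to_population_ratio"]
        start = fixture_config.parameters.patient_to_population_ratio
        pre = ratio[run.times <= fixture_config.intervention_start]
        post = ratio[run.times > fixture_config.intervention_start]
        assert np.all(pre == start)
        assert np.all(np.diff(post) > 0)

    def test_negative_travelers_ramp_never_raises_traveler_flow(self, fixture_config):
        """With physicians distributed more evenly elsewhere, the travel
        stream can only fall relative to the status quo."""
        base = fixture_config.run()
        ramped = apply_scenario(
            fixture_config,
            ScenarioSpec(id="S4", travelers_ratio_ramp=-1.0),
        ).run()
        assert np.all(ramped["flow_of_travelers"] <= base["flow_of_travelers"] + 1e-9)
        assert np.all(ramped["travelers_to_specialists_ratio"] >= 0.0)

    def test_s1_with_ramps_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioSpec(id="S1", los_ramp=0.1)


class TestApplyPolicy:
    def test_no_intervention_policy_is_identity(self, fixture_config):
        assert apply_policy(fixture_config, PolicySpec.none()) == fixture_config

    def test_negative_additions_rejected(self):
        with pytest.raises(ConfigurationError):
            PolicySpec(id="P2", bed_addition=-10.0)

    def test_policy_kind_constraints(self):
        with pytest.raises(ConfigurationError):
            PolicySpec(id="P2", bed_addition=10.0, home_care_addition=5.0)
        with pytest.raises(ConfigurationError):
            PolicySpec(id="P3", bed_addition=10.0)

    def test_bed_additions_accumulate_linearly_with_inert_feedback(self, inert_config):
        """100 beds/yr over 10 active years is exactly 1000 extra beds
        when every feedback loop is flat."""
        cfg = inert_config.replace(
            simulation=dataclasses.replace(inert_config.simulation, stop_time=2030.0)
        )
        base = cfg.run()
        boosted = apply_policy(cfg, PolicySpec(id="P2", bed_addition=100.0)).run()
        extra = boosted.final("number_of_bed") - base.final("number_of_bed")
        assert extra == pytest.approx(1000.0, rel=1e-12)

    def test_p4_weakly_dominates_no_intervention_end_states(self, fixture_config):
        base = fixture_config.run()
        boosted = apply_policy(
            fixture_config, PolicySpec(id="P4", bed_addition=50.0, home_care_addition=5000.0)
        ).run()
        assert boosted.final("number_of_bed") >= base.final("number_of_bed")
        assert boosted.final("capacity_of_home_care_services") >= base.final(
            "capacity_of_home_care_services"
        )


class TestFirstShortageTime:
    def test_no_shortage_returns_none(self):
        assert first_shortage_time(shortage_run(np.zeros(50))) is None

    def test_onset_index_arithmetic(self):
        values = np.zeros(40)
        values[26:] = 5.0
        assert first_shortage_time(shortage_run(values)) == pytest.approx(26 / 12)

    def test_threshold_is_strict(self):
        values = np.full(10, 3.0)
        assert first_shortage_time(shortage_run(values), threshold=3.0) is None
        assert first_shortage_time(shortage_run(values), threshold=2.9) == 0.0

    def test_missing_variable_is_contract_error(self):
        run = RunResult(np.arange(3.0), {"x": np.zeros(3)})
        with pytest.raises(KeyError):
            first_shortage_time(run)


class TestSolver:
    def test_no_shortage_baseline_returns_zero_intervention(self, inert_config):
        policy = solve_min_intervention(inert_config, "P2")
        assert policy == PolicySpec(id="P2")

    def test_solved_policies_eliminate_shortage(self, fixture_config):
        for pid in ("P2", "P3"):
            policy = solve_min_intervention(fixture_config, pid, tol=1.0)
            rerun = apply_policy(fixture_config, policy).run()
            assert peak_shortage(rerun) <= 1.0

    def test_p4_needs_no_more_beds_than_p2(self, fixture_config):
        p2 = solve_min_intervention(fixture_config, "P2", tol=1.0)
        p4 = solve_min_intervention(fixture_config, "P4", tol=1.0)
        assert p4.bed_addition <= p2.bed_addition
        assert p4.home_care_addition > 0.0  # genuinely mixed

    def test_unknown_policy_id_rejected(self, fixture_config):
        with pytest.raises(ConfigurationError):
            solve_min_intervention(fixture_config, "P1")


class TestSweep:
    def test_single_scenario_sweep_shape_and_consistency(self, fixture_config):
        rows = scenario_policy_sweep(fixture_config, scenario_ids=("S1",))
        assert [r.policy_id for r in rows] == ["P1", "P2", "P3", "P4"]
        direct = fixture_config.run()
        p1 = rows[0]
        assert p1.end_beds == direct.final("number_of_bed")
        assert p1.end_home_care == direct.final("capacity_of_home_care_services")
        assert p1.bed_addition == 0.0 and p1.home_care_addition == 0.0

    def test_sweep_is_deterministic(self, fixture_config):
        a = scenario_policy_sweep(fixture_config, scenario_ids=("S1",), policy_ids=("P1", "P2"))
        b = scenario_policy_sweep(fixture_config, scenario_ids=("S1",), policy_ids=("P1", "P2"))
        assert a == b
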