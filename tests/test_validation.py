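"""Historical fit metrics, marginal-limit tests, equilibrium, recovery."""

import dataclasses

import numpy as np
import pytest

from bedflow.bed_model import RateEffectTables
from bedflow.config import SynthesisSettings
from bedflow.engine import LookupTable, RunResult
from bedflow.validation import (
    HistoricalSeries,
    compare_to_history,
    equilibrium_test,
    extreme_condition_suite,
    recover_lookup_slopes,
)
from bedflow.synth import gen_config, gen_history, recovery_fixture


def make_run(years, values_by_var):
    times = np.asarray(years, dtype=float)
    return RunResult(times, {k: np.asarray(v, dtype=float) for k, v in values_by_var.items()})


class TestCompareToHistory:
    def test_identical_series_scores_zero(self, inert_config):
        hist = gen_history(inert_config, SynthesisSettings(seed=1, noise_sd=0.0))
        fit = compare_to_history(inert_config.run(), hist)
        assert fit.worst_mape == 0.0
        assert all(v == 0.0 for v in fit.rmse.values())

    def test_constant_bias_gives_its_percentage(self):
        years = (2015, 2016, 2017)
        run = make_run(years, {"beds": [110.0, 220.0, 330.0]})
        hist = HistoricalSeries(years, {"beds": (100.0, 200.0, 300.0)})
        fit = compare_to_history(run, hist)
        assert fit.mape["beds"] == pytest.approx(10.0, rel=1e-12)

    def test_mape_is_scale_invariant(self):
        years = (2015, 2016)
        for c in (0.5, 3.0, 1e6):
            a = compare_to_history(
                make_run(years, {"x": [1.1, 2.2]}), HistoricalSeries(years, {"x": (1.0, 2.0)})
            )
            b = compare_to_history(
                make_run(years, {"x": [1.1 * c, 2.2 * c]}),
                HistoricalSeries(years, {"x": (1.0 * c, 2.0 * c)}),
            )
            assert a.mape["x"] == pytest.approx(b.mape["x"], rel=1e-9)

    def test_zero_observations_excluded_with_warning(self):
        years = (2015, 2016)
        run = make_run(years, {"x": [1.0, 2.0]})
        hist = HistoricalSeries(years, {"x": (0.0, 2.0)})
        with pytest.warns(UserWarning, match="zero observation"):
            fit = compare_to_history(run, hist)
        assert fit.mape["x"] == 0.0

    def test_missing_run_variable_raises(self):
        run = make_run((2015, 2016), {"x": [1.0, 2.0]})
        hist = HistoricalSeries((2015, 2016), {"y": (1.0, 2.0)})
        with pytest.raises(KeyError, match="y"):
            compare_to_history(run, hist)

    def test_noisy_synthetic_history_scores_small_mape(self, inert_config):
        settings = SynthesisSettings(seed=11, noise_sd=0.05)
        hist = gen_history(inert_config, settings)
        fit = compare_to_history(inert_config.run(), hist)
        assert 0.0 < fit.worst_mape < 15.0  # 3 sigma of 5% multiplicative noise


class TestExtremeConditions:
    def test_all_marginal_limits_pass_on_fixture(self, fixture_config):
        report = extreme_condition_suite(fixture_config)
        assert report.ok, report.failed()
        assert len(report.checks) == 4
        assert len({c.name for c in report.checks}) == 4

    def test_suite_does_not_mutate_config(self, fixture_config):
        before = fixture_config.to_dict()
        extreme_condition_suite(fixture_config)
        assert fixture_config.to_dict() == before


class TestEquilibrium:
    def test_stocks_hold_at_equilibrium(self, fixture_config):
        report = equilibrium_test(fixture_config)
        assert report.ok, report.failed()

    @pytest.mark.parametrize("dt", [1.0, 1.0 / 12.0])
    def test_equilibrium_independent_of_dt(self, fixture_config, dt):
        cfg = fixture_config.replace(
            simulation=dataclasses.replace(fixture_config.simulation, dt=dt, saveper=None)
        )
        assert equilibrium_test(cfg).ok

    def test_single_active_loop_moves_only_its_stock(self, inert_config):
        """Perturbing F1 to a positive constant grows home care while the
        other inert stocks stay put."""
        lookups = RateEffectTables.inert().replace(
            f1=LookupTable("F1", ((0.0, 0.01), (1.0, 0.01)))
        )
        run = inert_config.replace(lookups=lookups).run()
        hc = run["capacity_of_home_care_services"]
        assert hc[-1] > hc[0]
        for frozen in ("number_of_bed", "number_of_specialist_physicians", "population"):
            assert np.all(run[frozen] == run[frozen][0])


class TestLookupRecovery:
    def test_noiseless_recovery_of_bed_growth_table(self):
        """Fitting F3's free y-values on a noiseless synthetic history
        recovers the generating table to 1% relative."""
        config, truth, hist = recovery_fixture("F3", seed=3)
        skeleton = truth.with_ys(np.asarray(truth.ys) * 1.3)  # offset initial guess
        fit = recover_lookup_slopes(config, hist, "F3", skeleton=skeleton)
        assert not fit.underdetermined
        rel_err = np.abs(np.array(fit.table.ys) - np.array(truth.ys)) / np.array(truth.ys)
        assert np.max(rel_err) < 0.01, fit

    def test_zero_information_history_is_underdetermined(self, inert_config):
        """An inert loop leaves the driver frozen, so interior
        breakpoints are unidentifiable."""
        hist = gen_history(inert_config, SynthesisSettings(seed=5, noise_sd=0.0))
        beds_only = HistoricalSeries(hist.years, {"number_of_bed": hist.observed["number_of_bed"]})
        skeleton = LookupTable(
            "F3", ((0.005, 0.01), (0.01, 0.008), (0.02, 0.004), (0.04, 0.001))
        )
        fit = recover_lookup_slopes(inert_config, beds_only, "F3", skeleton=skeleton)
        assert fit.underdetermined
        assert "under-determined" in fit.message

    def test_monotonicity_enforced_on_fitted_table(self):
        config, truth, hist = recovery_fixture("F2", seed=1)
        fit = recover_lookup_slopes(config, hist, "F2", maxfev=200)
        ys = fit.table.ys
        assert all(b <= a + 1e-12 for a, b in zip(ys, ys[1:]))
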