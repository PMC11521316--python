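"""Percent-error metric and capacity grid fitting."""

import numpy as np
import pytest

from guildflux.core import ModelError
from guildflux.fitting import (
    CapacityParameterSet,
    default_search_space,
    fit_exchange_capacities,
    percent_error,
)
from guildflux.steadycom import SolverSettings
from guildflux.synthetic import loading_condition, make_synthetic_observation

FAST = SolverSettings(mu_tolerance=1e-5)


class TestPercentError:
    def test_perfect_prediction_scores_zero(self):
        per_guild, avg = percent_error({"A": 0.5, "B": 0.5}, {"A": 0.5, "B": 0.5})
        assert per_guild == {"A": 0.0, "B": 0.0}
        assert avg == 0.0

    def test_double_everything_is_100_percent(self):
        per_guild, avg = percent_error({"A": 0.6, "B": 0.8}, {"A": 0.3, "B": 0.4})
        assert per_guild == pytest.approx({"A": 100.0, "B": 100.0})
        assert avg == pytest.approx(100.0)

    def test_unweighted_mean_of_reported_guild_errors(self):
        """Per-guild errors like the calibrated full-scale run (0.31, 10.79,
        5.61) average to 5.57."""
        avg = float(np.mean([0.31, 10.79, 5.61]))
        assert avg == pytest.approx(5.57, abs=0.005)

    def test_zero_observed_is_undefined(self):
        with pytest.raises(ModelError, match="percent error undefined"):
            percent_error({"A": 0.5}, {"A": 0.0})

    def test_guild_mismatch_rejected(self):
        with pytest.raises(ModelError, match="guild sets differ"):
            percent_error({"A": 1.0}, {"B": 1.0})


class TestCapacityParameterSet:
    def test_crossed_interval_rejected(self):
        with pytest.raises(ModelError, match="exceeds upper"):
            CapacityParameterSet({("G", "m", "lower"): 2.0, ("G", "m", "upper"): 1.0})

    def test_apply_mutates_the_model(self, toy_model):
        model = toy_model.copy()
        CapacityParameterSet({("SRB", "h2s", "upper"): 7.77}).apply(model)
        assert model.get_capacity("SRB", "h2s", "upper") == 7.77


@pytest.fixture(scope="module")
def fit_setup(toy_model, toy_spec):
    """Noise-free observation at a loading where both capacities bind."""
    slope = (2.09 - 0.77) / (3.61 - 0.48)
    db = toy_spec.butyrate
    condition = loading_condition(
        toy_spec, toy_spec.butyrate + db, toy_spec.acetate + slope * db, label="phase2"
    )
    observed = make_synthetic_observation(
        toy_model, condition, noise_sd=0.0, seed=0, settings=FAST
    )
    return condition, observed


class TestGridFit:
    def test_degenerate_single_point_grid(self, toy_model, fit_setup):
        condition, observed = fit_setup
        grid = {("SRB", "h2s", "upper"): [9.0]}
        result = fit_exchange_capacities(toy_model, condition, observed, grid, FAST)
        assert result.best.entries == {("SRB", "h2s", "upper"): 9.0}
        assert len(result.search_trace) == 1

    def test_best_is_the_trace_minimum(self, toy_model, fit_setup):
        condition, observed = fit_setup
        grid = {
            ("MET", "ac", "upper"): [-11.55 * f for f in (0.8, 1.0, 1.25)],
            ("SRB", "h2s", "upper"): [6.28 * f for f in (0.8, 1.0, 1.25)],
        }
        result = fit_exchange_capacities(toy_model, condition, observed, grid, FAST)
        errors = [r["average_error"] for r in result.search_trace]
        assert result.average_error == min(errors)
        assert len(result.search_trace) == 9

    def test_truth_recovered_from_noise_free_observation(self, toy_model, fit_setup):
        condition, observed = fit_setup
        grid = {
            ("MET", "ac", "upper"): [-11.55 * f for f in (0.8, 1.0, 1.25)],
            ("SRB", "h2s", "upper"): [6.28 * f for f in (0.8, 1.0, 1.25)],
        }
        result = fit_exchange_capacities(toy_model, condition, observed, grid, FAST)
        assert result.best.entries[("MET", "ac", "upper")] == pytest.approx(-11.55)
        assert result.best.entries[("SRB", "h2s", "upper")] == pytest.approx(6.28)
        assert result.average_error < 1.0

    def test_finer_grid_containing_best_never_increases_error(self, toy_model, fit_setup):
        condition, observed = fit_setup
        coarse = {("SRB", "h2s", "upper"): [4.0, 6.28, 9.0]}
        first = fit_exchange_capacities(toy_model, condition, observed, coarse, FAST)
        best = first.best.entries[("SRB", "h2s", "upper")]
        fine = {("SRB", "h2s", "upper"): sorted({4.0, 5.0, best, 7.0, 9.0})}
        second = fit_exchange_capacities(toy_model, condition, observed, fine, FAST)
        assert second.average_error <= first.average_error + 1e-12

    def test_sequential_mode_matches_joint_on_separable_axes(self, toy_model, fit_setup):
        condition, observed = fit_setup
        grid = {
            ("MET", "ac", "upper"): [-11.55 * f for f in (0.8, 1.0, 1.25)],
            ("SRB", "h2s", "upper"): [6.28 * f for f in (0.8, 1.0, 1.25)],
        }
        joint = fit_exchange_capacities(toy_model, condition, observed, grid, FAST,
                                        mode="joint")
        seq = fit_exchange_capacities(toy_model, condition, observed, grid, FAST,
                                      mode="sequential")
        assert seq.best.entries == joint.best.entries

    def test_all_points_infeasible_is_reported(self, toy_model, toy_spec):
        from guildflux.conditions import ConditionSpec

        observed = {"SRB": 0.2, "MET": 0.3, "SOB": 0.5}
        grid = {("SRB", "h2s", "upper"): [6.28]}
        result = fit_exchange_capacities(
            toy_model, ConditionSpec("closed", {}), observed, grid, FAST
        )
        assert result.best is None
        assert result.status == "all-points-infeasible"

    def test_observed_must_sum_to_x0(self, toy_model, fit_setup):
        condition, _ = fit_setup
        with pytest.raises(ModelError, match="sum to"):
            fit_exchange_capacities(
                toy_model, condition, {"SRB": 0.2, "MET": 0.2, "SOB": 0.2},
                {("SRB", "h2s", "upper"): [6.28]}, FAST,
            )

    def test_default_search_space_brackets_current_values(self, toy_model):
        space = default_search_space(toy_model, [("SRB", "h2s", "upper")], n_points=5)
        grid = space[("SRB", "h2s", "upper")]
        assert len(grid) == 5
        assert min(grid) == pytest.approx(0.628)
        assert max(grid) == pytest.approx(62.8)
        assert any(abs(v - 6.28) < 1e-9 for v in grid)
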