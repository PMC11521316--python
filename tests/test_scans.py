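"""Sensitivity scans and phase detection."""

import numpy as np
import pytest

from guildflux.scans import (
    ScanPoint,
    ScanResult,
    capacity_scan_2d,
    detect_transition,
    h_plus_sweep,
    olr_sweep,
)
from guildflux.steadycom import SolverSettings

FAST = SolverSettings(mu_tolerance=1e-5)


@pytest.fixture(scope="module")
def loading_sweep(toy_model, low_condition, toy_spec):
    """Joint organic sweep from the low-loading point to twice its level,
    following the butyrate/acetate gradient direction."""
    b0, a0 = toy_spec.butyrate, toy_spec.acetate
    slope = (2.09 - 0.77) / (3.61 - 0.48)
    return olr_sweep(
        toy_model, low_condition,
        butyrate_range=(b0, 2 * b0),
        acetate_range=(a0, a0 + slope * b0),
        n_points=13, settings=FAST,
    )


class TestOlrSweep:
    def test_degenerate_sweep_returns_identical_solutions(self, toy_model, low_condition, toy_spec):
        scan = olr_sweep(
            toy_model, low_condition,
            butyrate_range=(toy_spec.butyrate, toy_spec.butyrate),
            acetate_range=(toy_spec.acetate, toy_spec.acetate),
            n_points=2, settings=FAST,
        )
        p1, p2 = scan.points
        assert p1.mu == pytest.approx(p2.mu, abs=1e-9)
        for g in p1.abundances:
            assert p1.abundances[g] == pytest.approx(p2.abundances[g], abs=1e-8)

    def test_dominance_flips_from_sob_to_met(self, loading_sweep):
        dominance = loading_sweep.dominance
        assert dominance[0] == "SOB"
        assert dominance[-1] == "MET"
        flip = dominance.index("MET")
        assert all(d == "SOB" for d in dominance[:flip])
        assert all(d == "MET" for d in dominance[flip:])

    def test_growth_rate_nondecreasing_along_loading(self, loading_sweep):
        """Loading sweeps only relax community bounds, so mu* cannot drop."""
        mus = [p.mu for p in loading_sweep.points]
        assert all(b >= a - 1e-5 for a, b in zip(mus, mus[1:]))

    def test_normalized_series_span_unit_interval(self, loading_sweep):
        series = loading_sweep.normalized_series["Vex(but)^SRB"]
        mags = [abs(v) for v in series.values]
        assert max(mags) == pytest.approx(1.0)
        assert min(mags) == pytest.approx(0.0)
        raw = loading_sweep.exchange_series("SRB", "but")
        assert all(np.sign(n) == np.sign(r) for n, r in zip(series.values, raw) if n != 0)

    def test_solver_invariants_hold_at_every_point(self, loading_sweep):
        for p in loading_sweep.points:
            assert p.status == "optimal"
            assert sum(p.abundances.values()) == pytest.approx(1.0, abs=1e-8)


class TestDetectTransition:
    def test_monotone_single_guild_scan_has_no_dominance_switch(self):
        points = [
            ScanPoint({"x": float(i)}, "optimal", 0.1 * (i + 1), {"A": 1.0}, {})
            for i in range(5)
        ]
        scan = ScanResult({"x": [float(i) for i in range(5)]}, points)
        boundaries = detect_transition(scan, "A")
        assert [b for b in boundaries if b["kind"] == "dominance_switch"] == []
        assert [b for b in boundaries if b["kind"] == "slope_break"] == []

    def test_step_series_boundary_at_the_step(self):
        abundances = [0.8, 0.8, 0.8, 0.2, 0.2]
        points = [
            ScanPoint({"x": float(i)}, "optimal", 1.0,
                      {"A": a, "B": 1 - a}, {})
            for i, a in enumerate(abundances)
        ]
        scan = ScanResult({"x": [float(i) for i in range(5)]}, points)
        boundaries = detect_transition(scan, "A")
        switches = [b for b in boundaries if b["kind"] == "dominance_switch"]
        steps = [b for b in boundaries if b["kind"] == "max_step"]
        assert switches[0]["index"] == 3
        assert steps[0]["index"] == 3

    def test_toy_sweep_yields_switch_and_slope_break_in_order(self, loading_sweep):
        boundaries = detect_transition(loading_sweep, "SOB", axis="butyrate")
        kinds = [b["kind"] for b in boundaries]
        assert "dominance_switch" in kinds
        assert "slope_break" in kinds
        switch = next(b for b in boundaries if b["kind"] == "dominance_switch")
        brk = next(b for b in boundaries if b["kind"] == "slope_break")
        # the sulfide-oxidizer growth plateau and the dominance change are
        # the same episode: they fall within a few grid points
        assert abs(switch["index"] - brk["index"]) <= 3


class TestCapacityScan:
    def test_tiny_capacities_prevent_sulfide_oxidizer_dominance(
        self, toy_model, low_condition
    ):
        """With negligible SRB-SOB exchange capacities the sulfide oxidizers
        cannot grow, so they never dominate; wherever the community is
        feasible the methanogens take over."""
        result = capacity_scan_2d(
            toy_model, low_condition,
            sob_acetate_lb_range=(-1e-4, -1e-4),
            srb_sulfide_ub_range=(1e-4, 1e-4),
            n_capacity_points=1,
            loading_scales=[1.0, 1.5, 2.0],
            settings=FAST,
        )
        (cell,) = result["cells"]
        assert "SOB" not in cell["dominance"]
        feasible = [d for d in cell["dominance"] if d is not None]
        assert feasible and all(d == "MET" for d in feasible)

    def test_stronger_coupling_tolerates_more_loading(self, toy_model, low_condition):
        """Raising both SRB-SOB capacities moves the disruption point to
        higher organic loading."""
        scales = [float(s) for s in np.linspace(1.0, 1.6, 25)]
        result = capacity_scan_2d(
            toy_model, low_condition,
            sob_acetate_lb_range=(-1.05, -3.15),
            srb_sulfide_ub_range=(4.39, 13.18),
            n_capacity_points=2,
            loading_scales=scales,
            settings=FAST,
        )
        by_key = {
            (round(c["sob_acetate_lb"], 2), round(c["srb_sulfide_ub"], 2)): c
            for c in result["cells"]
        }
        weak = by_key[(-1.05, 4.39)]
        strong = by_key[(-3.15, 13.18)]
        assert weak["transition_scale"] is not None
        assert (strong["transition_scale"] is None
                or strong["transition_scale"] > weak["transition_scale"])
        assert weak["butyrate_increase_pct"] == pytest.approx(
            100 * (weak["transition_scale"] - 1)
        )


class TestProtonSweep:
    def test_minimum_bound_matches_plain_high_loading_solution(
        self, toy_model, high_condition, high_solution
    ):
        scan = h_plus_sweep(toy_model, high_condition, n_points=5, settings=FAST)
        first = scan.points[0]
        for g, x in high_solution.abundances.items():
            assert first.abundances[g] == pytest.approx(x, abs=2e-4)

    def test_sob_abundance_nondecreasing_in_proton_supply(
        self, toy_model, high_condition
    ):
        scan = h_plus_sweep(toy_model, high_condition, n_points=9, settings=FAST)
        sob = scan.abundance_series("SOB")
        assert all(b >= a - 1e-6 for a, b in zip(sob, sob[1:]))
        boundaries = detect_transition(scan, "MET", axis="h_uptake")
        assert any(b["kind"] == "max_step" for b in boundaries)
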