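"""Flux fold change, min-max normalization, ratios and partitions."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from guildflux.analytics import (
    FFCRecord,
    compare_solutions,
    exchange_ratio,
    flux_fold_change,
    minmax_normalize,
    nadh_partition,
)

nonzero = st.floats(min_value=1e-3, max_value=1e3)


class TestFluxFoldChange:
    @pytest.mark.parametrize(
        "v_h, v_l, expected",
        [
            (2.0, 1.0, 1.0),
            (7.5, 7.5, 0.0),
            (-2.0, -1.0, 1.0),
            (1.56, 1.0, 0.64),  # the seasonal butyrate-uptake fold change
        ],
    )
    def test_values(self, v_h, v_l, expected):
        value, flag = flux_fold_change(v_h, v_l)
        assert flag == "ok"
        assert value == pytest.approx(expected, abs=5e-3)

    @pytest.mark.parametrize(
        "v_h, v_l, flag",
        [
            (1.0, 5e-7, "zeroed_L"),
            (5e-7, 1.0, "zeroed_H"),
            (1e-9, -1e-9, "both_zero"),
            (1.0, -1.0, "sign_discordant"),
        ],
    )
    def test_flags(self, v_h, v_l, flag):
        value, got = flux_fold_change(v_h, v_l, zero_threshold=1e-6)
        assert value is None and got == flag

    @settings(derandomize=True, max_examples=50)
    @given(a=nonzero, b=nonzero)
    def test_antisymmetry(self, a, b):
        fab, _ = flux_fold_change(a, b)
        fba, _ = flux_fold_change(b, a)
        assert fab == pytest.approx(-fba, abs=1e-9)

    @settings(derandomize=True, max_examples=50)
    @given(a=nonzero, b=nonzero, c=nonzero)
    def test_additivity(self, a, b, c):
        fac, _ = flux_fold_change(a, c)
        fab, _ = flux_fold_change(a, b)
        fbc, _ = flux_fold_change(b, c)
        assert fac == pytest.approx(fab + fbc, abs=1e-9)

    def test_categories_follow_the_cut_points(self):
        assert FFCRecord("r", "g", 1, 1, 0.3, "ok").category == "low"
        assert FFCRecord("r", "g", 1, 1, -0.8, "ok").category == "medium"
        assert FFCRecord("r", "g", 1, 1, 2.5, "ok").category == "high"
        assert FFCRecord("r", "g", 0, 0, None, "both_zero").category is None


class TestMinMaxNormalization:
    def test_plain_series(self):
        assert minmax_normalize([1, 2, 3]).values == pytest.approx([0.0, 0.5, 1.0])

    def test_signs_reinstated(self):
        assert minmax_normalize([-1, -2, -4]).values == pytest.approx([0.0, -1 / 3, -1.0])

    def test_constant_series_flagged(self):
        series = minmax_normalize([5, 5, 5])
        assert series.constant
        assert series.values == [0.0, 0.0, 0.0]

    def test_idempotence_on_normalized_series(self):
        once = minmax_normalize([0.3, -1.4, 0.9, 0.0])
        twice = minmax_normalize(once.values)
        assert twice.values == pytest.approx(once.values, abs=1e-12)

    def test_bounds_invariant(self):
        values = minmax_normalize([0.2, -3.0, 7.0, 1.1]).values
        assert max(abs(v) for v in values) == pytest.approx(1.0)
        assert min(abs(v) for v in values) == pytest.approx(0.0)


class TestRatiosAndPartitions:
    def test_equal_exchange_fluxes_give_unit_ratio(self, low_solution):
        ratio, flag = exchange_ratio(low_solution, "ac", "MET", "MET")
        assert flag == "ok" and ratio == pytest.approx(1.0)

    def test_met_consumes_more_acetate_than_sob(self, low_solution, high_solution):
        """The methanogens out-consume the sulfide oxidizers on acetate,
        and more strongly so under high loading."""
        r_low, _ = exchange_ratio(low_solution, "ac", "MET", "SOB")
        r_high, _ = exchange_ratio(high_solution, "ac", "MET", "SOB")
        assert r_low > 1.0
        assert r_high > r_low

    def test_zero_denominator_flagged_infinite(self, low_solution):
        ratio, flag = exchange_ratio(low_solution, "ch4", "MET", "SRB")
        assert flag == "infinite" and math.isinf(ratio)

    def test_partition_of_equal_flux_sets_is_100_percent(self, low_solution):
        value, flag = nadh_partition(
            low_solution, "SRB", ["SRB__BUOX"], ["SRB__BUOX"]
        )
        assert flag == "ok" and value == pytest.approx(100.0)

    def test_partition_arithmetic(self, low_solution):
        """Constructed fluxes (1+1)/(4+0) give 50%."""
        sol = low_solution.__class__(
            mu=1.0,
            abundances={"G": 1.0},
            fluxes={"G": {"n1": 1.0, "n2": 1.0, "d1": 4.0, "d2": 0.0}},
            exchange_fluxes={"G": {}},
            community_uptake={},
            community_export={},
        )
        value, flag = nadh_partition(sol, "G", ["n1", "n2"], ["d1", "d2"])
        assert flag == "ok" and value == pytest.approx(50.0)

    def test_partition_undefined_for_zero_denominator(self, low_solution):
        sol = low_solution.__class__(
            mu=1.0, abundances={"G": 1.0}, fluxes={"G": {"a": 1.0, "b": 0.0}},
            exchange_fluxes={"G": {}}, community_uptake={}, community_export={},
        )
        _, flag = nadh_partition(sol, "G", ["a"], ["b"])
        assert flag == "undefined"

    def test_sulfate_respiration_share_declines_at_high_loading(
        self, low_solution, high_solution
    ):
        """The share of butyrate-derived reducing power routed into sulfate
        respiration drops when loading rises (electron-acceptor shortage)."""
        share_low, _ = nadh_partition(low_solution, "SRB", ["SRB__SRED"], ["SRB__BUOX"])
        share_high, _ = nadh_partition(high_solution, "SRB", ["SRB__SRED"], ["SRB__BUOX"])
        assert share_high < share_low

    def test_ratios_invariant_to_community_rescaling(
        self, toy_model, low_condition, low_solution
    ):
        from guildflux.conditions import apply_condition
        from guildflux.steadycom import maximize_growth

        scaled = toy_model.copy()
        scaled.x0 = 2.0
        sol2 = maximize_growth(apply_condition(scaled, low_condition))
        r1, _ = exchange_ratio(low_solution, "ac", "MET", "SOB")
        r2, _ = exchange_ratio(sol2, "ac", "MET", "SOB")
        assert r2 == pytest.approx(r1, rel=1e-3)


class TestSolutionComparison:
    def test_ffc_table_covers_exchanges_and_reactions(self, low_solution, high_solution):
        comparison = compare_solutions(low_solution, high_solution)
        butyrate = comparison.record("SRB", "vex(but)")
        assert butyrate.flag == "ok"
        # community butyrate uptake rises 1.56-fold between the seasons
        assert butyrate.ffc == pytest.approx(math.log2(1.56), abs=1e-3)
        assert butyrate.category == "medium"
        assert any(r.id == "SRB__BUOX" for r in comparison.records)

    def test_tsv_is_well_formed(self, low_solution, high_solution, tmp_path):
        comparison = compare_solutions(low_solution, high_solution)
        text = comparison.to_tsv(tmp_path / "ffc.tsv")
        header, *rows = text.strip().split("\n")
        assert header.split("\t") == ["id", "guild", "V_L", "V_H", "FFC", "flag", "category"]
        assert len(rows) == len(comparison.records)
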