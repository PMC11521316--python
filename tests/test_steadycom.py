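"""Community growth solver: oracles, invariants, flux resolution."""

import numpy as np
import pytest

from guildflux.conditions import ConditionSpec, apply_condition
from guildflux.core import GuildModel, Reaction, assemble_community
from guildflux.sbml import guild_to_cobra
from guildflux.steadycom import (
    SolverSettings,
    conservation_residuals,
    guild_balance_residuals,
    maximize_growth,
    resolve_fluxes,
    solve_at_growth,
)

from conftest import cross_feeding_pair, single_substrate_guild, substrate_condition


def grid_search_growth(model, mu_max, step=1e-4):
    """Brute-force oracle: largest feasible mu on a regular grid."""
    best = 0.0
    for mu in np.arange(step, mu_max + step, step):
        res = solve_at_growth(model, float(mu))
        if res.total_abundance >= model.x0 - 1e-9:
            best = float(mu)
        else:
            break  # feasibility is monotone in mu
    return best


def single_guild_community(bound=10.0, yield_per_substrate=0.5):
    guild = single_substrate_guild("A", yield_per_substrate)
    model = assemble_community([guild])
    return apply_condition(model, substrate_condition(bound))


class TestFixedGrowthLP:
    def test_capacity_not_binding_below_fba_max(self):
        model = single_guild_community(bound=10.0, yield_per_substrate=0.5)
        res = solve_at_growth(model, 1.0)  # FBA max is 5.0
        assert res.total_abundance >= 1.0

    def test_above_fba_max_cannot_reach_unit_abundance(self):
        model = single_guild_community(bound=10.0, yield_per_substrate=0.5)
        fba_max = guild_to_cobra(
            model.guilds[0], model.uptake_bounds, model.export_bounds
        ).optimize().objective_value
        res = solve_at_growth(model, fba_max * 1.01)
        assert res.total_abundance < 1.0

    def test_no_substrate_means_no_growth(self):
        guild = single_substrate_guild("A")
        model = apply_condition(assemble_community([guild]), ConditionSpec("empty", {}))
        res = solve_at_growth(model, 0.5)
        assert res.total_abundance == pytest.approx(0.0, abs=1e-9)

    def test_max_abundance_nonincreasing_in_mu(self):
        model = single_guild_community()
        totals = [solve_at_growth(model, mu).total_abundance for mu in (0.5, 1.0, 2.0, 4.0)]
        assert all(a >= b - 1e-9 for a, b in zip(totals, totals[1:]))


class TestMaximizeGrowth:
    def test_single_guild_matches_standalone_fba(self):
        """Degenerate one-guild community: mu* is the plain FBA optimum."""
        model = single_guild_community(bound=10.0, yield_per_substrate=0.5)
        sol = maximize_growth(model, SolverSettings(mu_tolerance=1e-7))
        fba = guild_to_cobra(
            model.guilds[0], model.uptake_bounds, model.export_bounds
        ).optimize()
        assert sol.mu == pytest.approx(fba.objective_value, abs=1e-6)

    def test_cross_feeding_chain_matches_grid_oracle(self):
        model, condition = cross_feeding_pair()
        conditioned = apply_condition(model, condition)
        sol = maximize_growth(conditioned, SolverSettings(mu_tolerance=1e-6))
        oracle = grid_search_growth(conditioned, mu_max=2 * sol.mu + 0.01)
        assert sol.mu == pytest.approx(oracle, abs=1e-4 + 1e-6)

    def test_empty_condition_reports_infeasible_growth(self, toy_model):
        model = apply_condition(toy_model, ConditionSpec("closed", {}))
        sol = maximize_growth(model)
        assert sol.mu == 0.0
        assert sol.status == "infeasible-growth"

    def test_abundances_sum_to_x0(self, low_solution, toy_model):
        assert low_solution.total_abundance == pytest.approx(toy_model.x0, abs=1e-8)
        assert all(x >= -1e-12 for x in low_solution.abundances.values())

    def test_biomass_coupling(self, low_solution, toy_model):
        for g in toy_model.guilds:
            v_bio = low_solution.flux(g.guild_id, g.biomass_reaction)
            assert v_bio == pytest.approx(
                low_solution.abundances[g.guild_id] * low_solution.mu, abs=1e-8
            )

    def test_mass_balance_residuals(self, low_solution, toy_model):
        assert max(guild_balance_residuals(toy_model, low_solution).values()) < 1e-8
        assert max(abs(v) for v in conservation_residuals(toy_model, low_solution).values()) < 1e-8

    def test_relaxation_monotonicity(self, toy_model, low_condition):
        """Enlarging a capacity interval never decreases mu*."""
        base = maximize_growth(apply_condition(toy_model, low_condition)).mu
        relaxed_model = toy_model.copy()
        relaxed_model.set_capacity("SRB", "h2s", "upper", 20.0)
        relaxed = maximize_growth(apply_condition(relaxed_model, low_condition)).mu
        assert relaxed >= base - 1e-6

    def test_x0_scaling_consistency(self, toy_model, low_condition):
        """Scaling X0 by c scales X and V by c and leaves mu* unchanged."""
        sol1 = maximize_growth(apply_condition(toy_model, low_condition))
        scaled_model = toy_model.copy()
        scaled_model.x0 = 3.0
        sol3 = maximize_growth(apply_condition(scaled_model, low_condition))
        assert sol3.mu == pytest.approx(sol1.mu, abs=2e-6)
        for g, x in sol1.abundances.items():
            assert sol3.abundances[g] == pytest.approx(3 * x, rel=1e-4, abs=1e-6)


class TestFluxResolution:
    def test_parsimony_zeroes_free_cycle(self):
        guild = single_substrate_guild("A", 0.5)
        guild.reactions.append(Reaction("A__FWD", {"A__u": -1, "A__v": 1}, 0, 1000))
        guild.reactions.append(Reaction("A__REV", {"A__v": -1, "A__u": 1}, 0, 1000))
        model = apply_condition(assemble_community([guild]), substrate_condition(10.0))
        sol = maximize_growth(model)
        resolved = resolve_fluxes(model, sol)
        assert resolved.flux("A", "A__FWD") == 0.0
        assert resolved.flux("A", "A__REV") == 0.0

    def test_exchange_fluxes_preserved(self, toy_model, low_condition, low_solution):
        model = apply_condition(toy_model, low_condition)
        resolved = resolve_fluxes(model, low_solution)
        for gid, ex in low_solution.exchange_fluxes.items():
            for met, v in ex.items():
                if abs(v) > 1e-6:
                    assert resolved.vex(gid, met) == pytest.approx(v, abs=1e-6, rel=1e-4)

    def test_equal_cost_alternative_pathways_reach_enumerated_minimum(self):
        """Two parallel routes s -> b: parsimony matches the brute-force
        minimum total |V| over all route splits."""
        guild = GuildModel(
            guild_id="A",
            reactions=[
                Reaction("A__EX_s", {"A__s": -1}, -1000, 0),
                Reaction("A__ROUTE1", {"A__s": -1, "A__b": 1}, 0, 1000),
                Reaction("A__ROUTE2", {"A__s": -1, "A__b": 1}, 0, 1000),
                Reaction("A__BIOMASS", {"A__b": -1}, 0, 1000),
            ],
            biomass_reaction="A__BIOMASS",
            exchange_reactions={"A__EX_s": "s"},
        )
        model = apply_condition(assemble_community([guild]), substrate_condition(4.0))
        sol = maximize_growth(model)
        resolved = resolve_fluxes(model, sol)
        total = abs(resolved.flux("A", "A__ROUTE1")) + abs(resolved.flux("A", "A__ROUTE2"))
        # any split r1 + r2 = V_bio has total |V| >= V_bio; enumeration over
        # splits attains exactly V_bio
        assert total == pytest.approx(resolved.flux("A", "A__BIOMASS"), abs=1e-6)
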