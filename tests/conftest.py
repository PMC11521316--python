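"""Shared fixtures: the toy community and a few hand-sized micro-models."""

from __future__ import annotations

import pytest

from guildflux.conditions import ConditionSpec, apply_condition
from guildflux.core import Reaction, GuildModel, assemble_community
from guildflux.steadycom import SolverSettings, maximize_growth
from guildflux.synthetic import (
    ToyCommunitySpec,
    high_loading_condition,
    low_loading_condition,
    make_toy_community,
)


@pytest.fixture(scope="session")
def toy_spec() -> ToyCommunitySpec:
    return ToyCommunitySpec()


@pytest.fixture(scope="session")
def toy_model(toy_spec):
    return make_toy_community(toy_spec)


@pytest.fixture(scope="session")
def low_condition(toy_spec):
    return low_loading_condition(toy_spec)


@pytest.fixture(scope="session")
def high_condition(toy_spec):
    return high_loading_condition(toy_spec)


@pytest.fixture(scope="session")
def low_solution(toy_model, low_condition):
    return maximize_growth(apply_condition(toy_model, low_condition), SolverSettings())


@pytest.fixture(scope="session")
def high_solution(toy_model, high_condition):
    return maximize_growth(apply_condition(toy_model, high_condition), SolverSettings())


def single_substrate_guild(gid: str = "A", yield_per_substrate: float = 1.0) -> GuildModel:
    """One guild growing directly on one substrate ``s``.

    Biomass yield is ``yield_per_substrate`` per unit substrate, so with a
    community influx bound U the standalone FBA growth maximum is
    ``U * yield_per_substrate``.
    """
    return GuildModel(
        guild_id=gid,
        reactions=[
            Reaction(f"{gid}__EX_s", {f"{gid}__s": -1}, -1000.0, 0.0),
            Reaction(
                f"{gid}__BIOMASS", {f"{gid}__s": -1.0 / yield_per_substrate}, 0.0, 1000.0
            ),
        ],
        biomass_reaction=f"{gid}__BIOMASS",
        exchange_reactions={f"{gid}__EX_s": "s"},
    )


def cross_feeding_pair() -> tuple:
    """Obligate chain: A grows on s and secretes p; B grows only on p."""
    a = GuildModel(
        guild_id="A",
        reactions=[
            Reaction("A__EX_s", {"A__s": -1}, -1000.0, 0.0),
            Reaction("A__EX_p", {"A__p": -1}, 0.0, 1000.0),
            Reaction("A__GROW", {"A__s": -1, "A__p": 2}, 0.0, 1000.0),
            Reaction("A__BIOMASS", {"A__p": -1}, 0.0, 1000.0),
        ],
        biomass_reaction="A__BIOMASS",
        exchange_reactions={"A__EX_s": "s", "A__EX_p": "p"},
    )
    b = GuildModel(
        guild_id="B",
        reactions=[
            Reaction("B__EX_p", {"B__p": -1}, -1000.0, 0.0),
            Reaction("B__BIOMASS", {"B__p": -1}, 0.0, 1000.0),
        ],
        biomass_reaction="B__BIOMASS",
        exchange_reactions={"B__EX_p": "p"},
    )
    model = assemble_community([a, b])
    condition = ConditionSpec("chain", {"s": 0.25})
    return model, condition


def substrate_condition(bound: float = 10.0) -> ConditionSpec:
    return ConditionSpec("substrate", {"s": bound})
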