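"""Guild and community model containers.

A *guild* is a functionally lumped microbial cohort represented by one
stoichiometric compartment (e.g. sulfate-reducing bacteria, acetoclastic
methanogens, sulfide-oxidizing bacteria).  Guilds are joined through a
fictitious shared extracellular pool (the community compartment) through
which all cross-feeding happens.  Exchange reactions carry the sign
convention: positive flux = secretion into the pool, negative flux =
consumption from the pool.  The pool itself talks to the outside world
through per-metabolite uptake (u >= 0, influx) and export (e >= 0, efflux)
reactions.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

#: default capacity for reactions without explicit bounds
#: (constraint-based-modeling convention), mmol g^-1 h^-1
DEFAULT_BOUND = 1000.0

NAMESPACE_SEP = "__"


class ModelError(ValueError):
    """Raised when a guild or community model violates its invariants."""


def namespaced(guild_id: str, raw_id: str) -> str:
    """Prefix ``raw_id`` with the guild namespace (idempotent)."""
    prefix = guild_id + NAMESPACE_SEP
    return raw_id if raw_id.startswith(prefix) else prefix + raw_id


def strip_namespace(identifier: str) -> str:
    """Remove a single guild prefix from an id, if present."""
    head, sep, tail = identifier.partition(NAMESPACE_SEP)
    return tail if sep else identifier


@dataclass
class Reaction:
    """A stoichiometric reaction with capacity bounds.

    ``stoich`` maps metabolite id -> coefficient (negative = consumed).
    Bounds are per-abundance capacities (mmol per g cell, O2 basis, per h):
    in the community problem the admissible aggregate flux of reaction j in
    guild k is ``lb * X_k <= V <= ub * X_k``.
    """

    id: str
    stoich: Dict[str, float]
    lb: float = -DEFAULT_BOUND
    ub: float = DEFAULT_BOUND
    name: str = ""

    def __post_init__(self) -> None:
        if self.lb > self.ub:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lb} exceeds upper bound {self.ub}"
            )

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoich), self.lb, self.ub, self.name)


@dataclass
class GuildModel:
    """One guild's stoichiometry, capacities and exchange wiring.

    ``exchange_reactions`` maps reaction id -> community-pool metabolite id.
    Every exchange reaction must touch exactly one (guild-internal)
    metabolite; its flux moves that metabolite to/from the pool.
    ``compositions`` optionally maps metabolite id -> elemental counts and is
    used for mass-balance validation and carbon bookkeeping.
    """

    guild_id: str
    reactions: List[Reaction]
    biomass_reaction: str
    exchange_reactions: Dict[str, str]
    gene_associations: Dict[str, List[str]] = field(default_factory=dict)
    compositions: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reactions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ModelError(f"guild {self.guild_id}: duplicate reaction ids {dupes}")
        if self.biomass_reaction not in set(ids):
            raise ModelError(
                f"guild {self.guild_id}: biomass reaction {self.biomass_reaction!r} "
                "not among reactions; pass an explicit biomass id"
            )
        for rid, pool_met in self.exchange_reactions.items():
            rxn = self.reaction(rid)
            if len(rxn.stoich) != 1:
                raise ModelError(
                    f"guild {self.guild_id}: exchange reaction {rid!r} must touch "
                    f"exactly one metabolite, got {sorted(rxn.stoich)}"
                )
            if not pool_met:
                raise ModelError(f"guild {self.guild_id}: exchange {rid!r} lacks a pool metabolite")

    # -- lookups ---------------------------------------------------------
    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"guild {self.guild_id}: no reaction {rid!r}")

    @property
    def metabolites(self) -> List[str]:
        seen: Dict[str, None] = {}
        for r in self.reactions:
            for m in r.stoich:
                seen.setdefault(m)
        return list(seen)

    @property
    def exchange_metabolites(self) -> List[str]:
        """Pool metabolite ids this guild can exchange."""
        seen: Dict[str, None] = {}
        for pool_met in self.exchange_reactions.values():
            seen.setdefault(pool_met)
        return list(seen)

    def exchange_for(self, pool_met: str) -> str:
        """Reaction id of this guild's exchange for ``pool_met``."""
        for rid, m in self.exchange_reactions.items():
            if m == pool_met:
                return rid
        raise KeyError(f"guild {self.guild_id}: no exchange for pool metabolite {pool_met!r}")

    def pool_coefficient(self, rid: str) -> float:
        """Pool-side stoichiometry of exchange ``rid`` per unit flux.

        With the canonical drain form ``{met: -1}`` this is +1: positive
        flux secretes one unit into the pool.
        """
        rxn = self.reaction(rid)
        (coeff,) = rxn.stoich.values()
        return -coeff

    def copy(self) -> "GuildModel":
        return GuildModel(
            guild_id=self.guild_id,
            reactions=[r.copy() for r in self.reactions],
            biomass_reaction=self.biomass_reaction,
            exchange_reactions=dict(self.exchange_reactions),
            gene_associations={k: list(v) for k, v in self.gene_associations.items()},
            compositions={k: dict(v) for k, v in self.compositions.items()},
        )


@dataclass
class CommunityModel:
    """Block-diagonal multi-guild model coupled through a shared pool.

    ``uptake_bounds`` / ``export_bounds`` give the maximal community influx /
    efflux per pool metabolite as specific rates (mmol per g of total
    community biomass per h); the solver multiplies them by ``x0``.
    """

    guilds: List[GuildModel]
    com_metabolites: List[str]
    uptake_bounds: Dict[str, float]
    export_bounds: Dict[str, float]
    x0: float = 1.0
    compositions: Dict[str, Dict[str, float]] = field(default_factory=dict)
    label: str = "community"

    def __post_init__(self) -> None:
        pool = set(self.com_metabolites)
        for g in self.guilds:
            for rid, met in g.exchange_reactions.items():
                if met not in pool:
                    raise ModelError(
                        f"guild {g.guild_id}: exchange {rid!r} targets {met!r}, "
                        "which is not a community-pool metabolite"
                    )
        for m in self.com_metabolites:
            if self.uptake_bounds.get(m, 0.0) < 0 or self.export_bounds.get(m, 0.0) < 0:
                raise ModelError(f"community bounds for {m!r} must be non-negative")

    # -- lookups ---------------------------------------------------------
    def guild(self, guild_id: str) -> GuildModel:
        for g in self.guilds:
            if g.guild_id == guild_id:
                return g
        raise KeyError(f"no guild {guild_id!r}")

    @property
    def guild_ids(self) -> List[str]:
        return [g.guild_id for g in self.guilds]

    def copy(self) -> "CommunityModel":
        return CommunityModel(
            guilds=[g.copy() for g in self.guilds],
            com_metabolites=list(self.com_metabolites),
            uptake_bounds=dict(self.uptake_bounds),
            export_bounds=dict(self.export_bounds),
            x0=self.x0,
            compositions={k: dict(v) for k, v in self.compositions.items()},
            label=self.label,
        )

    # -- capacity editing -------------------------------------------------
    def set_capacity(self, guild_id: str, pool_met: str, side: str, value: float) -> None:
        """Set one side of a guild's exchange-capacity interval.

        ``side`` is ``"lower"`` or ``"upper"``; values are per-abundance
        rates with positive = secretion.
        """
        guild = self.guild(guild_id)
        rxn = guild.reaction(guild.exchange_for(pool_met))
        if side == "lower":
            if value > rxn.ub:
                raise ModelError(
                    f"{guild_id}/{pool_met}: lower capacity {value} exceeds upper {rxn.ub}"
                )
            rxn.lb = value
        elif side == "upper":
            if value < rxn.lb:
                raise ModelError(
                    f"{guild_id}/{pool_met}: upper capacity {value} below lower {rxn.lb}"
                )
            rxn.ub = value
        else:
            raise ValueError(f"side must be 'lower' or 'upper', got {side!r}")

    def get_capacity(self, guild_id: str, pool_met: str, side: str) -> float:
        guild = self.guild(guild_id)
        rxn = guild.reaction(guild.exchange_for(pool_met))
        return rxn.lb if side == "lower" else rxn.ub


@dataclass
class ValidationReport:
    """Structural audit of an assembled community model."""

    reaction_count: int
    metabolite_count: int
    gene_count: int
    exchange_sets: Dict[str, List[str]]
    shared_exchange_counts: Dict[str, int]
    unbalanced_reactions: List[str]
    orphan_pool_metabolites: List[str]
    loop_candidates: List[List[str]]

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    def exchange_sets_tsv(self, path=None) -> str:
        lines = ["guild\tpool_metabolite"]
        for gid, mets in self.exchange_sets.items():
            for m in mets:
                lines.append(f"{gid}\t{m}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def assemble_community(
    guilds: Sequence[GuildModel],
    x0: float = 1.0,
    uptake_bounds: Optional[Mapping[str, float]] = None,
    export_bounds: Optional[Mapping[str, float]] = None,
    label: str = "community",
) -> CommunityModel:
    """Join guild models into a community with a shared metabolite pool.

    The pool is the union of the guilds' exchange metabolites; every pool
    metabolite gets an uptake and an export reaction (default capacity
    ``DEFAULT_BOUND`` each, i.e. open; apply a condition to impose a
    closed-world medium).  Raises on duplicate guild ids and on conflicting
    elemental compositions for the same pool metabolite.
    """
    if not guilds:
        raise ModelError("need at least one guild")
    ids = [g.guild_id for g in guilds]
    if len(set(ids)) != len(ids):
        raise ModelError(f"duplicate guild ids: {sorted({i for i in ids if ids.count(i) > 1})}")

    pool: Dict[str, None] = {}
    compositions: Dict[str, Dict[str, float]] = {}
    conflicts: List[str] = []
    for g in guilds:
        for rid, pool_met in g.exchange_reactions.items():
            pool.setdefault(pool_met)
            (internal_met,) = g.reaction(rid).stoich
            comp = g.compositions.get(internal_met)
            if comp is not None:
                prev = compositions.get(pool_met)
                if prev is not None and prev != comp:
                    conflicts.append(pool_met)
                compositions.setdefault(pool_met, dict(comp))
    if conflicts:
        raise ModelError(
            "conflicting elemental formulas for pool metabolites: "
            + ", ".join(sorted(set(conflicts)))
        )

    up = {m: DEFAULT_BOUND for m in pool}
    ex = {m: DEFAULT_BOUND for m in pool}
    if uptake_bounds is not None:
        up.update(uptake_bounds)
    if export_bounds is not None:
        ex.update(export_bounds)
    return CommunityModel(
        guilds=[g.copy() for g in guilds],
        com_metabolites=list(pool),
        uptake_bounds=up,
        export_bounds=ex,
        x0=x0,
        compositions=compositions,
        label=label,
    )


def _element_imbalance(rxn: Reaction, comps: Mapping[str, Mapping[str, float]]) -> bool:
    """True if the reaction visibly violates elemental balance.

    Only reactions whose every metabolite carries a composition are judged;
    metabolites with an empty composition count as element-free currency.
    """
    if any(m not in comps for m in rxn.stoich):
        return False
    totals: Dict[str, float] = {}
    for m, coeff in rxn.stoich.items():
        for el, n in comps[m].items():
            totals[el] = totals.get(el, 0.0) + coeff * n
    return any(abs(v) > 1e-9 for v in totals.values())


def _loop_candidates(guild: GuildModel) -> List[List[str]]:
    """Structural internal cycles: nullspace vectors of the internal S.

    Exchange and biomass columns are excluded, so any remaining nullspace
    direction is a flux mode invisible to the outside — a candidate
    thermodynamically infeasible loop.  Reported only; the solver applies a
    parsimonious objective rather than loop-law constraints.
    """
    internal = [
        r for r in guild.reactions
        if r.id not in guild.exchange_reactions and r.id != guild.biomass_reaction
    ]
    if not internal:
        return []
    mets = sorted({m for r in internal for m in r.stoich})
    midx = {m: i for i, m in enumerate(mets)}
    S = np.zeros((len(mets), len(internal)))
    for j, r in enumerate(internal):
        for m, c in r.stoich.items():
            S[midx[m], j] = c
    from scipy.linalg import null_space

    ns = null_space(S)
    loops: List[List[str]] = []
    for k in range(ns.shape[1]):
        support = [internal[j].id for j in range(len(internal)) if abs(ns[j, k]) > 1e-9]
        if len(support) > 1:
            loops.append(sorted(support))
    return loops


def validate_community(model: CommunityModel) -> ValidationReport:
    """Deterministic structural report; never raises on content."""
    n_rxn = sum(len(g.reactions) for g in model.guilds) + 2 * len(model.com_metabolites)
    n_met = sum(len(g.metabolites) for g in model.guilds) + len(model.com_metabolites)
    genes = {
        gene
        for g in model.guilds
        for gene_list in g.gene_associations.values()
        for gene in gene_list
    }

    exchange_sets = {g.guild_id: sorted(g.exchange_metabolites) for g in model.guilds}
    shared: Dict[str, int] = {g: len(s) for g, s in exchange_sets.items()}
    sets = {g: set(s) for g, s in exchange_sets.items()}
    for r in (2, 3):
        for combo in itertools.combinations(model.guild_ids, r):
            inter = set.intersection(*(sets[g] for g in combo))
            shared["&".join(sorted(combo))] = len(inter)
    if len(model.guild_ids) >= 2:
        union_pairs = set()
        for a, b in itertools.combinations(model.guild_ids, 2):
            union_pairs |= sets[a] & sets[b]
        shared["shared_by_2_or_more"] = len(union_pairs)
    if len(model.guild_ids) >= 3:
        shared["shared_by_all"] = len(set.intersection(*sets.values()))

    unbalanced = [
        r.id
        for g in model.guilds
        for r in g.reactions
        if r.id not in g.exchange_reactions
        and r.id != g.biomass_reaction
        and _element_imbalance(r, g.compositions)
    ]

    exchanged = {m for s in sets.values() for m in s}
    orphans = [m for m in model.com_metabolites if m not in exchanged]

    loops: List[List[str]] = []
    for g in model.guilds:
        loops.extend(_loop_candidates(g))

    return ValidationReport(
        reaction_count=n_rxn,
        metabolite_count=n_met,
        gene_count=len(genes),
        exchange_sets=exchange_sets,
        shared_exchange_counts=shared,
        unbalanced_reactions=sorted(unbalanced),
        orphan_pool_metabolites=orphans,
        loop_candidates=loops,
    )
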