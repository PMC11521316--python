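"""SBML input/output via COBRApy.

Guild models are read from standalone SBML files (level 3 + fbc preferred;
level 2 tolerated — COBRApy normalizes both).  A combined community SBML is
split into guilds by metabolite compartment: each guild occupies one
compartment and the shared pool occupies another (``com`` by convention,
configurable because published community models use varying tag dialects).
"""

from __future__ import annotations

import logging
import re
from typing import Dict, List, Mapping, Optional, Sequence

import cobra
from cobra.io import read_sbml_model, write_sbml_model

from .core import (
    DEFAULT_BOUND,
    CommunityModel,
    GuildModel,
    ModelError,
    Reaction,
    assemble_community,
    namespaced,
)

logger = logging.getLogger(__name__)

_BIOMASS_PATTERN = re.compile(r"biomass|growth", re.IGNORECASE)

POOL_COMPARTMENT = "com"


class SBMLError(ValueError):
    """Raised for malformed or unsupported SBML input."""


def _read(source) -> cobra.Model:
    try:
        return read_sbml_model(source if isinstance(source, str) else source)
    except Exception as exc:  # cobra raises a mix of IO/CobraSBML errors
        raise SBMLError(f"could not parse SBML from {source!r}: {exc}") from exc


def _base_met_id(met: cobra.Metabolite) -> str:
    """Metabolite id with its compartment tag stripped (pool identity)."""
    mid, comp = met.id, met.compartment or ""
    for suffix in (f"_{comp}", f"[{comp}]"):
        if comp and mid.endswith(suffix):
            return mid[: -len(suffix)]
    return mid


def _pick_biomass(model: cobra.Model, override: Optional[str]) -> str:
    if override is not None:
        if override not in model.reactions:
            raise ModelError(f"biomass reaction {override!r} not found in model")
        return override
    objective = [
        r.id for r in model.reactions if r.objective_coefficient not in (0, 0.0)
    ]
    if len(objective) == 1:
        return objective[0]
    named = [r.id for r in model.reactions if _BIOMASS_PATTERN.search(r.id)]
    if len(named) == 1:
        return named[0]
    raise ModelError(
        "no unambiguous biomass reaction (no single objective flux, "
        f"pattern matches: {named}); pass biomass_reaction explicitly"
    )


def load_guild_model(
    source,
    guild_id: str,
    biomass_reaction: Optional[str] = None,
) -> GuildModel:
    """Read one guild from SBML, namespacing all ids by ``guild_id``.

    Exchange reactions are recognized by the single-metabolite boundary
    pattern; the pool identity of the exchanged metabolite is its id with
    the compartment tag stripped.  Reactions without explicit bounds take
    COBRApy's defaults (+-1000) with a logged warning from the parser.
    """
    cm = _read(source)
    biomass = _pick_biomass(cm, biomass_reaction)

    reactions: List[Reaction] = []
    exchange: Dict[str, str] = {}
    genes: Dict[str, List[str]] = {}
    compositions: Dict[str, Dict[str, float]] = {}
    for met in cm.metabolites:
        if met.formula:
            compositions[namespaced(guild_id, met.id)] = dict(met.elements)
    for rxn in cm.reactions:
        rid = namespaced(guild_id, rxn.id)
        lb = rxn.lower_bound if rxn.lower_bound is not None else -DEFAULT_BOUND
        ub = rxn.upper_bound if rxn.upper_bound is not None else DEFAULT_BOUND
        stoich = {namespaced(guild_id, m.id): c for m, c in rxn.metabolites.items()}
        reactions.append(Reaction(rid, stoich, lb, ub, name=rxn.name or ""))
        if len(rxn.metabolites) == 1 and rxn.id != biomass:
            (met,) = rxn.metabolites
            exchange[rid] = _base_met_id(met)
        if rxn.genes:
            genes[rid] = sorted(g.id for g in rxn.genes)
    return GuildModel(
        guild_id=guild_id,
        reactions=reactions,
        biomass_reaction=namespaced(guild_id, biomass),
        exchange_reactions=exchange,
        gene_associations=genes,
        compositions=compositions,
    )


def community_to_cobra(model: CommunityModel) -> cobra.Model:
    """Flatten a community into one COBRApy model.

    Each guild becomes a compartment; the pool is the ``com`` compartment.
    Guild exchange reactions carry their pool metabolite explicitly, and the
    pool gets per-metabolite uptake (``UPT_*``) and export (``EXP_*``)
    boundary reactions.
    """
    model_id = re.sub(r"[^A-Za-z0-9_]", "_", model.label or "community")
    cm = cobra.Model(model_id)
    mets: Dict[str, cobra.Metabolite] = {}

    def met_for(mid: str, compartment: str, comp_src: Mapping) -> cobra.Metabolite:
        if mid not in mets:
            m = cobra.Metabolite(mid, compartment=compartment)
            comp = comp_src.get(mid)
            if comp:
                m.formula = "".join(f"{el}{int(n) if n == int(n) else n}" for el, n in sorted(comp.items()))
            mets[mid] = m
        return mets[mid]

    objective = []
    for g in model.guilds:
        for r in g.reactions:
            rxn = cobra.Reaction(r.id, lower_bound=r.lb, upper_bound=r.ub)
            cm.add_reactions([rxn])
            stoich = {met_for(m, g.guild_id, g.compositions): c for m, c in r.stoich.items()}
            if r.id in g.exchange_reactions:
                pool_met = g.exchange_reactions[r.id]
                stoich[met_for(pool_met, POOL_COMPARTMENT, model.compositions)] = (
                    g.pool_coefficient(r.id)
                )
            rxn.add_metabolites(stoich)
            if r.id == g.biomass_reaction:
                objective.append(rxn)
    for m in model.com_metabolites:
        pool = met_for(m, POOL_COMPARTMENT, model.compositions)
        upt = cobra.Reaction(f"UPT_{m}", lower_bound=0.0,
                             upper_bound=model.uptake_bounds.get(m, 0.0))
        exp = cobra.Reaction(f"EXP_{m}", lower_bound=0.0,
                             upper_bound=model.export_bounds.get(m, 0.0))
        cm.add_reactions([upt, exp])
        upt.add_metabolites({pool: 1.0})
        exp.add_metabolites({pool: -1.0})
    cm.objective = {r: 1.0 for r in objective}
    return cm


def write_community_sbml(model: CommunityModel, path: str) -> None:
    write_sbml_model(community_to_cobra(model), path)


def read_community_sbml(
    source,
    guild_compartments: Optional[Mapping[str, str]] = None,
    pool_compartment: Optional[str] = None,
    biomass_reactions: Optional[Mapping[str, str]] = None,
    x0: float = 1.0,
) -> CommunityModel:
    """Split a combined community SBML into guilds by compartment.

    ``guild_compartments`` maps SBML compartment id -> guild label; if
    omitted, every compartment except the pool becomes a guild named after
    itself.  ``pool_compartment`` defaults to ``com`` (``u`` and ``e`` are
    also recognized); published community models use undocumented tag
    dialects, so both mappings are caller-overridable.
    """
    cm = _read(source)
    comp_of = {m.id: m.compartment or "" for m in cm.metabolites}
    compartments = {c for c in comp_of.values()}
    if pool_compartment is None:
        candidates = [c for c in ("com", "COM", "u", "e") if c in compartments]
        if not candidates:
            raise ModelError(
                f"cannot identify the pool compartment among {sorted(compartments)}; "
                "pass pool_compartment explicitly"
            )
        pool_compartment = candidates[0]
    if guild_compartments is None:
        guild_compartments = {c: c for c in sorted(compartments) if c != pool_compartment}

    guild_rxns: Dict[str, List[Reaction]] = {g: [] for g in guild_compartments.values()}
    guild_exchange: Dict[str, Dict[str, str]] = {g: {} for g in guild_compartments.values()}
    guild_comps: Dict[str, Dict[str, Dict[str, float]]] = {g: {} for g in guild_compartments.values()}
    guild_genes: Dict[str, Dict[str, List[str]]] = {g: {} for g in guild_compartments.values()}
    uptake_bounds: Dict[str, float] = {}
    export_bounds: Dict[str, float] = {}
    pool_mets: Dict[str, None] = {}
    pool_comp_table: Dict[str, Dict[str, float]] = {}

    for rxn in cm.reactions:
        comps = {comp_of[m.id] for m in rxn.metabolites}
        pool_in = pool_compartment in comps
        guild_tags = sorted(c for c in comps if c != pool_compartment)
        if len(guild_tags) > 1:
            raise ModelError(
                f"reaction {rxn.id!r} spans guild compartments {guild_tags}; "
                "not a valid compartmentalized community model"
            )
        if not guild_tags:
            # pool-only boundary reaction
            if len(rxn.metabolites) != 1:
                raise ModelError(f"pool reaction {rxn.id!r} touches multiple metabolites")
            ((met, coeff),) = rxn.metabolites.items()
            base = _base_met_id(met)
            pool_mets.setdefault(base)
            if met.formula:
                pool_comp_table[base] = dict(met.elements)
            if coeff > 0:
                uptake_bounds[base] = max(uptake_bounds.get(base, 0.0), rxn.upper_bound)
            else:
                export_bounds[base] = max(export_bounds.get(base, 0.0), rxn.upper_bound)
            continue
        tag = guild_tags[0]
        if tag not in guild_compartments:
            raise ModelError(f"reaction {rxn.id!r} lives in unmapped compartment {tag!r}")
        gid = guild_compartments[tag]
        stoich: Dict[str, float] = {}
        pool_met = None
        for met, coeff in rxn.metabolites.items():
            if comp_of[met.id] == pool_compartment:
                pool_met = _base_met_id(met)
                pool_mets.setdefault(pool_met)
                if met.formula:
                    pool_comp_table[pool_met] = dict(met.elements)
            else:
                mid = namespaced(gid, met.id)
                stoich[mid] = coeff
                if met.formula:
                    guild_comps[gid][mid] = dict(met.elements)
        rid = namespaced(gid, rxn.id)
        guild_rxns[gid].append(Reaction(rid, stoich, rxn.lower_bound, rxn.upper_bound,
                                        name=rxn.name or ""))
        if pool_in and pool_met is not None:
            if len(stoich) != 1:
                raise ModelError(
                    f"exchange reaction {rxn.id!r} must couple one guild metabolite "
                    f"to the pool, got {sorted(stoich)}"
                )
            guild_exchange[gid][rid] = pool_met
        if rxn.genes:
            guild_genes[gid][rid] = sorted(g.id for g in rxn.genes)

    guilds = []
    for gid in guild_rxns:
        override = biomass_reactions.get(gid) if biomass_reactions else None
        if override is not None:
            biomass = namespaced(gid, override)
        else:
            candidates = [
                r.id for r in guild_rxns[gid] if _BIOMASS_PATTERN.search(r.id)
            ]
            if len(candidates) != 1:
                raise ModelError(
                    f"guild {gid}: cannot identify biomass among {candidates}; "
                    "pass biomass_reactions={guild: reaction_id}"
                )
            biomass = candidates[0]
        guilds.append(
            GuildModel(
                guild_id=gid,
                reactions=guild_rxns[gid],
                biomass_reaction=biomass,
                exchange_reactions=guild_exchange[gid],
                gene_associations=guild_genes[gid],
                compositions=guild_comps[gid],
            )
        )
    model = assemble_community(
        guilds, x0=x0, uptake_bounds=uptake_bounds, export_bounds=export_bounds,
        label=cm.id or "community",
    )
    # keep any pool metabolites that had boundary reactions but no guild exchange
    for m in pool_mets:
        if m not in model.com_metabolites:
            model.com_metabolites.append(m)
            model.uptake_bounds.setdefault(m, uptake_bounds.get(m, 0.0))
            model.export_bounds.setdefault(m, export_bounds.get(m, 0.0))
    model.compositions.update(pool_comp_table)
    return model


def guild_to_cobra(
    guild: GuildModel,
    uptake_bounds: Optional[Mapping[str, float]] = None,
    export_bounds: Optional[Mapping[str, float]] = None,
) -> cobra.Model:
    """Standalone FBA model of one guild (exchanges as boundary drains).

    When community bounds are given, each exchange reaction's interval is
    intersected with [-uptake, +export] of its pool metabolite — the
    single-guild equivalent of the pool balance at unit abundance.
    """
    cm = cobra.Model(guild.guild_id)
    mets = {m: cobra.Metabolite(m, compartment="c") for m in guild.metabolites}
    for r in guild.reactions:
        lb, ub = r.lb, r.ub
        if r.id in guild.exchange_reactions:
            pool_met = guild.exchange_reactions[r.id]
            if uptake_bounds is not None:
                lb = max(lb, -uptake_bounds.get(pool_met, 0.0))
            if export_bounds is not None:
                ub = min(ub, export_bounds.get(pool_met, 0.0))
            if lb > ub:  # closed both ways
                lb = ub = 0.0
        rxn = cobra.Reaction(r.id, lower_bound=lb, upper_bound=ub)
        cm.add_reactions([rxn])
        rxn.add_metabolites({mets[m]: c for m, c in r.stoich.items()})
    cm.objective = guild.biomass_reaction
    return cm
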