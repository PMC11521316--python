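"""Fully specified three-guild toy community for end-to-end testing.

The toy reproduces the assumed metabolic structure of a microbial-fuel-cell
community treating sulfide-rich, VFA-dominated wastewater:

* **SRB** (sulfate reducers) oxidize butyrate to two acetates (lumped
  acyl-CoA / 3-hydroxyacyl-CoA dehydrogenase step) yielding NADH and a
  little substrate-level ATP; NADH drives dissimilatory sulfate reduction
  (lumped Apr/Dsr + electron-transport ATPase) producing sulfide, or
  overflows to H2 and formate when sulfate is short.
* **MET** (acetoclastic methanogens) split acetate into CH4 + CO2 with a
  modest chemiosmotic ATP yield (lumped Hdr/Fpo/Mtr).
* **SOB** (sulfide oxidizers) gain photon-driven ATP from sulfide oxidation
  (full, to sulfate — regenerating SRB's electron acceptor — or partial, to
  elemental sulfur), assimilate acetate (lumped Pfor/Pepc) and fix CO2
  (lumped reductive TCA) into a single carbon precursor for biomass.

Exchange capacities default to the fitted values of the full-scale study
(acetate uptake caps for SOB and MET, sulfide secretion cap for SRB, tiny
proton caps for SRB/MET), so the toy exhibits the same qualitative
community dynamics: sulfide-oxidizer dominance at low organic loading,
methanogen dominance at high loading, and a sulfide-limited plateau of
sulfide-oxidizer growth once the sulfate reducers' secretion capacity
saturates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional

import numpy as np

from .conditions import ConditionSpec, apply_condition
from .core import (
    DEFAULT_BOUND,
    CommunityModel,
    GuildModel,
    ModelError,
    Reaction,
    assemble_community,
    namespaced,
)
from .steadycom import SolverSettings, maximize_growth

SRB, MET, SOB = "SRB", "MET", "SOB"

#: elemental compositions of the shared metabolites (carbon and sulfur are
#: tracked; energy/currency species are element-free tokens)
COMPOSITIONS: Dict[str, Dict[str, float]] = {
    "but": {"C": 4}, "ac": {"C": 2}, "co2": {"C": 1}, "ch4": {"C": 1},
    "formate": {"C": 1}, "cx": {"C": 1},
    "so4": {"S": 1}, "h2s": {"S": 1}, "s0": {"S": 1},
    "h2": {}, "h": {}, "nh4": {}, "photon": {}, "h2o": {}, "pi": {},
    "atp": {}, "nadh": {},
}


@dataclass
class ToyCommunitySpec:
    """Parameter preset for the toy community.

    Exchange capacities are per-abundance rates (mmol g^-1 h^-1, positive =
    secretion); the loading preset gives the low-loading community influx
    bounds, with the high-loading condition obtained by the butyrate x1.56 /
    acetate x1.30 seasonal fold changes.
    """

    # fitted exchange capacities
    vex_acetate_sob_lb: float = -1.50    # max acetate consumption of SOB
    vex_acetate_met_ub: float = -11.55   # min acetate consumption of MET
    vex_sulfide_srb_ub: float = 6.28     # max sulfide release of SRB
    vex_h_srb: float = 1e-5              # proton capacity of SRB (both sides)
    vex_h_met: float = 1e-5              # proton capacity of MET (both sides)

    # lumped-pathway energy yields (mol ATP per mol substrate)
    atp_per_butyrate: float = 0.3
    atp_per_sulfate: float = 2.0
    atp_per_acetate_met: float = 0.5
    atp_per_sulfide_full: float = 3.5
    atp_per_sulfide_partial: float = 1.0
    atp_per_h_sob: float = 0.6
    atp_per_h_other: float = 0.25
    cfix_atp: float = 4.0                # ATP per CO2 fixed (reductive TCA, lumped)
    acas_atp: float = 1.0                # ATP per acetate assimilated

    # biomass ATP costs and non-growth maintenance (per-abundance)
    biomass_atp: Dict[str, float] = field(
        default_factory=lambda: {SRB: 40.0, MET: 3.5, SOB: 9.0}
    )
    maintenance_atp: Dict[str, float] = field(
        default_factory=lambda: {SRB: 1.0, MET: 1.0, SOB: 2.0}
    )

    # low-loading community influx bounds, mmol gDW^-1 h^-1
    butyrate: float = 1.51
    acetate: float = 1.17
    sulfate: float = 0.10
    sulfide: float = 0.05
    h_uptake: float = 4.21e-4
    # seasonal fold changes low -> high loading
    butyrate_fold: float = 1.56
    acetate_fold: float = 1.30

    x0: float = 1.0
    seed: int = 0
    noise_sd: float = 0.05


def _guild(gid: str, reactions, biomass, exchanges) -> GuildModel:
    """Namespace raw reaction definitions into a GuildModel."""
    rxns = []
    for rid, stoich, lb, ub in reactions:
        rxns.append(
            Reaction(
                namespaced(gid, rid),
                {namespaced(gid, m): c for m, c in stoich.items()},
                lb,
                ub,
            )
        )
    comps = {}
    for r in rxns:
        for m in r.stoich:
            base = m.split("__", 1)[1]
            if base in COMPOSITIONS:
                comps[m] = dict(COMPOSITIONS[base])
    return GuildModel(
        guild_id=gid,
        reactions=rxns,
        biomass_reaction=namespaced(gid, biomass),
        exchange_reactions={namespaced(gid, rid): met for rid, met in exchanges.items()},
        compositions=comps,
    )


def _srb(p: ToyCommunitySpec) -> GuildModel:
    B = DEFAULT_BOUND
    # the 0.01 sulfide term is assimilatory sulfur: biomass synthesis
    # requires reduced S, so growth strictly depends on sulfate respiration
    bm = {"ac": -1.0, "atp": -p.biomass_atp[SRB], "nh4": -0.2, "pi": -0.05,
          "h2s": -0.01}
    reactions = [
        ("EX_but", {"but": -1}, -B, 0.0),
        ("EX_ac", {"ac": -1}, 0.0, B),
        ("EX_so4", {"so4": -1}, -B, 0.0),
        ("EX_h2s", {"h2s": -1}, 0.0, p.vex_sulfide_srb_ub),
        ("EX_co2", {"co2": -1}, -B, B),
        ("EX_h2", {"h2": -1}, 0.0, B),
        ("EX_formate", {"formate": -1}, 0.0, B),
        ("EX_nh4", {"nh4": -1}, -B, 0.0),
        ("EX_pi", {"pi": -1}, -B, 0.0),
        ("EX_h2o", {"h2o": -1}, -B, B),
        ("EX_h", {"h": -1}, -p.vex_h_srb, p.vex_h_srb),
        # butyrate -> 2 acetate (Acoad1/Hacd1 lumped with acetate kinase)
        ("BUOX", {"but": -1, "h2o": -1, "ac": 2, "nadh": 2, "atp": p.atp_per_butyrate}, 0.0, B),
        # dissimilatory sulfate reduction (Apr/Dsr + ET-phosphorylation lumped)
        ("SRED", {"so4": -1, "nadh": -4, "h2s": 1, "atp": p.atp_per_sulfate}, 0.0, B),
        ("H2_OVERFLOW", {"nadh": -1, "h2": 1}, 0.0, B),
        ("FORMATE_OVERFLOW", {"nadh": -1, "co2": -1, "formate": 1}, 0.0, B),
        ("H_ATPASE", {"h": -1, "atp": p.atp_per_h_other}, 0.0, B),
        ("ATPM", {"atp": -1}, p.maintenance_atp[SRB], B),
        ("BIOMASS", bm, 0.0, B),
    ]
    exchanges = {
        "EX_but": "but", "EX_ac": "ac", "EX_so4": "so4", "EX_h2s": "h2s",
        "EX_co2": "co2", "EX_h2": "h2", "EX_formate": "formate",
        "EX_nh4": "nh4", "EX_pi": "pi", "EX_h2o": "h2o", "EX_h": "h",
    }
    return _guild(SRB, reactions, "BIOMASS", exchanges)


def _met(p: ToyCommunitySpec) -> GuildModel:
    B = DEFAULT_BOUND
    bm = {"ac": -1.0, "atp": -p.biomass_atp[MET], "nh4": -0.2, "pi": -0.05}
    reactions = [
        ("EX_ac", {"ac": -1}, -B, p.vex_acetate_met_ub),
        ("EX_ch4", {"ch4": -1}, 0.0, B),
        ("EX_co2", {"co2": -1}, 0.0, B),
        ("EX_nh4", {"nh4": -1}, -B, 0.0),
        ("EX_pi", {"pi": -1}, -B, 0.0),
        ("EX_h2o", {"h2o": -1}, -B, B),
        ("EX_h", {"h": -1}, -p.vex_h_met, p.vex_h_met),
        # acetoclastic methanogenesis (Hdr/Fpo/Mtr chemiosmosis lumped)
        ("ACM", {"ac": -1, "ch4": 1, "co2": 1, "atp": p.atp_per_acetate_met}, 0.0, B),
        ("H_ATPASE", {"h": -1, "atp": p.atp_per_h_other}, 0.0, B),
        ("ATPM", {"atp": -1}, p.maintenance_atp[MET], B),
        ("BIOMASS", bm, 0.0, B),
    ]
    exchanges = {
        "EX_ac": "ac", "EX_ch4": "ch4", "EX_co2": "co2",
        "EX_nh4": "nh4", "EX_pi": "pi", "EX_h2o": "h2o", "EX_h": "h",
    }
    return _guild(MET, reactions, "BIOMASS", exchanges)


def _sob(p: ToyCommunitySpec) -> GuildModel:
    B = DEFAULT_BOUND
    bm = {"cx": -2.0, "atp": -p.biomass_atp[SOB], "nh4": -0.2, "pi": -0.05}
    reactions = [
        ("EX_ac", {"ac": -1}, p.vex_acetate_sob_lb, 0.0),
        ("EX_h2s", {"h2s": -1}, -B, 0.0),
        ("EX_so4", {"so4": -1}, 0.0, B),
        ("EX_s0", {"s0": -1}, 0.0, B),
        ("EX_co2", {"co2": -1}, -B, 0.0),
        ("EX_photon", {"photon": -1}, -B, 0.0),
        ("EX_nh4", {"nh4": -1}, -B, 0.0),
        ("EX_pi", {"pi": -1}, -B, 0.0),
        ("EX_h2o", {"h2o": -1}, -B, B),
        ("EX_h", {"h": -1}, -B, 0.0),
        # photon-assisted full sulfide oxidation back to sulfate
        ("SOX_FULL", {"h2s": -1, "photon": -4, "so4": 1, "h2o": 1,
                      "atp": p.atp_per_sulfide_full}, 0.0, B),
        # partial oxidation to elemental sulfur
        ("SOX_PARTIAL", {"h2s": -1, "photon": -1, "s0": 1,
                         "atp": p.atp_per_sulfide_partial}, 0.0, B),
        ("H_ATPASE", {"h": -1, "photon": -1, "atp": p.atp_per_h_sob}, 0.0, B),
        # acetate assimilation (Pfor/Pepc lumped) into the carbon precursor
        ("ACAS", {"ac": -1, "atp": -p.acas_atp, "cx": 2}, 0.0, B),
        # CO2 fixation via the reductive TCA route (lumped)
        ("CFIX", {"co2": -1, "atp": -p.cfix_atp, "cx": 1}, 0.0, B),
        ("ATPM", {"atp": -1}, p.maintenance_atp[SOB], B),
        ("BIOMASS", bm, 0.0, B),
    ]
    exchanges = {
        "EX_ac": "ac", "EX_h2s": "h2s", "EX_so4": "so4", "EX_s0": "s0",
        "EX_co2": "co2", "EX_photon": "photon", "EX_nh4": "nh4",
        "EX_pi": "pi", "EX_h2o": "h2o", "EX_h": "h",
    }
    return _guild(SOB, reactions, "BIOMASS", exchanges)


def make_toy_community(spec: Optional[ToyCommunitySpec] = None) -> CommunityModel:
    """Assemble the three-guild toy; raises if the default loading is infeasible."""
    spec = spec or ToyCommunitySpec()
    model = assemble_community(
        [_srb(spec), _met(spec), _sob(spec)], x0=spec.x0, label="toy-community"
    )
    conditioned = apply_condition(model, low_loading_condition(spec))
    probe = maximize_growth(conditioned, SolverSettings(mu_tolerance=1e-4))
    if probe.status != "optimal" or probe.mu <= 0:
        raise ModelError(
            "toy community infeasible at its default loading; "
            f"solver status {probe.status!r} at mu={probe.mu}"
        )
    return model


def low_loading_condition(spec: Optional[ToyCommunitySpec] = None) -> ConditionSpec:
    """Community bounds for the low-organic-loading season."""
    p = spec or ToyCommunitySpec()
    rates = {
        "but": p.butyrate,
        "ac": p.acetate,
        "so4": p.sulfate,
        "h2s": p.sulfide,
        "h": p.h_uptake,
        "ch4": -DEFAULT_BOUND,
        "co2": -DEFAULT_BOUND,
        "h2": -DEFAULT_BOUND,
        "formate": -DEFAULT_BOUND,
        "s0": -DEFAULT_BOUND,
    }
    return ConditionSpec("L-OLR", rates, ["photon", "h2o", "pi", "nh4"])


def high_loading_condition(spec: Optional[ToyCommunitySpec] = None) -> ConditionSpec:
    """High-loading season: butyrate x1.56, acetate x1.30 over low loading."""
    p = spec or ToyCommunitySpec()
    return low_loading_condition(p).scaled(
        {"but": p.butyrate_fold, "ac": p.acetate_fold}, label="H-OLR"
    )


def loading_condition(
    spec: ToyCommunitySpec, butyrate: float, acetate: float, label: str = "loading"
) -> ConditionSpec:
    """Condition with explicit butyrate/acetate community uptake bounds."""
    base = low_loading_condition(spec)
    base.community_rates["but"] = butyrate
    base.community_rates["ac"] = acetate
    base.label = label
    return base


def make_synthetic_observation(
    model: CommunityModel,
    condition: ConditionSpec,
    capacities=None,
    noise_sd: float = 0.05,
    seed: int = 0,
    settings: Optional[SolverSettings] = None,
) -> Dict[str, float]:
    """Ground-truth abundances with multiplicative log-normal noise.

    Solves the community at ``condition`` (optionally with a capacity
    parameter set applied), perturbs each abundance by a log-normal factor
    with the given relative spread, and renormalizes to the model's X0.
    ``seed`` fully determines the output.
    """
    work = model.copy()
    if capacities is not None:
        capacities.apply(work)
    conditioned = apply_condition(work, condition)
    sol = maximize_growth(conditioned, settings or SolverSettings(mu_tolerance=1e-6))
    if sol.status != "optimal":
        raise ModelError(f"infeasible capacities/condition: solver status {sol.status!r}")
    rng = np.random.default_rng(seed)
    gids = list(sol.abundances)
    values = np.array([sol.abundances[g] for g in gids])
    if noise_sd > 0:
        values = values * rng.lognormal(mean=0.0, sigma=noise_sd, size=len(values))
    values *= model.x0 / values.sum()
    return {g: float(v) for g, v in zip(gids, values)}
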