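"""Condition-specific community bounds from wastewater chemistry.

A condition converts reactor loads — total organics as chemical oxygen
demand (COD), its volatile-fatty-acid (VFA) share, sulfate and sulfide — into
specific community influx/efflux bounds (mmol per g of community cell mass,
O2 basis, per hour).  Community cell mass is estimated from the substrate
load through a constant cell yield Y = 0.15 g cell-O2 per g substrate-O2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional

from .core import DEFAULT_BOUND, CommunityModel, ModelError

#: g O2 demanded per mmol on complete oxidation (butyrate: 5 O2, acetate: 2 O2)
VFA_O2_EQUIV_MG_PER_MMOL = {"but": 160.0, "ac": 64.0}

#: mg per mmol
MOLAR_MASS_MG_PER_MMOL = {"so4": 96.06, "h2s": 34.08}

#: measured VFA share of total COD
DEFAULT_VFA_FRACTION = 0.6312

#: cell yield, g cell-O2 per g substrate-O2
DEFAULT_CELL_YIELD = 0.15

#: butyrate:acetate molar split implied by the low-loading C4/C2 uptake
#: ratio of 1.29 (the measured split itself is not published)
DEFAULT_VFA_MOLAR_SPLIT = {"but": 1.29 / 2.29, "ac": 1.0 / 2.29}

#: metabolites a community is always allowed to exchange freely
DEFAULT_FREE_EXCHANGE = ["photon", "h2o", "pi", "nh4"]

#: fermentation/respiration products allowed to leave the community
DEFAULT_EFFLUX_PRODUCTS = ["ch4", "co2", "h2", "formate", "s0"]


@dataclass
class ConditionSpec:
    """Named community boundary condition.

    ``community_rates`` maps pool metabolite -> signed specific rate:
    positive values bound the community uptake u_i, negative values bound
    the community export e_i (by magnitude).  ``free_exchange`` metabolites
    are unbounded in both directions.
    """

    label: str
    community_rates: Dict[str, float]
    free_exchange: List[str] = field(default_factory=list)
    cell_mass: float = 1.0
    cell_yield: float = DEFAULT_CELL_YIELD
    zero_condition: bool = False

    def __post_init__(self) -> None:
        if not self.zero_condition and self.cell_mass <= 0:
            raise ModelError(f"condition {self.label!r}: cell_mass must be > 0")
        if not 0 < self.cell_yield < 1:
            raise ModelError(f"condition {self.label!r}: cell_yield must be in (0, 1)")

    def copy(self) -> "ConditionSpec":
        return ConditionSpec(
            self.label,
            dict(self.community_rates),
            list(self.free_exchange),
            self.cell_mass,
            self.cell_yield,
            self.zero_condition,
        )

    def scaled(self, factors: Mapping[str, float], label: Optional[str] = None) -> "ConditionSpec":
        """New condition with selected rates multiplied by per-metabolite factors."""
        spec = self.copy()
        for met, f in factors.items():
            if met in spec.community_rates:
                spec.community_rates[met] *= f
        spec.label = label or self.label
        return spec

    def with_rate(self, met: str, rate: float, label: Optional[str] = None) -> "ConditionSpec":
        spec = self.copy()
        spec.community_rates[met] = rate
        spec.label = label or self.label
        return spec

    # -- serialization ---------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "label": self.label,
                "community_rates": self.community_rates,
                "free_exchange": self.free_exchange,
                "cell_mass": self.cell_mass,
                "cell_yield": self.cell_yield,
                "zero_condition": self.zero_condition,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source) -> "ConditionSpec":
        if hasattr(source, "read"):
            data = json.load(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        return cls(**data)

    def to_tsv(self, path=None) -> str:
        lines = ["metabolite\tdirection\tbound\tunits"]
        for met, rate in sorted(self.community_rates.items()):
            direction = "influx" if rate >= 0 else "efflux"
            lines.append(f"{met}\t{direction}\t{abs(rate):.10g}\tmmol.gDW-1.h-1")
        for met in self.free_exchange:
            lines.append(f"{met}\tfree\t\tmmol.gDW-1.h-1")
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def cod_to_substrate_rates(
    cod_load: float,
    sulfate_load: float = 0.0,
    sulfide_load: float = 0.0,
    vfa_fraction: float = DEFAULT_VFA_FRACTION,
    vfa_molar_split: Optional[Mapping[str, float]] = None,
    cell_yield: float = DEFAULT_CELL_YIELD,
    label: str = "condition",
    extra_rates: Optional[Mapping[str, float]] = None,
    free_exchange: Optional[List[str]] = None,
    efflux_products: Optional[List[str]] = None,
) -> ConditionSpec:
    """Specific substrate rates from reactor loads.

    ``cod_load`` in mg O2 h^-1; ``sulfate_load`` / ``sulfide_load`` in
    mg h^-1.  The VFA pool (``vfa_fraction`` of COD) is split between
    butyrate and acetate by mole fractions; each VFA's COD share follows
    from its complete-oxidation O2 equivalent.  Cell mass (g O2 basis) is
    ``cell_yield * cod_load``, and every specific rate is load / cell mass.
    """
    if cod_load < 0 or sulfate_load < 0 or sulfide_load < 0:
        raise ModelError("loads must be >= 0")
    if not 0 < vfa_fraction <= 1:
        raise ModelError(f"vfa_fraction must be in (0, 1], got {vfa_fraction}")
    split = dict(vfa_molar_split) if vfa_molar_split is not None else dict(DEFAULT_VFA_MOLAR_SPLIT)
    unknown = sorted(set(split) - set(VFA_O2_EQUIV_MG_PER_MMOL))
    if unknown:
        raise ModelError(f"unknown VFA ids in molar split: {unknown}")
    if abs(sum(split.values()) - 1.0) > 1e-9:
        raise ModelError("vfa_molar_split mole fractions must sum to 1")

    free = list(free_exchange) if free_exchange is not None else list(DEFAULT_FREE_EXCHANGE)
    products = (
        list(efflux_products) if efflux_products is not None else list(DEFAULT_EFFLUX_PRODUCTS)
    )
    rates: Dict[str, float] = {m: -DEFAULT_BOUND for m in products}

    if cod_load == 0:
        for vfa in split:
            rates[vfa] = 0.0
        rates.update({"so4": 0.0, "h2s": 0.0})
        if extra_rates:
            rates.update(extra_rates)
        return ConditionSpec(label, rates, free, cell_mass=0.0, cell_yield=cell_yield,
                             zero_condition=True)

    cell_mass = cell_yield * cod_load / 1000.0  # g cell-O2 (per hour-of-load basis)
    vfa_cod = vfa_fraction * cod_load
    cod_per_mmol = sum(x * VFA_O2_EQUIV_MG_PER_MMOL[v] for v, x in split.items())
    total_vfa_mmol = vfa_cod / cod_per_mmol
    for vfa, x in split.items():
        rates[vfa] = x * total_vfa_mmol / cell_mass
    rates["so4"] = sulfate_load / MOLAR_MASS_MG_PER_MMOL["so4"] / cell_mass
    rates["h2s"] = sulfide_load / MOLAR_MASS_MG_PER_MMOL["h2s"] / cell_mass
    if extra_rates:
        rates.update(extra_rates)
    return ConditionSpec(label, rates, free, cell_mass=cell_mass, cell_yield=cell_yield)


def apply_condition(model: CommunityModel, spec: ConditionSpec) -> CommunityModel:
    """Closed-world application of a condition to a community model.

    Community uptake/export bounds are set from the spec; free-exchange
    metabolites are opened in both directions; every other pool metabolite
    is closed to the outside (guild-to-guild exchange only).
    """
    pool = set(model.com_metabolites)
    unresolved = sorted((set(spec.community_rates) | set(spec.free_exchange)) - pool)
    if unresolved:
        raise ModelError(
            f"condition {spec.label!r} references metabolites absent from the "
            f"community pool: {unresolved}"
        )
    out = model.copy()
    out.uptake_bounds = {m: 0.0 for m in model.com_metabolites}
    out.export_bounds = {m: 0.0 for m in model.com_metabolites}
    for met, rate in spec.community_rates.items():
        if rate >= 0:
            out.uptake_bounds[met] = rate
        else:
            out.export_bounds[met] = -rate
    for met in spec.free_exchange:
        out.uptake_bounds[met] = DEFAULT_BOUND
        out.export_bounds[met] = DEFAULT_BOUND
    out.label = f"{model.label}@{spec.label}"
    return out
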