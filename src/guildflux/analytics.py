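"""Flux comparison metrics between two community solutions.

Flux fold change (FFC) contrasts a reaction or exchange flux between the
high- and low-loading optima as log2(V_H / V_L); magnitudes below the
zero-flux threshold (1e-6 mmol g^-1 h^-1) count as zero and produce a flag
instead of a number, as do pairs whose flux reverses direction.  Sweep
series are compared on a min-max-normalized absolute scale with the
original flux signs reinstated afterwards.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core import ModelError
from .steadycom import SteadyComSolution

ZERO_FLUX_THRESHOLD = 1e-6

#: |FFC| category cut points: low < 0.64 <= medium < 2 <= high
#: (anchored at the butyrate-uptake fold change between seasons)
FFC_CATEGORY_CUTS = (0.64, 2.0)


@dataclass
class FFCRecord:
    id: str
    guild: str
    v_l: float
    v_h: float
    ffc: Optional[float]
    flag: str  # ok | zeroed_L | zeroed_H | both_zero | sign_discordant

    @property
    def category(self) -> Optional[str]:
        if self.ffc is None:
            return None
        a = abs(self.ffc)
        if a < FFC_CATEGORY_CUTS[0]:
            return "low"
        if a < FFC_CATEGORY_CUTS[1]:
            return "medium"
        return "high"


@dataclass
class FluxComparison:
    records: List[FFCRecord]
    zero_threshold: float = ZERO_FLUX_THRESHOLD

    def record(self, guild: str, rxn_or_met: str) -> FFCRecord:
        for r in self.records:
            if r.guild == guild and r.id == rxn_or_met:
                return r
        raise KeyError(f"no record for {guild}/{rxn_or_met}")

    def to_tsv(self, path=None) -> str:
        lines = ["id\tguild\tV_L\tV_H\tFFC\tflag\tcategory"]
        for r in self.records:
            ffc = f"{r.ffc:.4f}" if r.ffc is not None else ""
            lines.append(
                f"{r.id}\t{r.guild}\t{r.v_l:.6g}\t{r.v_h:.6g}\t{ffc}\t{r.flag}\t{r.category or ''}"
            )
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class NormalizedSeries:
    """Signed min-max-normalized flux series in [-1, 1]."""

    values: List[float]
    source_ids: List = field(default_factory=list)
    metabolite: str = ""
    guild: str = ""
    constant: bool = False


def flux_fold_change(
    v_h: float, v_l: float, zero_threshold: float = ZERO_FLUX_THRESHOLD
) -> Tuple[Optional[float], str]:
    """log2(V_H / V_L) for same-sign nonzero pairs, else a flag.

    Returns ``(value, "ok")`` or ``(None, flag)`` with flag in
    {zeroed_L, zeroed_H, both_zero, sign_discordant}.
    """
    if not (math.isfinite(v_h) and math.isfinite(v_l)):
        raise ModelError("flux fold change requires finite inputs")
    zl = abs(v_l) < zero_threshold
    zh = abs(v_h) < zero_threshold
    if zl and zh:
        return None, "both_zero"
    if zl:
        return None, "zeroed_L"
    if zh:
        return None, "zeroed_H"
    if (v_h > 0) != (v_l > 0):
        return None, "sign_discordant"
    return math.log2(v_h / v_l), "ok"


def compare_solutions(
    sol_l: SteadyComSolution,
    sol_h: SteadyComSolution,
    zero_threshold: float = ZERO_FLUX_THRESHOLD,
    include_exchanges: bool = True,
    include_reactions: bool = True,
) -> FluxComparison:
    """FFC table over all shared reactions and exchange fluxes."""
    records: List[FFCRecord] = []

    def add(gid: str, rid: str, vl: float, vh: float) -> None:
        ffc, flag = flux_fold_change(vh, vl, zero_threshold)
        records.append(FFCRecord(rid, gid, vl, vh, ffc, flag))

    if include_reactions:
        for gid, fl in sol_l.fluxes.items():
            fh = sol_h.fluxes.get(gid, {})
            for rid, vl in fl.items():
                if rid in fh:
                    add(gid, rid, vl, fh[rid])
    if include_exchanges:
        for gid, exl in sol_l.exchange_fluxes.items():
            exh = sol_h.exchange_fluxes.get(gid, {})
            for met, vl in exl.items():
                if met in exh:
                    add(gid, f"vex({met})", vl, exh[met])
    return FluxComparison(records, zero_threshold)


def minmax_normalize(
    series: Sequence[float],
    source_ids: Optional[Sequence] = None,
    metabolite: str = "",
    guild: str = "",
) -> NormalizedSeries:
    """Min-max normalization on magnitudes, signs reinstated elementwise.

    (|v| - min|v|) / (max|v| - min|v|), then each element recovers the sign
    of the raw flux.  A constant-magnitude series normalizes to all zeros
    and is flagged.
    """
    if len(series) < 2:
        raise ModelError("need at least 2 values to normalize")
    arr = np.asarray(series, dtype=float)
    mags = np.abs(arr)
    span = mags.max() - mags.min()
    if span <= 0:
        values = [0.0] * len(arr)
        return NormalizedSeries(values, list(source_ids or []), metabolite, guild, constant=True)
    normalized = (mags - mags.min()) / span
    signed = np.sign(arr) * normalized
    return NormalizedSeries(
        [float(v) for v in signed], list(source_ids or []), metabolite, guild, constant=False
    )


def exchange_ratio(
    solution: SteadyComSolution,
    metabolite: str,
    guild_a: str,
    guild_b: str,
    zero_threshold: float = ZERO_FLUX_THRESHOLD,
) -> Tuple[float, str]:
    """|Vex(met)^a| / |Vex(met)^b|; flagged infinite below the threshold."""
    va = abs(solution.vex(guild_a, metabolite))
    vb = abs(solution.vex(guild_b, metabolite))
    if vb < zero_threshold:
        return float("inf"), "infinite"
    return va / vb, "ok"


def nadh_partition(
    solution: SteadyComSolution,
    guild: str,
    numerator_rxns: Sequence[str],
    denominator_rxns: Sequence[str],
) -> Tuple[float, str]:
    """Share (%) of reducing power routed into one pathway set vs another.

    Sum of numerator reaction fluxes over sum of denominator fluxes, as a
    percentage — e.g. (V_Apr + V_Dsr) / (V_Acoad1 + V_Hacd1) measures how
    much of the NADH from butyrate oxidation feeds sulfate respiration.
    """
    fluxes = solution.fluxes[guild]
    missing = [r for r in (*numerator_rxns, *denominator_rxns) if r not in fluxes]
    if missing:
        raise ModelError(f"guild {guild}: reactions not in solution: {missing}")
    num = sum(fluxes[r] for r in numerator_rxns)
    den = sum(fluxes[r] for r in denominator_rxns)
    if den == 0:
        return float("nan"), "undefined"
    return 100.0 * num / den, "ok"
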