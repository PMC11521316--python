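"""Sensitivity scans: organic loading, capacity coupling, proton supply.

Three protocols probe how the guild equilibrium responds to its drivers:

* a joint linear butyrate/acetate loading sweep (the seasonal organic
  gradient), tracking growth, abundances and exchange fluxes;
* a 2-D scan of the SRB sulfide-secretion and SOB acetate-uptake
  capacities, mapping which guild dominates as loading rises and where the
  sulfide-oxidizer-dominant community is disrupted;
* an exponential community proton-uptake sweep under high loading (neutral
  to acidic), following the guild abundances and the sulfide oxidizers'
  fluxes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .analytics import NormalizedSeries, minmax_normalize
from .conditions import ConditionSpec, apply_condition
from .core import CommunityModel, ModelError
from .steadycom import SolverSettings, SteadyComSolution, maximize_growth


@dataclass
class ScanPoint:
    axis_values: Dict[str, float]
    status: str
    mu: float
    abundances: Dict[str, float]
    exchange_fluxes: Dict[str, Dict[str, float]]

    @property
    def dominant(self) -> Optional[str]:
        if not self.abundances or self.status not in ("optimal",):
            return None
        return max(self.abundances, key=self.abundances.get)

    def capacity_flux(self, guild: str, met: str) -> float:
        """Per-abundance exchange flux vex = Vex / X (0 when X = 0)."""
        x = self.abundances.get(guild, 0.0)
        if x <= 0:
            return 0.0
        return self.exchange_fluxes[guild].get(met, 0.0) / x


@dataclass
class ScanResult:
    axes: Dict[str, List[float]]
    points: List[ScanPoint]
    normalized_series: Dict[str, NormalizedSeries] = field(default_factory=dict)
    phase_boundaries: List[Dict] = field(default_factory=list)

    @property
    def dominance(self) -> List[Optional[str]]:
        return [p.dominant for p in self.points]

    def abundance_series(self, guild: str) -> List[float]:
        return [p.abundances.get(guild, 0.0) for p in self.points]

    def growth_series(self, guild: str) -> List[float]:
        """Aggregate biomass production mu * X^k along the scan."""
        return [p.mu * p.abundances.get(guild, 0.0) for p in self.points]

    def exchange_series(self, guild: str, met: str) -> List[float]:
        return [p.exchange_fluxes.get(guild, {}).get(met, 0.0) for p in self.points]

    def capacity_series(self, guild: str, met: str) -> List[float]:
        return [p.capacity_flux(guild, met) for p in self.points]

    def to_tsv(self, path=None) -> str:
        axis_names = list(self.axes)
        lines = ["\t".join([*axis_names, "guild", "abundance", "mu", "status"])]
        for p in self.points:
            prefix = [f"{p.axis_values[a]:.6g}" for a in axis_names]
            for g, x in p.abundances.items():
                lines.append("\t".join([*prefix, g, f"{x:.6g}", f"{p.mu:.6g}", p.status]))
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "axes": self.axes,
                "points": [
                    {
                        "axis_values": p.axis_values,
                        "status": p.status,
                        "mu": p.mu,
                        "abundances": p.abundances,
                    }
                    for p in self.points
                ],
                "dominance": self.dominance,
                "phase_boundaries": self.phase_boundaries,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def _solve_point(
    model: CommunityModel,
    condition: ConditionSpec,
    axis_values: Dict[str, float],
    settings: SolverSettings,
    track: Sequence[Tuple[str, str]],
) -> ScanPoint:
    try:
        sol = maximize_growth(apply_condition(model, condition), settings)
    except RuntimeError as exc:  # backend failure: record, keep sweeping
        return ScanPoint(axis_values, f"error: {exc}", 0.0, {}, {})
    exch = {
        g: dict(sol.exchange_fluxes.get(g, {}))
        for g in {gid for gid, _ in track} | set(sol.exchange_fluxes)
    }
    return ScanPoint(axis_values, sol.status, sol.mu, dict(sol.abundances), exch)


DEFAULT_TRACKED = [
    ("SRB", "but"), ("SRB", "so4"), ("SRB", "h2s"), ("SRB", "ac"),
    ("SRB", "h2"), ("SRB", "formate"),
    ("MET", "ac"), ("MET", "ch4"), ("MET", "co2"),
    ("SOB", "ac"), ("SOB", "h2s"), ("SOB", "so4"), ("SOB", "co2"),
]


def _normalize_tracked(result: ScanResult, track: Sequence[Tuple[str, str]]) -> None:
    for gid, met in track:
        series = result.exchange_series(gid, met)
        if len(series) >= 2 and any(v != 0 for v in series):
            result.normalized_series[f"Vex({met})^{gid}"] = minmax_normalize(
                series, metabolite=met, guild=gid
            )
        cap = result.capacity_series(gid, met)
        if len(cap) >= 2 and any(v != 0 for v in cap):
            result.normalized_series[f"vex({met})^{gid}"] = minmax_normalize(
                cap, metabolite=met, guild=gid
            )


def olr_sweep(
    model: CommunityModel,
    condition_base: ConditionSpec,
    butyrate_range: Tuple[float, float] = (0.48, 3.61),
    acetate_range: Tuple[float, float] = (0.77, 2.09),
    n_points: int = 25,
    butyrate_met: str = "but",
    acetate_met: str = "ac",
    track: Sequence[Tuple[str, str]] = DEFAULT_TRACKED,
    settings: Optional[SolverSettings] = None,
) -> ScanResult:
    """Joint linear increase of community butyrate and acetate uptake.

    Both substrate bounds advance together along one scalar (the organic
    gradient); everything else in ``condition_base`` is held fixed.
    Infeasible points are recorded with their status and the sweep
    continues.
    """
    settings = settings or SolverSettings()
    but_axis = np.linspace(*butyrate_range, n_points)
    ac_axis = np.linspace(*acetate_range, n_points)
    points = []
    for b, a in zip(but_axis, ac_axis):
        cond = condition_base.with_rate(butyrate_met, float(b)).with_rate(acetate_met, float(a))
        points.append(
            _solve_point(model, cond, {"butyrate": float(b), "acetate": float(a)},
                         settings, track)
        )
    result = ScanResult(
        {"butyrate": [float(v) for v in but_axis], "acetate": [float(v) for v in ac_axis]},
        points,
    )
    _normalize_tracked(result, track)
    return result


def detect_transition(
    scan: ScanResult,
    guild: str,
    slope_fraction: float = 0.1,
    axis: Optional[str] = None,
) -> List[Dict]:
    """Phase boundaries of a 1-D scan, two detectors.

    (a) dominance switches: indices where the most-abundant guild changes;
    (b) slope break: first index where the guild's growth-vs-loading slope
    falls below ``slope_fraction`` of its initial (first-phase) slope;
    (c) max step: the single largest discrete change of the guild's
    abundance, reported as a drop-point candidate.
    Returns an empty list for monotone featureless scans.
    """
    axis = axis or next(iter(scan.axes))
    xs = scan.axes[axis]
    out: List[Dict] = []
    dom = scan.dominance
    for i in range(1, len(dom)):
        if dom[i] is not None and dom[i - 1] is not None and dom[i] != dom[i - 1]:
            out.append(
                {"kind": "dominance_switch", "index": i, "axis_value": xs[i],
                 "from": dom[i - 1], "to": dom[i]}
            )
    growth = scan.growth_series(guild)
    if len(growth) >= 3:
        slopes = np.diff(growth) / np.diff(xs)
        baseline = slopes[0]
        if baseline > 0:
            for i, s in enumerate(slopes[1:], start=1):
                if s < slope_fraction * baseline:
                    out.append(
                        {"kind": "slope_break", "index": i + 1, "axis_value": xs[i + 1],
                         "guild": guild}
                    )
                    break
    abundance = scan.abundance_series(guild)
    if len(abundance) >= 2:
        steps = np.abs(np.diff(abundance))
        if steps.max() > 0:
            i = int(steps.argmax()) + 1
            out.append({"kind": "max_step", "index": i, "axis_value": xs[i], "guild": guild})
    return sorted(out, key=lambda d: (d["index"], d["kind"]))


def capacity_scan_2d(
    model: CommunityModel,
    condition: ConditionSpec,
    sob_acetate_lb_range: Tuple[float, float] = (-1.05, -3.15),
    srb_sulfide_ub_range: Tuple[float, float] = (4.39, 13.18),
    n_capacity_points: int = 3,
    loading_scales: Optional[Sequence[float]] = None,
    butyrate_met: str = "but",
    acetate_met: str = "ac",
    sob_guild: str = "SOB",
    srb_guild: str = "SRB",
    met_guild: str = "MET",
    acetate_pool: str = "ac",
    sulfide_pool: str = "h2s",
    settings: Optional[SolverSettings] = None,
) -> Dict:
    """Dominance map over (SRB-SOB capacity strength, organic loading).

    For every pair of capacities — the SOB maximal acetate consumption
    (lower bound of vex(acetate)^SOB) and the SRB maximal sulfide release
    (upper bound of vex(sulfide)^SRB) — the loading axis multiplies the
    base condition's butyrate and acetate bounds by each scale in
    ``loading_scales``.  The disruption point of each capacity pair is the
    smallest loading scale at which the methanogens dominate, reported also
    as percent butyrate/acetate increase over the base condition.
    """
    settings = settings or SolverSettings()
    if loading_scales is None:
        loading_scales = [float(s) for s in np.linspace(1.0, 2.5, 16)]
    sob_axis = np.linspace(*sob_acetate_lb_range, n_capacity_points)
    srb_axis = np.linspace(*srb_sulfide_ub_range, n_capacity_points)
    b0 = condition.community_rates[butyrate_met]
    a0 = condition.community_rates[acetate_met]
    # the loading axis advances along the joint organic gradient: butyrate
    # scales by s while acetate follows with the sweep's d(ac)/d(but) slope
    slope = (2.09 - 0.77) / (3.61 - 0.48)
    cells = []
    for ca in sob_axis:
        for cs in srb_axis:
            work = model.copy()
            work.set_capacity(sob_guild, acetate_pool, "lower", float(ca))
            work.set_capacity(srb_guild, sulfide_pool, "upper", float(cs))
            dominance, transition = [], None
            for s in loading_scales:
                db = b0 * (s - 1.0)
                cond = condition.with_rate(butyrate_met, b0 + db).with_rate(
                    acetate_met, a0 + slope * db
                )
                point = _solve_point(work, cond, {"scale": s}, settings, [])
                dominance.append(point.dominant)
                if transition is None and point.dominant == met_guild:
                    transition = s
            cells.append(
                {
                    "sob_acetate_lb": float(ca),
                    "srb_sulfide_ub": float(cs),
                    "dominance": dominance,
                    "transition_scale": transition,
                    "butyrate_increase_pct": None if transition is None
                    else 100.0 * (transition - 1.0),
                    "acetate_increase_pct": None if transition is None
                    else 100.0 * slope * b0 * (transition - 1.0) / a0,
                }
            )
    return {
        "sob_acetate_lb_axis": [float(v) for v in sob_axis],
        "srb_sulfide_ub_axis": [float(v) for v in srb_axis],
        "loading_scales": list(loading_scales),
        "base_butyrate": b0,
        "base_acetate": a0,
        "cells": cells,
    }


def h_plus_sweep(
    model: CommunityModel,
    condition: ConditionSpec,
    h_range: Tuple[float, float] = (4.21e-4, 4.21),
    n_points: int = 25,
    h_met: str = "h",
    track: Sequence[Tuple[str, str]] = (("SOB", "ac"), ("SOB", "h2s"), ("SOB", "co2"),
                                        ("SOB", "h"), ("SOB", "so4")),
    settings: Optional[SolverSettings] = None,
) -> ScanResult:
    """Exponential sweep of the community proton-uptake bound.

    Models acidification under fixed (typically high) organic loading: the
    maximal community H+ influx rises geometrically from neutral to acidic.
    Abundances and the tracked sulfide-oxidizer fluxes are min-max
    normalized across the sweep.
    """
    settings = settings or SolverSettings()
    axis = np.geomspace(*h_range, n_points)
    points = []
    for h in axis:
        cond = condition.with_rate(h_met, float(h))
        points.append(_solve_point(model, cond, {"h_uptake": float(h)}, settings, track))
    result = ScanResult({"h_uptake": [float(v) for v in axis]}, points)
    _normalize_tracked(result, track)
    for gid in model.guild_ids:
        series = result.abundance_series(gid)
        if any(v != 0 for v in series):
            result.normalized_series[f"X^{gid}"] = minmax_normalize(series, guild=gid)
    return result
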