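"""Fitting exchange capacities to observed guild abundances.

The community model's free parameters are per-abundance exchange-capacity
bounds vex(i)^k on the major energy metabolites (acetate, sulfide, protons).
They are calibrated by grid search: every candidate capacity set is applied
to the model, the community optimum is solved, and simulated relative
abundances are scored against observations by unweighted mean percent
error.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .conditions import ConditionSpec, apply_condition
from .core import CommunityModel, ModelError
from .steadycom import SolverSettings, maximize_growth

#: a capacity axis: (guild id, pool metabolite, "lower" | "upper")
CapacityKey = Tuple[str, str, str]


@dataclass
class CapacityParameterSet:
    """A concrete assignment of exchange-capacity bounds."""

    entries: Dict[CapacityKey, float]
    provenance: str = "manual"  # "fitted" | "manual"

    def __post_init__(self) -> None:
        by_pair: Dict[Tuple[str, str], Dict[str, float]] = {}
        for (gid, met, side), value in self.entries.items():
            if side not in ("lower", "upper"):
                raise ModelError(f"capacity side must be lower/upper, got {side!r}")
            by_pair.setdefault((gid, met), {})[side] = value
        for (gid, met), sides in by_pair.items():
            if "lower" in sides and "upper" in sides and sides["lower"] > sides["upper"]:
                raise ModelError(
                    f"{gid}/{met}: lower capacity {sides['lower']} exceeds upper "
                    f"{sides['upper']}"
                )

    def apply(self, model: CommunityModel) -> None:
        for (gid, met, side), value in self.entries.items():
            model.set_capacity(gid, met, side, value)

    def to_dict(self) -> Dict[str, float]:
        return {f"{g}:{m}:{s}": v for (g, m, s), v in self.entries.items()}


@dataclass
class FitResult:
    """Best capacity set plus the full evaluated search trace."""

    best: Optional[CapacityParameterSet]
    per_guild_error: Dict[str, float]
    average_error: float
    search_trace: List[Dict]
    status: str = "ok"

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "status": self.status,
                "best": self.best.to_dict() if self.best else None,
                "per_guild_error": self.per_guild_error,
                "average_error": self.average_error,
                "search_trace": self.search_trace,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload


def percent_error(
    predicted: Mapping[str, float], observed: Mapping[str, float]
) -> Tuple[Dict[str, float], float]:
    """Per-guild |predicted - observed| / observed * 100 and unweighted mean.

    Undefined when any observed abundance is zero.
    """
    if set(predicted) != set(observed):
        raise ModelError(
            f"guild sets differ: predicted {sorted(predicted)} vs observed {sorted(observed)}"
        )
    per_guild = {}
    for g, obs in observed.items():
        if obs <= 0:
            raise ModelError(f"observed abundance of {g!r} must be > 0 (percent error undefined)")
        per_guild[g] = abs(predicted[g] - obs) / obs * 100.0
    return per_guild, float(np.mean(list(per_guild.values())))


def evaluate_capacities(
    model: CommunityModel,
    conditions: Sequence[ConditionSpec],
    capacities: CapacityParameterSet,
    observations: Sequence[Mapping[str, float]],
    settings: Optional[SolverSettings] = None,
) -> Dict:
    """One grid point: apply capacities, solve each condition, score.

    The reported error is the unweighted mean percent error across all
    condition/observation pairs; the per-guild errors are those of the
    first condition (the primary calibration condition).
    """
    work = model.copy()
    capacities.apply(work)
    record = {"capacities": capacities.to_dict(), "status": "optimal"}
    avgs, first_per_guild, first_mu, first_ab = [], None, 0.0, None
    for i, (cond, obs) in enumerate(zip(conditions, observations)):
        sol = maximize_growth(apply_condition(work, cond), settings or SolverSettings())
        if sol.status != "optimal":
            record.update(status=sol.status, per_guild_error=None,
                          average_error=float("inf"), mu=0.0)
            return record
        per_guild, avg = percent_error(sol.abundances, obs)
        avgs.append(avg)
        if i == 0:
            first_per_guild, first_mu, first_ab = per_guild, sol.mu, sol.abundances
    record.update(
        per_guild_error=first_per_guild,
        average_error=float(np.mean(avgs)),
        condition_errors=avgs,
        mu=first_mu,
        abundances=first_ab,
    )
    return record


def fit_exchange_capacities(
    model: CommunityModel,
    condition,
    observed,
    search_space: Mapping[CapacityKey, Sequence[float]],
    settings: Optional[SolverSettings] = None,
    mode: str = "auto",
    refinement_rounds: int = 2,
) -> FitResult:
    """Grid-search capacity bounds to match observed abundances.

    ``search_space`` maps each capacity axis to a finite grid.  With
    ``mode="joint"`` (default for <= 3 axes) the full product grid is
    evaluated in row-major order; ``mode="sequential"`` runs coordinate-wise
    sweeps (repeated ``refinement_rounds`` times), the practical choice for
    larger parameterizations.  Deterministic given the grids; equal-error
    ties resolve to the first point in scan order.

    ``condition``/``observed`` may each be a single item or equal-length
    sequences: fitting against several conditions at once breaks capacity
    degeneracies that a single condition cannot resolve.
    """
    if not search_space:
        raise ModelError("empty search space")
    for key, axis in search_space.items():
        if len(axis) == 0:
            raise ModelError(f"axis {key} is empty")
    conditions = [condition] if isinstance(condition, ConditionSpec) else list(condition)
    observations = [observed] if isinstance(observed, Mapping) else list(observed)
    if len(conditions) != len(observations):
        raise ModelError("need one observation table per condition")
    for obs in observations:
        if abs(sum(obs.values()) - model.x0) > 0.01 * model.x0:
            raise ModelError(
                f"observed abundances sum to {sum(obs.values()):.4f}, expected x0={model.x0}"
            )
    if mode == "auto":
        mode = "joint" if len(search_space) <= 3 else "sequential"

    keys = list(search_space)
    trace: List[Dict] = []

    def score(values: Sequence[float]) -> Dict:
        cand = CapacityParameterSet(dict(zip(keys, values)), provenance="fitted")
        rec = evaluate_capacities(model, conditions, cand, observations, settings)
        trace.append(rec)
        return rec

    if mode == "joint":
        for values in itertools.product(*(search_space[k] for k in keys)):
            score(values)
    elif mode == "sequential":
        current = [search_space[k][0] for k in keys]
        for _ in range(refinement_rounds):
            for i, k in enumerate(keys):
                best_v, best_err = None, float("inf")
                for v in search_space[k]:
                    rec = score([*current[:i], v, *current[i + 1:]])
                    if rec["average_error"] < best_err:
                        best_v, best_err = v, rec["average_error"]
                if best_v is not None:
                    current[i] = best_v
    else:
        raise ValueError(f"unknown mode {mode!r}")

    finite = [r for r in trace if np.isfinite(r["average_error"])]
    if not finite:
        return FitResult(None, {}, float("inf"), trace, status="all-points-infeasible")
    best_rec = min(finite, key=lambda r: r["average_error"])  # first minimum in scan order
    best = CapacityParameterSet(
        {k: best_rec["capacities"][f"{k[0]}:{k[1]}:{k[2]}"] for k in keys},
        provenance="fitted",
    )
    return FitResult(
        best=best,
        per_guild_error=best_rec["per_guild_error"],
        average_error=best_rec["average_error"],
        search_trace=trace,
    )


def default_search_space(
    model: CommunityModel,
    keys: Sequence[CapacityKey],
    n_points: int = 5,
    decades: float = 2.0,
) -> Dict[CapacityKey, List[float]]:
    """Log-spaced grids around each capacity's current value.

    Each axis spans ``decades`` decades (centered) around the present bound
    magnitude, keeping its sign; used when no explicit grid is supplied.
    """
    space = {}
    for gid, met, side in keys:
        current = model.get_capacity(gid, met, side)
        if current == 0:
            raise ModelError(f"{gid}/{met}/{side} is 0; supply an explicit grid")
        mag = abs(current)
        grid = np.geomspace(mag / 10 ** (decades / 2), mag * 10 ** (decades / 2), n_points)
        space[(gid, met, side)] = [float(np.sign(current) * v) for v in grid]
    return space
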