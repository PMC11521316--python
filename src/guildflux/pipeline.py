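"""Config-driven pipeline runner with run manifests.

A run executes the standard analysis sequence — assemble, condition,
(optional) capacity fit, simulate, flux comparison, sensitivity scans —
from one structured config, writing TSV/JSON outputs plus a manifest that
records config and input digests, solver backend, seeds and timestamps.
Identical manifest inputs imply identical deterministic outputs.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import os
import sys
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional

import scipy
import yaml

from . import __version__
from .analytics import compare_solutions
from .conditions import ConditionSpec, apply_condition, cod_to_substrate_rates
from .core import CommunityModel, ModelError, validate_community
from .fitting import fit_exchange_capacities
from .scans import capacity_scan_2d, detect_transition, h_plus_sweep, olr_sweep
from .sbml import read_community_sbml, write_community_sbml
from .steadycom import SolverSettings, maximize_growth
from .synthetic import (
    ToyCommunitySpec,
    high_loading_condition,
    low_loading_condition,
    make_synthetic_observation,
    make_toy_community,
)

STAGES = ("assemble", "condition", "fit", "simulate", "ffc", "scan")


class ConfigError(ValueError):
    """Invalid pipeline configuration (reported before any compute)."""


@dataclass
class RunManifest:
    command: str
    config_hash: str
    input_digests: Dict[str, str]
    solver_backend: str
    seeds: Dict[str, int]
    started: str
    finished: str = ""
    status: str = "running"
    outputs: List[str] = field(default_factory=list)
    version: str = __version__

    def write(self, out_dir: str) -> str:
        path = os.path.join(out_dir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")
        return path


def _sha256(data: bytes) -> str:
    return hashlib.sha256(data).hexdigest()


def _digest_file(path: str) -> str:
    with open(path, "rb") as fh:
        return _sha256(fh.read())


def load_config(source) -> Dict:
    if isinstance(source, Mapping):
        return dict(source)
    with open(source) as fh:
        return yaml.safe_load(fh)


def build_model(cfg: Mapping) -> CommunityModel:
    source = cfg.get("source", "toy")
    if source == "toy":
        spec = ToyCommunitySpec(**cfg.get("toy", {}))
        return make_toy_community(spec)
    return read_community_sbml(
        source,
        guild_compartments=cfg.get("guild_compartments"),
        pool_compartment=cfg.get("pool_compartment"),
        biomass_reactions=cfg.get("biomass_reactions"),
        x0=cfg.get("x0", 1.0),
    )


def build_condition(cfg: Mapping, toy_spec: Optional[ToyCommunitySpec] = None) -> ConditionSpec:
    if "file" in cfg:
        return ConditionSpec.from_json(cfg["file"])
    preset = cfg.get("preset")
    if preset == "low":
        return low_loading_condition(toy_spec)
    if preset == "high":
        return high_loading_condition(toy_spec)
    if "cod_load" in cfg:
        return cod_to_substrate_rates(**cfg)
    if "community_rates" in cfg:
        return ConditionSpec(
            cfg.get("label", "condition"), dict(cfg["community_rates"]),
            list(cfg.get("free_exchange", [])),
            cfg.get("cell_mass", 1.0), cfg.get("cell_yield", 0.15),
        )
    raise ConfigError(f"cannot build a condition from {sorted(cfg)}")


def run_pipeline(config, out_dir: Optional[str] = None) -> RunManifest:
    """Execute the configured stages; nonzero-stage errors keep partial
    outputs and a manifest marked failed."""
    cfg = load_config(config)
    stages = cfg.get("stages", ["assemble", "simulate"])
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigError(f"unknown pipeline stages: {unknown}; valid: {list(STAGES)}")

    out_dir = out_dir or cfg.get("out_dir", "results/run")
    os.makedirs(out_dir, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    digests = {}
    model_cfg = cfg.get("model", {"source": "toy"})
    if model_cfg.get("source", "toy") != "toy" and os.path.exists(model_cfg["source"]):
        digests[model_cfg["source"]] = _digest_file(model_cfg["source"])
    manifest = RunManifest(
        command=" ".join(sys.argv) or "run_pipeline",
        config_hash=_sha256(json.dumps(cfg, sort_keys=True, default=str).encode()),
        input_digests=digests,
        solver_backend=f"scipy-{cfg.get('lp_backend', 'highs')}-{scipy.__version__}",
        seeds={"seed": seed},
        started=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )
    manifest.write(out_dir)

    def emit(name: str, writer) -> str:
        path = os.path.join(out_dir, name)
        writer(path)
        manifest.outputs.append(name)
        return path

    settings = SolverSettings(
        mu_tolerance=float(cfg.get("mu_tolerance", 1e-6)),
        flux_resolution=cfg.get("flux_resolution", "none"),
    )
    try:
        toy_spec = ToyCommunitySpec(**model_cfg.get("toy", {})) \
            if model_cfg.get("source", "toy") == "toy" else None
        model = build_model(model_cfg)
        conditions = {
            name: build_condition(ccfg, toy_spec)
            for name, ccfg in cfg.get("conditions", {}).items()
        }

        if "assemble" in stages:
            report = validate_community(model)
            emit("validation.json", report.to_json)
            emit("exchange_sets.tsv", report.exchange_sets_tsv)
            emit("community.xml", lambda p: write_community_sbml(model, p))
        if "condition" in stages:
            for name, spec in conditions.items():
                emit(f"condition_{name}.json", spec.to_json)
                emit(f"condition_{name}.tsv", spec.to_tsv)
        if "fit" in stages:
            fcfg = cfg["fit"]
            cond = conditions[fcfg["condition"]]
            observed = dict(fcfg["observed"])
            grid = {
                tuple(k.split(":")): [float(v) for v in axis]
                for k, axis in fcfg["grid"].items()
            }
            result = fit_exchange_capacities(
                model, cond, observed, grid, settings, mode=fcfg.get("mode", "auto")
            )
            emit("fit.json", result.to_json)
            if result.best is not None:
                result.best.apply(model)
        solutions = {}
        if "simulate" in stages or "ffc" in stages:
            for name, cond in conditions.items():
                sol = maximize_growth(apply_condition(model, cond), settings)
                solutions[name] = sol
                emit(f"solution_{name}.json", sol.to_json)
                emit(f"solution_{name}.tsv", sol.to_tsv)
        if "ffc" in stages:
            fcfg = cfg.get("ffc", {})
            low = fcfg.get("low", "low")
            high = fcfg.get("high", "high")
            if low not in solutions or high not in solutions:
                raise ConfigError(f"ffc stage needs conditions {low!r} and {high!r}")
            comparison = compare_solutions(solutions[low], solutions[high])
            emit("ffc.tsv", comparison.to_tsv)
        if "scan" in stages:
            scfg = cfg.get("scan", {"mode": "olr"})
            mode = scfg.get("mode", "olr")
            cond = conditions[scfg.get("condition", next(iter(conditions)))]
            if mode == "olr":
                scan = olr_sweep(
                    model, cond,
                    tuple(scfg.get("butyrate_range", (0.48, 3.61))),
                    tuple(scfg.get("acetate_range", (0.77, 2.09))),
                    int(scfg.get("n_points", 25)), settings=settings,
                )
                scan.phase_boundaries = detect_transition(scan, scfg.get("guild", "SOB"))
                emit("scan_olr.tsv", scan.to_tsv)
                emit("scan_olr.json", scan.to_json)
            elif mode == "hplus":
                scan = h_plus_sweep(
                    model, cond, tuple(scfg.get("h_range", (4.21e-4, 4.21))),
                    int(scfg.get("n_points", 25)), settings=settings,
                )
                scan.phase_boundaries = detect_transition(
                    scan, scfg.get("guild", "MET"), axis="h_uptake"
                )
                emit("scan_hplus.tsv", scan.to_tsv)
                emit("scan_hplus.json", scan.to_json)
            elif mode == "capacity2d":
                result = capacity_scan_2d(
                    model, cond,
                    tuple(scfg.get("sob_acetate_lb_range", (-1.05, -3.15))),
                    tuple(scfg.get("srb_sulfide_ub_range", (4.39, 13.18))),
                    int(scfg.get("n_capacity_points", 3)),
                    scfg.get("loading_scales"), settings=settings,
                )
                emit("scan_capacity2d.json",
                     lambda p: json.dump(result, open(p, "w"), indent=2))
            else:
                raise ConfigError(f"unknown scan mode {mode!r}")
    except Exception:
        manifest.status = "failed"
        manifest.finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
        manifest.write(out_dir)
        raise
    manifest.status = "ok"
    manifest.finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
    manifest.write(out_dir)
    return manifest
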