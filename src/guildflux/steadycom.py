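"""Community steady-state growth optimization (SteadyCom formulation).

The community problem maximizes a growth rate mu shared by all guilds:

    max mu   s.t., for every guild k
        S^k V^k = 0                      (guild mass balance)
        LB_j^k X^k <= V_j^k <= UB_j^k X^k  (abundance-scaled capacities)
        V_biomass^k = X^k mu             (biomass coupling)
        X^k >= 0
    and, for every pool metabolite i,
        u_i - e_i + sum_k Vex(i)^k = 0   (community-pool balance)
        0 <= u_i <= U_i X0,  0 <= e_i <= E_i X0
        sum_k X^k = X0

For a fixed mu everything is linear in (V, X, u, e), so feasibility is an
LP: maximize sum_k X^k under all constraints except the abundance total;
mu is feasible iff that optimum reaches X0.  The largest feasible mu is
found by monotone bisection.  Optima are flux-degenerate; a parsimonious
re-solve (minimize total absolute internal flux at fixed mu and X) makes
reported fluxes unique.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core import CommunityModel, ModelError

_STATUS = {0: "optimal", 1: "iteration-limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


@dataclass
class SolverSettings:
    """Numerical knobs for the community solver.

    mu_tolerance      bisection convergence threshold on mu (h^-1)
    mu_upper_seed     initial upper bracket for mu; grown by doubling if
                      still feasible (None -> 1.0)
    lp_backend        scipy linprog method name
    flux_resolution   "none" or "parsimonious"
    zero_flux_threshold  |flux| below this reports as exactly zero
                      (mmol g^-1 h^-1)
    """

    mu_tolerance: float = 1e-6
    mu_upper_seed: Optional[float] = None
    lp_backend: str = "highs"
    flux_resolution: str = "none"
    zero_flux_threshold: float = 1e-6
    feasibility_tol: float = 1e-9
    x_cap: float = 1e6  # abundance cap to keep the max-X LP bounded

    def __post_init__(self) -> None:
        if self.mu_tolerance <= 0:
            raise ValueError("mu_tolerance must be > 0")
        if self.zero_flux_threshold < 0:
            raise ValueError("zero_flux_threshold must be >= 0")


@dataclass
class FeasibilityResult:
    """Outcome of the fixed-mu LP: max total abundance and a witness."""

    mu: float
    status: str
    total_abundance: float
    abundances: Dict[str, float]
    raw: Optional[np.ndarray] = None  # full variable vector (V, X, u, e)

    @property
    def unbounded(self) -> bool:
        return self.status == "unbounded"


@dataclass
class SteadyComSolution:
    """Community optimum: growth rate, abundances and aggregate fluxes.

    ``fluxes[k][j]`` is the aggregate flux V_j^k (already scaled by
    abundance); ``exchange_fluxes[k][i]`` the guild->pool exchange flux of
    pool metabolite i (positive = secretion).  ``community_uptake`` /
    ``community_export`` are the pool's u_i / e_i.
    """

    mu: float
    abundances: Dict[str, float]
    fluxes: Dict[str, Dict[str, float]]
    exchange_fluxes: Dict[str, Dict[str, float]]
    community_uptake: Dict[str, float]
    community_export: Dict[str, float]
    status: str = "optimal"

    def abundance_vector(self, order: Optional[List[str]] = None) -> np.ndarray:
        order = order or list(self.abundances)
        return np.array([self.abundances[g] for g in order])

    @property
    def total_abundance(self) -> float:
        return float(sum(self.abundances.values()))

    def flux(self, guild_id: str, rxn_id: str) -> float:
        return self.fluxes[guild_id][rxn_id]

    def vex(self, guild_id: str, pool_met: str) -> float:
        return self.exchange_fluxes[guild_id].get(pool_met, 0.0)

    def growth_flux(self, guild_id: str) -> float:
        """Aggregate biomass production X^k mu of one guild."""
        return self.abundances[guild_id] * self.mu

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "mu": self.mu,
                "status": self.status,
                "abundances": self.abundances,
                "exchange_fluxes": self.exchange_fluxes,
                "community_uptake": self.community_uptake,
                "community_export": self.community_export,
                "fluxes": self.fluxes,
            },
            indent=2,
            sort_keys=True,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload + "\n")
        return payload

    def to_tsv(self, path=None) -> str:
        lines = ["guild\treaction\tflux"]
        for gid, fl in self.fluxes.items():
            for rid, v in fl.items():
                lines.append(f"{gid}\t{rid}\t{v:.10g}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class CommunityLP:
    """Index bookkeeping and matrix assembly for the community LP.

    Variable layout: all guild reaction fluxes (guild-major), then one
    abundance per guild, then pool uptakes u_i, then pool exports e_i.
    """

    def __init__(self, model: CommunityModel):
        self.model = model
        self.var_names: List[str] = []
        self.rxn_index: Dict[Tuple[str, str], int] = {}
        for g in model.guilds:
            for r in g.reactions:
                self.rxn_index[(g.guild_id, r.id)] = len(self.var_names)
                self.var_names.append(f"V[{g.guild_id}][{r.id}]")
        self.x_index = {}
        for g in model.guilds:
            self.x_index[g.guild_id] = len(self.var_names)
            self.var_names.append(f"X[{g.guild_id}]")
        self.u_index = {}
        for m in model.com_metabolites:
            self.u_index[m] = len(self.var_names)
            self.var_names.append(f"u[{m}]")
        self.e_index = {}
        for m in model.com_metabolites:
            self.e_index[m] = len(self.var_names)
            self.var_names.append(f"e[{m}]")
        self.n_vars = len(self.var_names)
        self._build_static()

    def _build_static(self) -> None:
        model = self.model
        eq_rows: List[Tuple[int, int, float]] = []
        n_eq = 0
        # guild-internal metabolite balances
        for g in model.guilds:
            met_row = {}
            for m in g.metabolites:
                met_row[m] = n_eq
                n_eq += 1
            for r in g.reactions:
                col = self.rxn_index[(g.guild_id, r.id)]
                for m, c in r.stoich.items():
                    eq_rows.append((met_row[m], col, c))
        # pool balances: u - e + sum_k Vex = 0
        self.pool_row = {}
        for m in model.com_metabolites:
            row = n_eq
            self.pool_row[m] = row
            n_eq += 1
            eq_rows.append((row, self.u_index[m], 1.0))
            eq_rows.append((row, self.e_index[m], -1.0))
        for g in model.guilds:
            for rid, pool_met in g.exchange_reactions.items():
                col = self.rxn_index[(g.guild_id, rid)]
                eq_rows.append((self.pool_row[pool_met], col, g.pool_coefficient(rid)))
        # biomass coupling rows V_bio - mu X = 0 (mu coefficient patched later)
        self.biomass_row = {}
        self._mu_entries: List[Tuple[int, int]] = []
        for g in model.guilds:
            row = n_eq
            self.biomass_row[g.guild_id] = row
            n_eq += 1
            eq_rows.append((row, self.rxn_index[(g.guild_id, g.biomass_reaction)], 1.0))
            self._mu_entries.append((row, self.x_index[g.guild_id]))
        self.n_eq = n_eq
        self._eq_static = eq_rows

        # capacity inequalities: V - ub X <= 0 and lb X - V <= 0
        ub_rows: List[Tuple[int, int, float]] = []
        n_ub = 0
        for g in model.guilds:
            xcol = self.x_index[g.guild_id]
            for r in g.reactions:
                col = self.rxn_index[(g.guild_id, r.id)]
                if np.isfinite(r.ub):
                    ub_rows.append((n_ub, col, 1.0))
                    ub_rows.append((n_ub, xcol, -r.ub))
                    n_ub += 1
                if np.isfinite(r.lb):
                    ub_rows.append((n_ub, col, -1.0))
                    ub_rows.append((n_ub, xcol, r.lb))
                    n_ub += 1
        self.n_ub = n_ub
        self._ub_static = ub_rows

    def matrices(self, mu: float):
        rows = self._eq_static + [(r, c, -mu) for r, c in self._mu_entries]
        i, j, v = zip(*rows)
        A_eq = sparse.coo_matrix((v, (i, j)), shape=(self.n_eq, self.n_vars)).tocsr()
        if self._ub_static:
            i, j, v = zip(*self._ub_static)
            A_ub = sparse.coo_matrix((v, (i, j)), shape=(self.n_ub, self.n_vars)).tocsr()
        else:
            A_ub = None
        return A_eq, A_ub

    def variable_bounds(self, x_cap: float) -> List[Tuple[Optional[float], Optional[float]]]:
        model = self.model
        bounds: List[Tuple[Optional[float], Optional[float]]] = [
            (None, None)
        ] * (self.n_vars - 2 * len(model.com_metabolites) - len(model.guilds))
        bounds += [(0.0, x_cap)] * len(model.guilds)
        scale = model.x0
        bounds += [(0.0, scale * model.uptake_bounds.get(m, 0.0)) for m in model.com_metabolites]
        bounds += [(0.0, scale * model.export_bounds.get(m, 0.0)) for m in model.com_metabolites]
        return bounds

    def unpack(self, z: np.ndarray) -> Tuple[Dict, Dict, Dict, Dict, Dict]:
        model = self.model
        fluxes = {
            g.guild_id: {r.id: float(z[self.rxn_index[(g.guild_id, r.id)]]) for r in g.reactions}
            for g in model.guilds
        }
        abundances = {gid: float(z[ix]) for gid, ix in self.x_index.items()}
        exchange = {
            g.guild_id: {
                pool_met: float(g.pool_coefficient(rid) * z[self.rxn_index[(g.guild_id, rid)]])
                for rid, pool_met in g.exchange_reactions.items()
            }
            for g in model.guilds
        }
        uptake = {m: float(z[self.u_index[m]]) for m in model.com_metabolites}
        export = {m: float(z[self.e_index[m]]) for m in model.com_metabolites}
        return abundances, fluxes, exchange, uptake, export


def solve_at_growth(
    model: CommunityModel, mu: float, settings: Optional[SolverSettings] = None
) -> FeasibilityResult:
    """Fixed-mu LP: maximize total abundance under all other constraints.

    mu is feasible for the community iff ``total_abundance >= model.x0``.
    A zero-coupling community at mu = 0 is flagged "unbounded" rather than
    raising.
    """
    settings = settings or SolverSettings()
    if mu < 0:
        raise ValueError("mu must be >= 0")
    lp = CommunityLP(model)
    return _solve_max_abundance(lp, mu, settings)


def _solve_max_abundance(lp: CommunityLP, mu: float, settings: SolverSettings) -> FeasibilityResult:
    A_eq, A_ub = lp.matrices(mu)
    c = np.zeros(lp.n_vars)
    for ix in lp.x_index.values():
        c[ix] = -1.0
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=np.zeros(lp.n_ub) if A_ub is not None else None,
        A_eq=A_eq,
        b_eq=np.zeros(lp.n_eq),
        bounds=lp.variable_bounds(settings.x_cap),
        method=settings.lp_backend,
    )
    if res.status not in (0, 3):
        if res.status == 2:
            return FeasibilityResult(mu, "infeasible", 0.0, {g: 0.0 for g in lp.x_index})
        raise RuntimeError(f"LP backend failure at mu={mu}: {_STATUS.get(res.status)} ({res.message})")
    total = float(-res.fun)
    abundances = {gid: float(res.x[ix]) for gid, ix in lp.x_index.items()}
    status = "optimal"
    if res.status == 3 or total >= 0.99 * settings.x_cap:
        status = "unbounded"
    return FeasibilityResult(mu, status, total, abundances, raw=res.x)


def maximize_growth(
    model: CommunityModel, settings: Optional[SolverSettings] = None
) -> SteadyComSolution:
    """Largest feasible community growth rate, by monotone bisection.

    Feasibility of a trial mu means the fixed-mu LP reaches the required
    total abundance X0.  The bracket starts at ``mu_upper_seed`` and doubles
    while still feasible; bisection stops at ``mu_tolerance``.  The witness
    point is rescaled so abundances sum exactly to X0 (the constraint set is
    positively homogeneous in (V, X, u, e), so scaling preserves
    feasibility).  If no mu >= mu_tolerance is feasible the solution reports
    mu = 0 with status "infeasible-growth".
    """
    settings = settings or SolverSettings()
    lp = CommunityLP(model)
    target = model.x0 - max(1e-9, 1e-9 * model.x0)

    def attempt(mu: float) -> FeasibilityResult:
        return _solve_max_abundance(lp, mu, settings)

    lo_res = attempt(settings.mu_tolerance)
    if lo_res.total_abundance < target:
        zero = attempt(0.0)
        return _witness_solution(lp, zero, 0.0, status="infeasible-growth", rescale=False)
    lo, best = settings.mu_tolerance, lo_res
    hi = settings.mu_upper_seed if settings.mu_upper_seed is not None else 1.0
    hi = max(hi, 2 * lo)
    while True:
        res = attempt(hi)
        if res.total_abundance < target:
            break
        lo, best = hi, res
        if hi > 1e4:
            return _witness_solution(lp, best, hi, status="unbounded", rescale=True)
        hi *= 2.0
    while hi - lo > settings.mu_tolerance:
        mid = 0.5 * (lo + hi)
        res = attempt(mid)
        if res.total_abundance >= target:
            lo, best = mid, res
        else:
            hi = mid
    solution = _witness_solution(lp, best, lo, status="optimal", rescale=True)
    if settings.flux_resolution == "parsimonious":
        solution = resolve_fluxes(model, solution, settings)
    return solution


def _witness_solution(
    lp: CommunityLP,
    res: FeasibilityResult,
    mu: float,
    status: str,
    rescale: bool,
) -> SteadyComSolution:
    if res.raw is None:
        empty = {g.guild_id: {} for g in lp.model.guilds}
        return SteadyComSolution(mu, {g: 0.0 for g in lp.x_index}, empty, empty, {}, {}, status)
    z = res.raw.copy()
    if rescale and res.total_abundance > 0:
        z *= lp.model.x0 / res.total_abundance
    abundances, fluxes, exchange, uptake, export = lp.unpack(z)
    return SteadyComSolution(mu, abundances, fluxes, exchange, uptake, export, status)


def resolve_fluxes(
    model: CommunityModel,
    solution: SteadyComSolution,
    settings: Optional[SolverSettings] = None,
) -> SteadyComSolution:
    """Parsimonious flux determinization at fixed mu and abundances.

    Re-solves for V, u, e minimizing the total absolute flux of internal
    (non-exchange, non-biomass) reactions, with each V_j confined to its
    abundance-scaled capacity interval and each biomass flux pinned to
    X^k mu.  Fluxes below ``zero_flux_threshold`` are reported as exact
    zeros.  On numerical infeasibility the biomass pins are relaxed by 1e-7
    and the solve retried once.
    """
    settings = settings or SolverSettings()
    if solution.status not in ("optimal",):
        raise ModelError(f"cannot resolve fluxes of a {solution.status!r} solution")
    lp = CommunityLP(model)
    n_pool = len(model.com_metabolites)

    internal_cols = []
    for g in model.guilds:
        for r in g.reactions:
            if r.id in g.exchange_reactions or r.id == g.biomass_reaction:
                continue
            internal_cols.append(lp.rxn_index[(g.guild_id, r.id)])
    n_aux = len(internal_cols)

    def build_and_solve(relax: float):
        bounds: List[Tuple[Optional[float], Optional[float]]] = []
        for g in model.guilds:
            xk = solution.abundances[g.guild_id]
            for r in g.reactions:
                if r.id == g.biomass_reaction:
                    pin = xk * solution.mu
                    bounds.append((pin - relax, pin + relax))
                else:
                    lb = r.lb * xk if np.isfinite(r.lb) else None
                    ub = r.ub * xk if np.isfinite(r.ub) else None
                    bounds.append((lb, ub))
        # X variables pinned
        for g in model.guilds:
            xk = solution.abundances[g.guild_id]
            bounds.append((xk, xk))
        scale = model.x0
        bounds += [(0.0, scale * model.uptake_bounds.get(m, 0.0)) for m in model.com_metabolites]
        bounds += [(0.0, scale * model.export_bounds.get(m, 0.0)) for m in model.com_metabolites]
        bounds += [(0.0, None)] * n_aux  # t_j >= |V_j|

        A_eq, _ = lp.matrices(solution.mu)
        A_eq = sparse.hstack([A_eq, sparse.csr_matrix((lp.n_eq, n_aux))]).tocsr()
        rows, cols, vals = [], [], []
        for k, col in enumerate(internal_cols):
            rows += [2 * k, 2 * k, 2 * k + 1, 2 * k + 1]
            cols += [col, lp.n_vars + k, col, lp.n_vars + k]
            vals += [1.0, -1.0, -1.0, -1.0]
        A_ub = sparse.coo_matrix((vals, (rows, cols)), shape=(2 * n_aux, lp.n_vars + n_aux)).tocsr()
        c = np.zeros(lp.n_vars + n_aux)
        c[lp.n_vars:] = 1.0
        return linprog(
            c,
            A_ub=A_ub,
            b_ub=np.zeros(2 * n_aux),
            A_eq=A_eq,
            b_eq=np.zeros(lp.n_eq),
            bounds=bounds,
            method=settings.lp_backend,
        )

    res = build_and_solve(relax=0.0)
    if res.status != 0:
        res = build_and_solve(relax=1e-7)
        if res.status != 0:
            raise RuntimeError(
                f"parsimonious re-solve failed: {_STATUS.get(res.status)} ({res.message})"
            )
    z = res.x[: lp.n_vars]
    thr = settings.zero_flux_threshold
    z[np.abs(z) < thr] = 0.0
    abundances, fluxes, exchange, uptake, export = lp.unpack(z)
    return SteadyComSolution(
        solution.mu, dict(solution.abundances), fluxes, exchange, uptake, export, "optimal"
    )


def conservation_residuals(model: CommunityModel, solution: SteadyComSolution) -> Dict[str, float]:
    """Pool-balance residuals u - e + sum_k Vex per pool metabolite."""
    out = {}
    for m in model.com_metabolites:
        tot = solution.community_uptake.get(m, 0.0) - solution.community_export.get(m, 0.0)
        for g in model.guilds:
            tot += solution.exchange_fluxes[g.guild_id].get(m, 0.0)
        out[m] = tot
    return out


def guild_balance_residuals(model: CommunityModel, solution: SteadyComSolution) -> Dict[str, float]:
    """Max |S^k V^k| residual per guild."""
    out = {}
    for g in model.guilds:
        acc: Dict[str, float] = {}
        for r in g.reactions:
            v = solution.fluxes[g.guild_id][r.id]
            for m, coeff in r.stoich.items():
                acc[m] = acc.get(m, 0.0) + coeff * v
        out[g.guild_id] = max((abs(x) for x in acc.values()), default=0.0)
    return out
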