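# guildflux

Community flux-balance modeling of cross-feeding microbial guilds in
anaerobic wastewater treatment.

Microbial fuel cells (MFCs) treating sulfide-rich industrial wastewater are
run by a small set of functional guilds: sulfate-reducing bacteria (SRB)
that oxidize butyrate to acetate using sulfate as the terminal electron
acceptor, acetoclastic methanogens (MET) that split acetate into CH₄ and
CO₂, and photon-driven sulfide-oxidizing bacteria (SOB) that regenerate
sulfate and assimilate acetate and CO₂. These guilds feed each other through
a shared extracellular pool — acetate and sulfur cycling above all — and the
balance of that cross-feeding decides which guild dominates as the organic
loading rate (OLR) of the wastewater varies between production seasons.

`guildflux` builds compartmentalized community models of such guilds (one
stoichiometric compartment per guild plus a shared `COM` pool), solves the
community steady-state growth problem, derives condition-specific boundary
fluxes from wastewater chemistry, calibrates exchange capacities against
observed relative abundances, and runs the comparison analytics and
sensitivity scans that expose the cross-feeding mechanism.

## The community growth problem

All guilds grow at a common specific rate μ, with per-guild abundances
Xᵏ acting as capacity scalers:

```
max μ   subject to, for every guild k:
    Σⱼ Sᵢⱼᵏ Vⱼᵏ = 0                       (guild mass balance)
    LBⱼᵏ Xᵏ ≤ Vⱼᵏ ≤ UBⱼᵏ Xᵏ              (abundance-scaled capacities)
    V_biomassᵏ = Xᵏ μ                     (biomass coupling)
    Xᵏ ≥ 0
and, for every pool metabolite i:
    uᵢ − eᵢ + Σₖ Vex(i)ᵏ = 0              (community-pool balance)
    Σₖ Xᵏ = X₀
```

For fixed μ this is a linear program in (V, X, u, e); μ is feasible when the
maximal total abundance reaches X₀, and the optimum μ\* is found by monotone
bisection (HiGHS backend through `scipy.optimize.linprog`). Optima are
flux-degenerate, so reported fluxes come from a parsimonious re-solve
(minimum total absolute internal flux at fixed μ\*, X\*).

The key tunable parameters are the per-abundance exchange capacities
vex(i)ᵏ of the major energy metabolites — e.g. the maximum acetate
consumption of SOB (lower bound of vex(acetate)ᴼᴮ), the minimum acetate
consumption of MET (upper bound of vex(acetate)ᴹᴱᵀ), and the maximum
sulfide release of SRB (upper bound of vex(sulfide)ˢᴿᴮ) — which are
calibrated by grid search against observed guild abundances (unweighted
mean percent error).

## Worked example

The package ships a fully specified three-guild community
(`guildflux.synthetic`) whose lumped pathways mirror the MFC guild roles.
Simulating its two seasonal conditions:

```python
from guildflux.conditions import apply_condition
from guildflux.steadycom import SolverSettings, maximize_growth
from guildflux.synthetic import (ToyCommunitySpec, make_toy_community,
                                 low_loading_condition, high_loading_condition)

spec = ToyCommunitySpec()
model = make_toy_community(spec)
for cond in (low_loading_condition(spec), high_loading_condition(spec)):
    sol = maximize_growth(apply_condition(model, cond), SolverSettings())
    print(cond.label, f"mu={sol.mu:.4f}",
          {g: round(x, 3) for g, x in sol.abundances.items()})
```

prints

```
L-OLR mu=0.3232 {'SRB': 0.141, 'MET': 0.344, 'SOB': 0.515}
H-OLR mu=0.4529 {'SRB': 0.108, 'MET': 0.521, 'SOB': 0.371}
```

At low loading the sulfide oxidizers hold 51% of the community and the
sulfate reducers are the smallest guild; multiplying the butyrate bound by
1.56 and the acetate bound by 1.30 (the seasonal fold changes) hands
dominance to the methanogens (52%). The mechanism is visible in the flux
analytics (`analysis/04_flux_fold_changes.py`): the share of
butyrate-derived NADH entering sulfate respiration falls from 50% to 29%
between the seasons, sulfide delivery to the SOB stalls at the SRB
secretion capacity, and the acetate surplus accrues to the methanogens.

The numbered drivers under `analysis/` run the full study end to end
(community assembly and audit, seasonal simulation, capacity calibration,
flux fold changes, sensitivity scans) and write their tables under
`results/`. A `guildflux` command-line interface wraps the same steps
(`guildflux simulate --model toy --condition low --out sol.json`; see
`guildflux --help`).

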