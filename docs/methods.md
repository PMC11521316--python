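# Methods

## Model and assumptions

The community is represented as a compartmentalized stoichiometric model:
one compartment per microbial guild (a functional cohort, not a species)
and one fictitious shared pool (`COM`) through which all cross-feeding
passes. Guild exchange reactions carry the sign convention positive =
secretion into the pool; the pool exchanges with the outside world through
non-negative uptake (u) and export (e) reactions per metabolite. The
steady-state assumption applies at the community level: every guild-internal
metabolite and every pool metabolite is balanced, all guilds share one
growth rate μ, and each guild's flux capacities scale with its relative
abundance Xᵏ (bounds LBⱼᵏ·Xᵏ ≤ Vⱼᵏ ≤ UBⱼᵏ·Xᵏ). Biomass production is
coupled as V_biomassᵏ = Xᵏ·μ and abundances satisfy ΣXᵏ = X₀.

Community uptake/export bounds are interpreted as specific rates per gram
of total community biomass and are multiplied by X₀ inside the solver; this
makes the whole constraint set positively homogeneous in (V, X, u, e), so
rescaling X₀ rescales fluxes and abundances without changing μ\*.

## Solver

For fixed μ the problem is an LP in (V, X, u, e); we maximize ΣXᵏ subject
to everything except the abundance total, and call μ feasible when the
optimum reaches X₀. Since the feasible μ-set is an interval, the optimum is
found by doubling the upper bracket from `mu_upper_seed` (default 1.0) and
bisecting to `mu_tolerance` (default 1e-6 h⁻¹). μ = 0 is trivially feasible
and excluded; when no μ ≥ `mu_tolerance` is feasible the solution reports
μ = 0 with status `infeasible-growth`. The witness point of the last
feasible LP is rescaled so ΣXᵏ = X₀ exactly (homogeneity makes the scaled
point feasible). LPs are solved with HiGHS via `scipy.optimize.linprog`;
abundance ties at the optimum are reported as returned by the LP and are
solver-determined to machine precision.

Flux degeneracy: the max-ΣX optimum does not pin individual fluxes, so
reported flux distributions come from a parsimonious re-solve — with μ and
X fixed, minimize Σ|Vⱼ| over internal (non-exchange, non-biomass)
reactions, biomass fluxes pinned to Xᵏμ, each flux confined to its
abundance-scaled capacity interval. Fluxes below the zero-flux threshold
(1e-6 mmol g⁻¹ h⁻¹) are reported as exact zeros. If the pinned LP is
numerically infeasible the biomass pins are relaxed by 1e-7 and the solve
retried once.

Thermodynamically infeasible loops are detected structurally (nullspace
basis vectors of the internal stoichiometric matrix with support on more
than one reaction) and reported by the validator; no loop-law constraints
are imposed — the parsimonious objective removes free cycles from reported
fluxes.

## Condition derivation from wastewater chemistry

Loads are converted to specific community bounds as follows: the volatile
fatty acid (VFA) pool is a fixed fraction of the chemical-oxygen-demand
(COD) load — default 0.6312, the measured share — and is split between
butyrate and acetate by mole fractions. O₂ equivalents per mmol come from
complete-oxidation stoichiometry (butyrate 5 O₂ → 160 mg O₂/mmol; acetate
2 O₂ → 64 mg O₂/mmol). Community cell mass is cell yield × COD load with
the default yield 0.15 g cell-O₂ per g substrate-O₂, and every specific
rate is load (mmol/h) divided by cell mass (g). Sulfate and sulfide loads
convert by molar mass (96.06, 34.08 mg/mmol). A zero COD load returns a
flagged zero-condition instead of dividing by zero.

The butyrate:acetate molar split is not published; the default (0.563 :
0.437) is the value implied by the low-loading community C4/C2 uptake-flux
ratio of 1.29. With the seasonal fold changes (butyrate ×1.56, acetate
×1.30) this reproduces the shift of the C4/C2 ratio from 1.29 to 1.54 —
an arithmetic identity of the builder that the tests assert exactly.

Applying a condition is closed-world: metabolites named in the condition
get the specified one-sided bound (positive = max influx, negative = max
efflux), free-exchange metabolites (default photon, water, phosphate,
ammonium) are opened both ways, everything else is closed so it can only
circulate among guilds.

## Capacity calibration

Exchange capacities are fitted by exhaustive grid search (row-major order,
first-minimum tie-break; coordinate-wise refinement is available for > 3
axes). The score is the unweighted mean percent error of simulated vs
observed relative abundances. The fitter accepts several
condition/observation pairs and averages the error across them: in the
synthetic community a single condition leaves a near-degenerate ridge
(weaker methanogen acetate minimum compensated by stronger sulfide
release), and adding a second, higher-loading condition breaks it. Fitting
only makes sense for capacities that are active constraints at the fitting
conditions; in the synthetic community these are the methanogens' minimum
acetate consumption and the sulfate reducers' maximum sulfide release (the
sulfide-oxidizer acetate cap only binds at growth rates above ~0.75 h⁻¹,
which the default conditions do not reach, so it is held at its preset).

## Comparison analytics

Flux fold change: FFC = log₂(V_high / V_low) for pairs that are nonzero
(|V| ≥ 1e-6 mmol g⁻¹ h⁻¹) and of equal sign; zero and sign-reversing pairs
return flags (`zeroed_L`, `zeroed_H`, `both_zero`, `sign_discordant`)
rather than numbers. |FFC| categories low/medium/high use cut points 0.64
(the seasonal butyrate-uptake fold change, log₂ 1.56) and 2. Sweep series
are min-max normalized on magnitudes — (|v|−min|v|)/(max|v|−min|v|) — with
original signs reinstated elementwise; constant series normalize to zero
and are flagged. Cross-feeding ratios are magnitude ratios of two guilds'
exchange fluxes of one metabolite; the NADH partition is the flux sum of a
pathway set over another, as a percentage (in the synthetic community,
sulfate reduction over butyrate oxidation).

## Sensitivity scans

The organic-loading sweep advances the community butyrate and acetate
uptake bounds jointly and linearly (default ranges 0.48–3.61 and 0.77–2.09
mmol g⁻¹ h⁻¹; 25 points), holding everything else at the base condition.
The 2-D capacity scan varies the sulfide-oxidizer acetate lower bound
(−1.05 to −3.15) and the sulfate-reducer sulfide upper bound (4.39 to
13.18) and, for each pair, walks the loading axis along the sweep
direction (d acetate/d butyrate = 1.32/3.13 ≈ 0.42) until the methanogens
dominate, reporting the disruption point as percent butyrate/acetate
increase over the base loading. The proton sweep raises the community H⁺
uptake bound geometrically (4.21×10⁻⁴ to 4.21 mmol g⁻¹ h⁻¹, neutral to
acidic) under the high-loading condition.

Phase detection on a 1-D scan reports three candidate boundaries:
dominance switches; the first point where a guild's growth-vs-loading
slope falls below 10% (configurable) of its initial slope; and the largest
single step of the guild's abundance (the drop-point candidate). Infeasible
scan points are recorded with their status and skipped in dominance labels.

## The synthetic community

Each guild carries 11–18 reactions lumping its defining pathways:

* **SRB** — butyrate → 2 acetate + 2 NADH + 0.3 ATP (acyl-CoA /
  3-hydroxyacyl-CoA dehydrogenases with acetate kinase); sulfate + 4 NADH →
  sulfide + 2 ATP (Apr/Dsr plus electron-transport phosphorylation); NADH
  overflow to H₂ and formate; biomass = 1 acetate + 40 ATP + NH₄ + Pᵢ +
  0.01 sulfide. The sulfide term is assimilatory sulfur: biomass synthesis
  strictly requires reduced S, so deleting sulfate from the pool blocks SRB
  growth entirely (respiration and assimilation both fail).
* **MET** — acetate → CH₄ + CO₂ + 0.5 ATP (acetoclastic chemiosmosis,
  Hdr/Fpo/Mtr lumped); biomass = 1 acetate + 3.5 ATP + NH₄ + Pᵢ.
* **SOB** — sulfide + 4 photon → sulfate + 3.5 ATP (full oxidation,
  regenerating the SRB electron acceptor) or sulfide + photon → S⁰ + 1 ATP
  (partial); acetate + 1 ATP → 2 carbon-precursor (Pfor/Pepc lumped); CO₂ +
  4 ATP → 1 precursor (reductive TCA lumped); H⁺ + photon → 0.6 ATP;
  biomass = 2 precursor + 9 ATP + NH₄ + Pᵢ.

Every guild carries a non-growth ATP maintenance flux proportional to its
abundance (SRB 1, MET 1, SOB 2 mmol ATP g⁻¹ h⁻¹). Elemental compositions
track carbon and sulfur, so the validator proves all internal reactions
balanced and the tests verify community-level carbon bookkeeping (C in as
butyrate + acetate = C out as CH₄ + CO₂ + formate + biomass carbon to
1e-6).

Exchange-capacity presets are the full-scale study's fitted values: SOB
acetate lower bound −1.50, MET acetate upper bound −11.55 (a *minimum*
consumption: the guild must draw at least 11.55·X, which caps how large the
methanogen compartment can grow on a given acetate surplus), SRB sulfide
upper bound 6.28, and ±1×10⁻⁵ proton caps for SRB and MET so protons
accrue to the sulfide oxidizers.

The default low-loading condition grants butyrate 1.51 and acetate 1.17
mmol g⁻¹ h⁻¹ (C4/C2 = 1.29), sulfate 0.10, sulfide 0.05, H⁺ 4.21×10⁻⁴;
products (CH₄, CO₂, H₂, formate, S⁰) may leave freely; photons, water,
phosphate and ammonium exchange freely. The high-loading condition applies
the seasonal fold changes ×1.56/×1.30. The absolute loading level and the
guild energy costs were chosen together, once, so that the default
community sits in the empirically observed regime: sulfide-oxidizer
dominance with the sulfate reducers smallest at low loading, methanogen
dominance at high loading, and a methanogen takeover at roughly +30%
butyrate above the low-loading point — driven by the same mechanism as in
the full-scale system (the sulfide-secretion capacity 6.28·X_SRB saturates
early in the sweep, pinning the sulfide oxidizers' energy supply while the
acetate surplus keeps growing).

Synthetic observations multiply the solver abundances by log-normal noise
(default relative spread 0.05) and renormalize to X₀; the seed fully
determines the table.

What the toy does *not* show: quantitative agreement with the full
genome-scale community model. Its acetate MET:SOB consumption ratios
(≈ 24–36) exaggerate the full-scale values, the sulfide-oxidizer acetate
capacity is inactive at default growth rates (hence unidentifiable from
toy abundances), the proton sweep improves the sulfide oxidizers gradually
rather than through a sharp methanogen collapse, and the capacity scan's
loading tolerance saturates near +38% because the methanogen abundance
ceiling (surplus / 11.55) bounds the transition point. Passing tests on
the toy therefore validate the machinery and the mechanism, not the
full-scale numbers.

## Numerical choices

* μ bisection tolerance 1e-6 h⁻¹ (1e-5 in scans and fitting, which trade
  a μ digit for ~40% fewer LP iterations); feasibility margin 1e-9 on ΣX.
* Capacity bounds default to ±1000 mmol g⁻¹ h⁻¹ when a loaded SBML reaction
  has none (constraint-based-modeling convention, with a parser warning).
* Zero-flux threshold 1e-6 mmol g⁻¹ h⁻¹ (reported fluxes below it are
  exact zeros after parsimonious resolution).
* Grid-fit ties: first point in row-major scan order.
* Degenerate inputs: constant series normalize to zeros with a flag;
  percent error is refused for zero observed abundances; exchange ratios
  with sub-threshold denominators return a flagged infinity.
* Problem sizes: the test suite and the acceptance script use the 74-
  reaction synthetic community, 13–25-point sweeps, 5×5 capacity grids and
  20 noise replicates; the μ-grid oracle uses step 1e-4 from below.

## Known limitations

* No flux variability analysis, loop-law solving, or dynamic (time-course)
  extension; abundances at μ\* can be degenerate in principle and are then
  backend-determined.
* The structural checks against the published full-scale community SBML
  (model size 3,535 reactions; 62 exchange metabolites shared by ≥ 2
  guilds, 26 by all three; fitted capacities −1.50 / −11.55 / 6.28) require
  that file at `data/mmgem.sbml`; it is distributed via the
  KMUTT-CASB/mmGEM repository and is not bundled here. The corresponding
  acceptance test fails in its absence rather than silently skipping.
* Sulfide speciation (H₂S/HS⁻) and pH chemistry are out of scope; the
  proton sweep manipulates a transport bound, not a pH equilibrium.
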