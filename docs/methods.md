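# Methods

This package simulates, designs, and evaluates hydrogel-encapsulated
anaerobic treatment systems for high-strength brewery wastewater
(50 m³·d⁻¹; 6760 mg·L⁻¹ total COD, 5640 mg·L⁻¹ soluble COD), benchmarks
them against a UASB, and maps which design decisions and technological
parameters drive the levelized cost (LC, USD·tonne⁻¹ COD removed) and
carbon intensity (CI, kg CO₂eq·tonne⁻¹ COD removed) of treatment.

## Process model

### Biokinetics

The biochemical core is the standard ADM1 component set (12 soluble and 12
particulate species plus a strong-ion pair) and its 19 processes:
first-order disintegration of composites, hydrolysis of carbohydrates,
proteins and lipids, Monod uptake of sugars, amino acids, LCFA, valerate,
butyrate, propionate, acetate and hydrogen by seven biomass guilds, and
first-order guild decay back to composites. Inhibition follows the common
formulation: lower-pH exponential switches, non-competitive dissolved-H₂
inhibition of the acetogenic steps, free-ammonia inhibition of acetoclastic
methanogenesis, and inorganic-nitrogen limitation of all growth.

The stoichiometric matrix is assembled programmatically. After the
COD-carrying coefficients of a process column are set, the inorganic-carbon
and inorganic-nitrogen coefficients are solved from the elemental contents
of every component, so COD, C, and N balance to machine precision in every
column — this invariant is asserted in the test suite and is what makes the
reactor-scale COD closure checks meaningful.

pH is closed algebraically at every evaluation point (DAE-free): the charge
balance with acid–base speciation of the VFAs, bicarbonate, ammonium and
water is strictly monotone in the proton concentration, so the root is
unique; a damped Newton iteration (vectorized across all bulk and shell
locations, warm-started between integrator calls) solves it to ~1e-12. The
warm start changes only the iteration count, never the root.

Gas–liquid transfer of H₂, CH₄ and CO₂ uses Henry's-law driving forces
(van 't Hoff temperature corrections) with a single kLa. Headspace states
evolve dynamically; the gas outflow uses the ideal-pressure form, which
keeps the headspace near 1 atm and makes the steady-state gas COD flux
exactly equal the liquid-side transfer flux (used by the closure checks).

Rate constants are referenced to 35 °C and scaled by a configurable
exponential temperature factor (default θ = 0.07 K⁻¹) between the ambient
(22 °C) and mesophilic (35 °C) operating points in the decision space.

### Influent fractionation

Only the COD totals of the influent are measurements. The soluble pool is
split across sugars, amino acids, LCFA, VFAs and a small soluble-inert
residue by configurable weights (defaults chosen as a plausible brewery
profile: 50% sugars, 20% amino acids, 12% acetate, the rest minor); all
particulate COD enters as composite. Inorganic N, C, and the strong-ion
pair default to values giving a realistic buffered pH (~6.8–7) in a
methanogenic reactor; all are configuration inputs.

### Bead model

Beads are monodisperse spheres discretized into concentric shells (uniform
radial grid, default 30 shells; reduced presets use 3–5). Transport is a
conservative finite-volume scheme: zero flux at the center and the surface
concentration clamped to the bulk — no external film, because the single
exposed transport parameter is the internal bead-to-water diffusivity
ratio, applied uniformly to all solutes. Particulates do not diffuse;
encapsulated biomass is immobile. The scheme reproduces the closed-form
first-order effectiveness factor η(φ) = 3(φ coth φ − 1)/φ² within 1% at 50
shells across φ ∈ {0.1, 1, 3, 10}, converging with second-order behavior.

The encapsulation capacity cap limits the **total particulate solids** a
shell of matrix can hold (live guilds plus decay residue); without
including the residue, inert decay products would accumulate in the gel
without bound and no steady state would exist. Growth beyond the cap is
exported to the bulk ("sloughing", retaining species proportions) — chosen
over growth arrest because it keeps the COD books closed and lets the
effluent carry the excess biomass. In the ODEs the cap is enforced by a
continuous first-order relaxation (default 50 d⁻¹), which holds capped
shells within a few tenths of a percent of the cap at realistic growth
rates; a discrete projection operator is also provided.

### Reactors and flowsheets

Fluidized- and packed-bed stages are bulk CSTRs exchanging with the bead
population through surface flux × interfacial area (6φ/d); the two types
differ in bead volume fraction (a decision in 0.03–0.40 for fluidized
beds; 1 − voidage ≈ 0.55–0.65 for packed beds) and in their
energy/costing models. The UASB benchmark is a suspended-growth CSTR whose
solids retention is decoupled from the hydraulic retention by a
three-phase-separator retention factor (SRT = HRT × RF, default RF = 50, a
placeholder); its effluent carries 1/RF of the in-reactor particulates. The
washout boundary of a single-guild reduction of this model matches the
analytic chemostat criterion within 2%.

HRT is defined on the working volume (beads included), which makes the
organic loading OLR = COD_in/HRT span the study's 1.36–40.6
kg-COD·m⁻³·d⁻¹ range between 5-day and 4-hour HRTs. Two-stage systems
chain stage-1 effluent into stage 2 with a default 1:3 HRT split
(configurable; the split is a free assumption) and stage-specific seeds:
fermenter-rich stage 1, methanogen-rich stage 2, balanced single-stage.
Active H₂ extraction (vacuum at 0.1/0.4 bar, or sidestream membrane at
recirculation ratio 1/50) is modeled as an enhanced first-order dissolved-H₂
stripping term on the first stage with configurable coefficients (the
device-level models are not public; interfaces are preserved), with the
extracted H₂ routed to the recovered gas stream.

Steady state: the packed state vector (bulk + headspace + shells, per
stage) is integrated with BDF (structural Jacobian sparsity, vectorized
right-hand side) and accepted when the relative derivative norm
max |dC/dt|/(|C| + 10⁻³) falls below tolerance (default 10⁻⁶ d⁻¹; reduced
presets 10⁻³–5·10⁻³). The 10⁻³ floor in the denominator keeps trace
species (dissolved H₂ ~10⁻⁷ kg·m⁻³) from dominating the test with
physically meaningless relative rates. Unconverged runs are flagged, never
silently reported. Converged scenarios close the COD balance (influent =
effluent + gas COD, with CH₄ at 64 and H₂ at 16 g-COD·mol⁻¹) to well
within 0.5%.

Beads are seeded at 20 kg-COD·m⁻³ (a dense manufactured inoculum, placing
the initial state near colonized operation); sterile systems remove ~0%
COD, as asserted in the tests.

## Design and costing

Vessels are cylinders (aspect ratio 1.5, 15% headspace) in concrete with
rockwool insulation and a carbon-steel facing; the UASB adds a stainless
three-phase separator sized on the cross-section. Encapsulant inventory is
working volume × bead fraction × bead density, replaced in whole batches:
ceil(project years / bead lifetime) batches over the 30-year project (30
batches at 1-year lifetime, 3 at 10, 1 at 30). Fluidization power uses the
Wen–Yu minimum-fluidization correlation with a 1.3 velocity margin and the
buoyant bed weight as head; packed-bed circulation uses the Ergun pressure
gradient; heating duty is ρc_pQΔT(1 − HX effectiveness) with a boiler
efficiency for the gas-equivalent demand.

All cost coefficients live in `src/anaerobead/data/cost_curves.csv`
(power-law installed-cost curves) and `prices.yaml`; **every number there
is a documented placeholder** standing in for vendor- and database-grade
coefficients this package does not bundle, so absolute LC/CI levels are
indicative, while comparative and sensitivity results (which decision
dominates, how indicators scale) are the intended outputs. Wall
thicknesses, piping runs, pump efficiencies (0.7/0.65) and the headspace
fraction are likewise editable defaults reported in run metadata.

## TEA and LCA

LC is the negative annualized net present value divided by annual COD
removal: cash flows (construction at year 0, equipment and membrane
replacements at their lifetimes, encapsulant batches at each lifetime
interval, annual O&M, biogas revenue) are discounted at 5% over 30 years
and annualized by the capital recovery factor (CRF(5%, 30 yr) = 0.06505).
The implementation agrees with a brute-force year-by-year NPV oracle to
1e-10. Contributions are computed per source group from group-wise
schedules, so the breakdown sums to the net LC exactly.

CI is the GWP100-characterized inventory per tonne COD removed: material
and equipment flows amortized over replacement lifetimes, annual
electricity and heat, fugitive CH₄ (effluent dissolved CH₄ — recovered at
85% by the optional degassing membrane — plus a 2% biogas collection
leak), and recovered biogas credited as avoided natural gas (LHV basis:
50 MJ·kg⁻¹ CH₄, 120 MJ·kg⁻¹ H₂). Characterization factors are bundled
editable stand-ins in `impact_factors.csv` (ecoinvent is licensed); the
grid-electricity factor (0.4405 kg CO₂eq·kWh⁻¹) is derived from the
published aerobic-treatment benchmark conversion (0.79 kWh·kg⁻¹ COD ↔ 348
kg CO₂eq·tonne⁻¹), the natural-gas offset uses a well-to-gate supply-chain
factor, and CH₄ carries GWP100 = 28 (configurable). Outputs carry the
factor-table checksum. All nine TRACI-style categories are supported
generically by the table; only GWP100 ships with defaults. Project
end-of-life is excluded.

When a scenario removes (essentially) no COD, the functional-unit
denominator is floored at 0.5% of the influent load so indicators stay
finite inside optimizers; the flag is recorded in metadata.

## The three analysis stages

**Stage I** enumerates the discrete decision space — reactor type (UASB,
packed, fluidized), stages (1/2), H₂ extraction (passive for single-stage;
passive/vacuum 0.1/vacuum 0.4/membrane r=1/membrane r=50 for two-stage),
effluent degassing, temperature (22/35 °C), HRT (1/2/4/12 d), bead
diameter (2/5/10 mm), bead lifetime (1/10/30 yr), and fluidized bead
volume fraction (0.10/0.25/0.40) — yielding exactly 3552 scenarios (96
UASB-only), verified against an independent counting formula. Restricting
active H₂ extraction to two-stage systems is the reconstruction that
reproduces this count. Relative impacts ΔY are indicator differences
between baseline–alternative pairs differing in one decision (matching on
every decision applicable to both), normalized by the indicator range over
the whole enumeration; |ΔY| ≤ 1 and antisymmetry are property-tested.

**Stage II** draws a Latin hypercube sample (full scale N = 1000; reduced
presets N = 30–50) over an 18-parameter space per reactor type — six ADM1
kinetic parameters (k_dis, k_hyd_ch, k_m_ac, K_S_ac, k_m_pro, k_m_h2; the
published list names only the first three, the rest are this package's
choice of the remaining high-leverage uptake constants), the HRT decision,
and type-specific technological parameters (bead geometry/lifetime/
diffusivity/capacity/density and encapsulant prices for encapsulated
systems; retention factor, kLa, inoculum, alkalinity for the UASB).
Decision variables are uniform; technological parameters use triangular or
log-uniform families. Samples are stratified exactly (one draw per
equal-probability stratum per dimension) and a shared matrix supports
paired cross-reactor comparisons. Monte Carlo filtering splits samples at
the top-25% quantile of each of five indicators (rCOD, LC and CI with and
without degassing) and runs two-sample KS tests per parameter (exact ECDF
statistic; asymptotic p at effective size n_a·n_b/(n_a+n_b), uncorrected
across the grid — a multiplicity note is emitted in metadata). Under a
null indicator the p < 0.05 rate calibrates to 0.05 ± 0.02.

**Stage III** maps, for each encapsulated reactor type, a 2-D grid over
its two key technological parameters (bead lifetime × k_m_ac for fluidized
beds; bead lifetime × diffusivity ratio for packed beds; full-scale grid
12×15 = 180 points) with 1 mm beads and, for packed beds, loose packing
(voidage 0.45). At each grid point the decision variables (HRT ∈ [1 h,
5 d]; fluidized bead volume fraction ∈ [0.03, 0.25]) are optimized to
minimize CI (with effluent degassing, the CI-favoring configuration). The
optimizer is a seeded Latin-hypercube pre-screen of the decision box
followed by bounded Powell polishes from the best screen points, returning
the best evaluation ever made (a budget-limited line search can end away
from its best visited point); it is deterministic under a fixed seed,
flags nonconvergence, and beats 20 random feasible draws at every grid
point of the reduced test map.

## Problem sizes and numerical presets

Three presets trade radial resolution and integration horizon for speed:
`default` (30 shells, 3000 d horizon, tol 1e-6 d⁻¹), `fast` (5 shells,
1500 d, 1e-3), and `tiny` (3 shells, 1000 d, 5e-3). The bundled analysis
scripts and the test suite run the reduced presets and reduced scales
(50-scenario enumerations, N = 24–50 Monte Carlo, 3×3–4×4 grids); the
full-scale runs (3552 scenarios, N = 1000, 180-point grids) are the same
one-command entry points with different flags. Shell-count refinement
changes steady fluxes with second-order-like convergence, so the tiny
preset biases absolute rCOD by at most a few tenths of a percent relative
to the fast preset — small against the decision-to-decision differences
the stages rank.

## What the synthetic conditions do and do not show

The generator reproduces the study conditions (influent flow and COD
split, option sets, parameter ranges) with plausible documented defaults
wherever a coefficient is not publicly fixed. Passing tests
therefore demonstrate internal correctness (conservation, closed forms,
oracles, calibration) and faithful reproduction of the study's structural
numbers — not predictive accuracy for a real brewery system: the ADM1 is
uncalibrated to the study's batch experiments, costs and factors are
placeholders, and the influent is steady (no dynamic variability, by
scope). Published Monte Carlo medians that depend on the non-public cost
coefficients and licensed inventory data are out of reach by construction
and are not claimed.

## Known limitations

- No sulfur or precipitation chemistry; no bead swelling/degradation
  dynamics (lifetime acts only through the replacement schedule).
- The UASB hydrodynamic treatment is a single retention factor.
- H₂-extraction device models are first-order stand-ins.
- The slough-overflow capacity mechanism is a modeling decision
  (vs growth arrest) and is flagged as sensitivity-worthy.
- Acid-base constants are not temperature-corrected (Henry constants and
  rate constants are).
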