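# Methods

## Scope and shape

The package has two halves. The *controller* half (model_core, fba_engine,
uptake_kinetics, mmc_controller, ledger_io) implements metabolic model
control: OD-based growth estimation, growth-pinned uptake minimization, and
flux-to-mass feed conversion. The *test-bed* half (culture_sim) is a virtual
culture that deliberately does **not** share the controller's model class: the
controller reasons with steady-state FBA, the culture runs a dynamic
nitrogen-quota model. Closed-loop tests therefore probe the controller against
dynamics it does not assume, not against a mirror of itself.

## The FBA layer

A model is a stoichiometric matrix S (metabolites × reactions), per-reaction
flux bounds, a tagged biomass reaction (flux in h⁻¹, column normalized to
1 gDW), and a nutrient→uptake-reaction map. LPs (`optimize c·v, S·v = 0,
lb ≤ v ≤ ub`) are solved with scipy's HiGHS. Numerical conventions:

- steady state is accepted at ‖S·v‖∞ < 1e-7; bound violations at 1e-9;
- pinning growth uses an equality (lb = ub = μ); `growth_tolerance` widens the
  upper bound to μ(1+ε) for brittle genome-scale models;
- in lexicographic minimization each stage's optimum is fixed within ±1e-9
  before the next stage, so earlier optima cannot be degraded;
- only objective *values* feed the controller. Alternate optimal flux vectors
  are left degenerate on purpose: the minimized uptake value is unique even
  when the flux vector is not, and nothing downstream reads other fluxes
  (hence no parsimonious-FBA step);
- infeasible growth-pinned solves report the maximum achievable growth in
  `meta["max_growth"]`; the controller then re-solves at that capped rate
  (`feasible_growth`) rather than failing the feed.

## The toy network

Genome-scale models have thousands of reactions; the controller only ever
reads two numbers from a solve (growth flux, uptake flux), so a desk-scale
network that makes those numbers composition-dependent is enough for exact
testing. `build_toy_model` emits ~19 reactions: uptakes for nitrate, glucose,
acetate (closed by default, a substitutable carbon source for lexicographic
tests), a recycled-N pool (closed by default), photons and CO₂; N assimilation
(1 N-unit per nitrate); glucose catabolism (6 C-units + 2 energy units per
glucose); CO₂ fixation (1 C + costs 1 E); photon capture (1 E); an energy
dissipation sink whose lower bound doubles as non-growth maintenance (default
0); one synthesis reaction per macromolecule class; and a biomass reaction
consuming the macromolecule pools in their mass fractions. Autotrophic
variants close glucose; heterotrophic variants close photons *and* CO₂ (dark
growth, no net fixation of CO₂ with glucose-derived energy).

Elemental bookkeeping uses abstract N-units and C-units carried as per-
metabolite formulas; `validate_mass_balance` checks every internal column
balances exactly, exempting exchange and biomass columns. By construction the
biomass nitrogen demand is Σ_m f_m·n_m and the carbon demand Σ_m f_m·c_m, so
minimized nitrate at growth μ is exactly (Σ f·n)·μ when nitrate is the sole N
source — the closed forms the unit tests lean on.

## Biomass compositions

A composition is mass fractions over six macromolecule classes (amino acids,
carbohydrate, lipid, chlorophyll, nucleotide, other; sum to 1 within 1e-9)
plus per-class nitrogen and carbon contents (mmol/g). Editing the amino-acid
fraction to a target rescales the other classes by (1−target)/(1−old) and
rebuilds the biomass stoichiometry; the edit is involutive to round-off.

The shipped default vectors are **representative config values, not
measurements**: a nitrogen-replete autotrophic cell (45% amino acid), a
replete heterotrophic cell (42%), and a nitrogen-starved cell (16% amino
acid, 40% lipid) from which the 10%- and 2%-amino-acid rationing variants are
derived. Protein nitrogen content is 11.1 mmol N/g (≈16% N by mass); nucleic
acid 10.7; chlorophyll 4.5. Anyone with measured composition vectors should
supply their own `BiomassComposition`. Composition editing rebuilds only
toy-built networks; genome-scale biomass columns cannot be reconstructed from
six mass fractions, so editing an SBML-loaded variant raises.

## Feed conversion

Flux → mass integrates F·MW·X(t) over the interval with X(t) = X₀e^{μt}:
mass = F·MW·X₀·(e^{μΔt}−1)/μ, switching to the μ→0 limit F·MW·X₀·Δt below
|μ| < 1e-9 to avoid cancellation. Exponential biomass is the minimal
assumption consistent with having pinned the model to grow at μ; a
constant-biomass alternative is available (`biomass_model="constant"`).
Negative estimated growth feeds nothing by default (cultures are never fed
for shrinking) and flags the prediction. Feed volume changes are ignored:
feeds model concentrated stock additions (tens of g/L), negligible next to
culture volume.

Defaults: nitrate MW 62.00 mg/mmol, glucose 180.16; OD₇₅₀ → dry weight
0.4 gDW·L⁻¹ per OD unit (approximate, from pairing OD ≈ 1.3 with ~0.52 g/L
dry biomass; override per instrument and strain).

## The glucose uptake cap

At high cell density, measured glucose consumption falls below growth-pinned
model demand. The cap is an ordinary least-squares polynomial (default degree
2 — the lowest degree that can represent saturation followed by decline) in
either the time-integrated biomass (default, matching how such curves are
constructed from cumulative data) or instantaneous biomass concentration; the
axis choice travels with the fitted object. Evaluation clips at zero, and
applying a cap never *raises* the existing uptake bound. R² is 1 − SS_res/SS_tot.
When a cap makes the estimated growth infeasible, the controller caps growth
at the model's maximum under the bound — this is the mechanism by which the
cap "restricts both the growth rate prediction and the glucose uptake rate".

## The virtual culture

A discrete-time quota model, chosen over a dynamic-FBA culture because the
phenomena the controller must survive — luxury uptake into storage, growth
continuing after medium exhaustion, over-feeding being absorbed without
growth benefit — are storage phenomena that steady-state FBA cannot express.

State: biomass X, medium nitrate and glucose pools, protein fraction p. The
internal quota q (mmol N/gDW) maps linearly to p via the replete point
(p = p_target·q/q_target, i.e. all cellular N pools scale together). Per step
(default dt = 0.5 h, small enough that the replete-growth discretization is
exact because uptake precedes growth):

1. feeds enter the pools;
2. nitrate uptake = min(pool, vmax_N·X·dt, storage headroom up to
   q_max = 1.1·q_target) — uptake, not growth demand, empties the medium,
   reproducing near-zero measured nitrate between feeds even when over-fed;
3. growth at μ = mu_max · ramp(q) · [glucose limitation], where ramp(q) is 0
   below q_min (the ~10%-protein cessation threshold), rises linearly, and
   saturates at 0.95·q_target. Under heterotrophy growth is further limited
   by the glucose pool, vmax_G, and the optional polynomial uptake cap;
4. growth dilutes the quota (cellular N is conserved exactly; per-step
   nutrient balance pool_out = pool_in + feed − uptake holds to 1e-9).

The ramp floor (zero at 0.8·q_min) makes starving cultures keep creeping
until the quota actually crosses q_min, so the protein fraction genuinely
crosses 10% and growth then stops for good — the starvation plateau. The
saturation point at 0.95·q_target encodes that cells a few percent below
replete quota already grow measurably slower: this is what makes chronic
80%-of-requirement feeding visibly costly within a ~6-day run while exact
feeding holds full speed, the qualitative fingerprint the closed loop must
reproduce. Both shape factors are parameters (`q_floor_frac`, `q_sat_frac`).

Defaults: mu_max 0.0137 h⁻¹ (the reference autotrophic rate), Y_N = 1/5.665
gDW per mmol nitrate so the virtual cell's replete demand matches the default
controller composition (the "matched model" condition), p_target 0.45,
p_min 0.10, Y_G 0.09 gDW per mmol glucose, vmax_N 0.5 and vmax_G 2.0
mmol·gDW⁻¹·h⁻¹.

Observation noise is kept out of the dynamics: `generate_observations` adds
multiplicative lognormal noise to OD and relative truncated-normal noise to
concentrations, seeded explicitly. What passing closed-loop tests show is
that the control *logic* is sound against quota dynamics under stated noise;
they do not show robustness to real-culture effects the simulator omits —
light gradients and self-shading, pH and O₂ transfer, composition drift
beyond the protein axis, volume changes, or measurement outliers.

## Closed-loop study conditions

The standard autotrophic experiment: X₀ = 0.1 gDW/L, 25 mg/L initial nitrate
charge, feeds every 24 h from t = 24 h, 144 h horizon, compared against a
single 285 mg/L bulk charge; feed scaling 0.8/1.0/1.2. The rationing
experiment: 549 h, no nitrate charge, feeds predicted by the 10%-amino-acid
variant, against an unfed starvation culture. These sizes keep every
simulation in the sub-second range while leaving all regimes (replete,
quota-diluting, post-cessation) represented.

## Accounting

Ledger totals use compensated summation and are exact; totals are reported
both with and without the initial medium charge, since "total supply" is
genuinely ambiguous between the two conventions. Percentage helpers return
unrounded values; reporting rounds to integer percent. The average-feed-rate
helper divides the mass fed in a window by its duration and reports unrounded
(note 36 mg/L over 549 h is 0.0656 mg·L⁻¹·h⁻¹, which rounds to 0.07, not the
colloquial 0.06 — the package reports the unrounded number).

## Known limitations

- The toy network's energetics are schematic (free photon supply, fixed
  glucose energy yield, zero default maintenance); it is a harness for the
  controller, not a metabolic reconstruction.
- SBML support reads FBC-style bounds via cobrapy and auto-detects the
  biomass reaction from the objective; models encoding bounds only in legacy
  kinetic-law parameters are not parsed.
- The uptake-cap regression is phenomenological; it does not distinguish
  transporter saturation from oxygen limitation, and its coefficients are
  instrument- and culture-specific.
- The quota model tracks a single internal pool (nitrogen); carbon storage
  (starch/lipid partitioning) is not modeled, so product yields are outside
  the simulator's scope and handled only as ledger bookkeeping.
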