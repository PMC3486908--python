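# Methods

## Model structure

### Whole-body scale

The PBPK engine represents a body as lumped, well-stirred compartments
(default scaffold: venous blood 3.9 L, arterial blood 1.8 L, liver 2.1 L,
kidney 1.5 L, rest-of-body 35 L, optional gut lumen 1 L) connected by blood
flows (cardiac output 5 L/min, hepatic 1.5, renal 1.2, rest 2.3).  The
kidney box is deliberately larger than the anatomical organ: it lumps the
kidney with its immediate perfusion bed, which keeps the fastest local rate
constant within the stability region of the fixed-step explicit integrator
at the 1-minute coupling interval (see *Numerics*).  Sub-space subdivision
(vascular/interstitial/intracellular) is supported by the types but the
bundled fixtures use one box per organ; a full sub-compartmentalized body
is out of scope.

Distribution is perfusion-limited: a compartment presents the effective
concentration `C/K` to its outflows, where `K` is the species' tissue
partition coefficient (1 for blood).  Partition coefficients are
user-supplied parameters; predicting them from compound physicochemistry is
a non-goal.  Kinetic processes are first-order (`k·A`), Michaelis–Menten
(`Vmax·C/(Km+C)·V`), zero-order production (`rate·V`) and first-order oral
absorption from the gut lumen.  Clearance processes may declare metabolite
products (`link_metabolite` chains a parent clearance into a metabolite's
formation at a molar yield).

**Units** are fixed package-wide: minutes, liters, µmol, µM; volumetric
rates (production, Vmax, network fluxes) in µmol/L/min normalized to the
volume of the hosting compartment.

### Rate normalization and `volume_basis`

The literature rates the fixtures reproduce (ammonia production 0.694,
hepatic/renal elimination 0.163/0.530 µmol/L/min) are mutually consistent
as *ratios* and as per-liter values, but their absolute scale cannot be
mapped onto physiologic organ volumes: taking them per liter of liver
tissue would require hepatic extraction beyond what hepatic blood flow can
deliver.  hepaflux therefore treats such rates as normalized to a single
whole-body reference volume `V_REF` (the scaffold's non-lumen volume,
44.3 L), and the `DirectLink.volume_basis` field carries the conversion
between a network flux (µmol/L/min) and a PBPK amount rate (µmol/min)
explicitly.  The ammonia fixtures use `volume_basis = V_REF` on both sides,
which preserves every reported ratio and steady state.

### Cellular scale

A metabolic network is a stoichiometric matrix with per-reaction bounds,
loaded from a plain-text reaction-table TSV (`reaction_id  equation  lb  ub
notes`, equations like `2 nh3[c] + co2[c] -> urea[c]`, one-sided equations
being exchange reactions) or from SBML through cobra.  Inhibitable enzyme
activities are declared as tags in the notes column (`tag=XO`); one
activity may span several reactions (xanthine oxidase catalyzes both
oxidation steps of the purine chain), and an inhibitor link caps every
tagged reaction against its own reference flux.

FBA maximizes a linear objective subject to `S·v = 0` and bounds
(scipy linprog, HiGHS).  Because such optima are usually degenerate, a
second stage fixes the objective at its optimum and minimizes `Σ|v|` via
flux splitting.  This parsimonious selection is what makes flux vectors
reproducible across solver runs and reaction orderings — a precondition for
classifying flux changes between reference and perturbed solutions.
Feasibility tolerance is 1e-9; reported fluxes are rounded at 1e-10 to
suppress solver noise.  Element-balance checking is advisory (the toy
networks are nitrogen-balanced by construction; genome-scale
reconstructions contain lumped pseudo-reactions).

## Coupling

### Indirect (regulatory, feed-forward)

Enzyme inhibition uses competitive Michaelis–Menten algebra with the
substrate-at-Km convention: `relE(I) = 1/(1 + I/IC50)`, equivalently
`1/(1 + I/(2·Ki))` with `Ki = IC50/2` (Cheng–Prusoff at S = Km).  This
choice makes `relE(IC50) = 0.5`, is monotone and continuous, and is the
natural reading when only IC50s are published; a noncompetitive variant
sits behind `inhibition_mode="noncompetitive"`.  Several inhibitors of one
activity combine same-site competitively:
`relE = 1/(1 + Σ Iᵢ/IC50ᵢ)` (a drug and its active metabolite are purine
analogs acting at one site; the combination rule is a package choice).

The inhibitor concentration `I(t)` is the PBPK tissue concentration of the
linked species in the linked compartment (the lumped liver box standing in
for the intracellular space).  The constraint applied to the network is a
*magnitude cap* `|v| ≤ relE·|v₀|` intersected with the reaction's own
bounds, preserving the sign of `v₀` — not an equality, which could render
unrelated objectives infeasible.  `v₀` is taken from the reference solution
of the active objective, recomputed per objective, since a flux through an
enzyme depends on what the cell is asked to maximize.  When no measured
IC50 exists, `calibrate_ki_to_max_inhibition` inverts the rate law so the
peak inhibitor concentration of a worst-case exposure produces a stated
maximal activity loss.

### Direct (mass exchange, feed-back)

`dfba_step` implements the five-step loop: (1) evaluate the PBPK kinetic
rates of every linked process at the current state; (2) offer them (divided
by `volume_basis`) as upper bounds on the linked exchange reactions, and
apply all indirect caps; (3) solve the two-stage FBA; (4) replace the
linked PBPK process rates with the FBA exchange fluxes (times
`volume_basis`); (5) integrate the whole-body model one interval with those
rates held constant.  Holding fluxes piecewise constant is the dFBA
assumption that cellular re-equilibration is fast relative to whole-body
distribution; the default interval is 1 min.  An infeasible FBA (e.g. at
near-zero substrate, where obligatory demands exceed the offered uptake)
falls back to zero linked rates for that step and is counted and logged —
it is a boundary condition of the discretization, not an error.

### Scheduler, events, memoization

`simulate_coupled` iterates the loop, applies timed events (bound changes,
capacity upregulation) that snap to the coupling grid, and records
synchronized concentration and flux series plus relE time courses.  Two
performance measures keep desk-scale runs fast without changing results
beyond stated tolerances:

* LP solutions are cached on the quantized constraint set; relE values are
  quantized at 1e-4 (far below every physiological tolerance in the
  package) so near-identical inhibition states share one solution.
* A solution is reused without re-solving when only direct-link exchange
  bounds moved and the previous solution retains strict slack in both the
  old and the new bound.  For the uptake-maximizing objectives used here
  the optimum is `min(offered bound, internal capacity)`, so a non-binding
  availability bound cannot affect it.  `reuse_slack_solutions=False`
  disables this and re-solves every step; a test asserts both paths give
  identical trajectories on a ramping-inhibition scenario.

## Numerics

Integration is fixed-step explicit RK4 on the coupling grid.  A fixed step
is required because linked rates are piecewise constant per interval; the
removal of a linked amount over a step is then *exactly*
`flux·volume_basis·dt` (asserted per step in tests).  Each compiled model
derives its fastest local rate constant (flow/volume plus first-order and
Vmax/Km terms) and sub-steps automatically so `dt/sub_steps` stays inside
the RK4 stability region; halving `dt` changes fixture endpoints by well
under 0.5 %.  Amounts are clipped at zero with a logged warning when a
discretized clearance overshoots near-empty compartments.  Dose events
inject at the start of the step containing their scheduled time.

Steady states are detected on a 60-minute window (relative concentration
change below `tol`); non-convergence returns a flagged result rather than
raising.  For purely linear, dose-free models `linear_steady_state` solves
the balance system directly and is verified against the windowed detector.
Calibration is deterministic local least squares (`scipy least_squares`) on
relative residuals from the model's current parameter values; a flat
Jacobian direction triggers an identifiability warning.

## Fixtures and case studies

### Ammonia / urea-cycle disorder

The toy detoxification network routes ammonia nitrogen into urea
(`2 nh3 + co2 -> urea`, carrying the OTC tag), glutamine (2 N: the amide
plus the amine of de-novo glutamate via GDH) and alanine (1 N), so
`uptake = 2·urea + 2·gln + ala`.  Glutamine and alanine exports are fixed
demands at their caps (lb = ub): hepatic glutamine/alanine output is an
obligatory, capacity-limited liver function.  With pure upper bounds the
parsimonious optimum would route all nitrogen through urea and the reported
baseline partitioning (0.163 uptake = 2·0.0725 + 2·0.008 + 0.002) would be
unreachable; the demand form reproduces it exactly, as well as the
disease-state uptake 2·(4·0.008) + 4·0.002 = 0.072.  The baseline caps are
5 % and 1 % of baseline uptake in molar terms, rounded to 0.008 and 0.002.

The whole-body model fixes production at 0.694 µmol/L/min (V_REF basis) and
calibrates the hepatic/renal first-order constants to the healthy venous
target (29 µM) with the 13:4 renal:hepatic flux split, giving
0.163/0.531 µmol/L/min.  The network's uptake cap is the *rounded* printed
value 0.163, slightly below the calibrated 0.1633, so the coupled baseline
settles at 29.02 µM — the two-decimal steady state emerges from the
rounding of the hepatic rate, not from tuning.  The disease protocol ramps
OTC activity linearly to zero over 4 days starting at 24 h (the ramp length
is configurable; 4 days places the new steady state at about day 6.5) and
raises the glutamine/alanine demands fourfold 6 h after onset
(transcription/translation delay).  The new steady state follows the
balance `C_new ≈ C_base·(P − U_new)/(P − U_base)` and lands at 33.99 µM
(+17 %).

### Allopurinol / hyperuricemia

Urate production sits in the liver behind the purine-chain network
(hypoxanthine → xanthine → uric acid, both steps one XO activity);
renal clearance is calibrated so the healthy steady state is 302 µM and the
gouty state (identical production, reduced renal clearance — gout is
modeled purely as impaired excretion) is 476 µM.  Urate turnover is set to
a one-day half-life.  Allopurinol (oral, 200 mg once daily by default —
the dosing interval is configurable; the label dose is daily) is oxidized
by XO to oxypurinol (molar yield 1); both inhibit XO with the published
IC50s 13.4 and 15.6 µM.  Absorption and clearance constants are package
choices at literature-plausible half-lives (allopurinol ≈ 1.5 h, oxypurinol
≈ 20 h); consequently the absolute drug concentration curves are
qualitative, and the quantitative claims of this scenario are the
calibrated steady states, the percent reduction between them, parent
non-accumulation and metabolite accumulation.

### Paracetamol / overdose robustness

Paracetamol clears through saturable glucuronidation
(Vmax 38.5 µmol/L/min, Km 700 µM on the liver volume) and sulfation
(6.0, 200) plus linear CYP2E1 N-hydroxylation (k 0.010/min) producing
NAPQI; PG and PS are renally eliminated, NAPQI is conjugated in the liver
(k 0.034/min, an effective whole-body half-life of several hours).  These
constants are package choices giving a therapeutic half-life ≈ 2.5 h and
route shares ≈ 58/31/11 %; their purpose is the kinetic *signature* —
conjugation saturates at overdose, the NAPQI share grows more than
proportionally with dose, and after 15 g the parent persists long enough
that NAPQI is still high at 24 h.  The AC conjugate is not modeled
separately; its concentration is taken equal to NAPQI's.

Ki values for the four inhibited targets — THFDH, GDH, mitochondrial ATP
synthase, and the GSH-producing reactions (GSH depletion is represented
phenomenologically as inhibition of GSH synthesis, since stoichiometric
models carry no metabolite pool sizes) — are calibrated so the NAPQI peak
of the 15 g reference dose produces 25/25/60/80 % activity loss.  These
extents are read as *fraction of activity lost at peak* ("up to X %"); the
alternative reading (reduced *to* X %) can be expressed by passing a
different `max_inhibition` map.  The objective panel (12 export-maximization
tasks on a branched toy network with known tag dependencies) is evaluated
at t_max(paracetamol), t_max(NAPQI) and 24 h; affected means a relative
decrease beyond 1e-6 (the tolerance is part of every report, since on
genome-scale networks the unchanged-flux percentages are
tolerance-sensitive).

### Virtual population

Individuals are drawn by perturbing the production and the two clearance
constants independently with normal noise of 10 % relative SD, truncated at
zero by redraw, under a single seed.  Independence of the perturbations is
an assumption.  Healthy endpoints use the linear steady state of the
uncoupled model (the coupled model is equivalent when nothing is impaired);
diseased endpoints run the coupled model with the urea cycle blocked and
fourfold capacity from the healthy state for 36 h and require the last hour
to move < 0.1 % (endpoint = final steady-state value, not a time average;
non-converged individuals are excluded and counted).  The two-sample KS
test uses the exact ECDF supremum D and the asymptotic Kolmogorov
distribution at `sqrt(n_eff)·D`; a test cross-checks the p-value against a
10,000-permutation estimate (agreement within 0.005 at n = 100).

## What the toy fixtures do and do not show

The bundled networks are constructed so that printed exchange-rate
arithmetic is exact where the toy stoichiometry supports it (baseline and
UCD ammonia rates, XO chain scaling).  They do not reproduce genome-scale
behavior: a real hepatocyte reconstruction has internal nitrogen sinks
(its baseline urea export is 0.070 where the toy nitrogen balance gives
0.0725), its 67-objective panel and the published affected counts (20/24)
and unchanged-flux percentages (54.8 %/11.1 %) depend on that network and
its alternate-optima handling, and the printed diseased alanine rate
(0.007) reflects rounding of the baseline cap (4·0.002 = 0.008).  The toy
panel therefore supports *property-level* conclusions (dose monotonicity,
dependent-set recovery, rerouting, recovery at 24 h for the therapeutic
dose) rather than genome-scale counts.  The SBML import path exists for
users with a genome-scale reconstruction; it is not exercised at scale in
the test suite.

## Problem sizes and determinism

Default desk-scale runs: 21 simulated days at 1-min coupling for the UCD
endpoint (~30,000 LP-backed steps), 7–35 days for allopurinol dosing,
25 h for paracetamol PK, 100 + 100 individuals for the population
experiment.  All randomness (population draws, test noise) flows from
explicit seeds; simulations and calibrations are otherwise deterministic,
and repeated runs produce byte-identical CSV outputs.
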