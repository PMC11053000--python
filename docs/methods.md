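# Methods

## Model structure

The network couples 34 species across four stress axes. Each ordinary
species obeys

    dx/dt = [ b + Σ_a w_a H(s_a; K_a, n_a) ] · Π_i R(s_i; K_i, n_i) − d·x,

with `H(s; K, n) = s^n/(K^n + s^n)` for activators and
`R(s; K, n) = K^n/(K^n + s^n)` for inhibitors. All rates are per day;
first-order turnover is one per day for every species, so transients
settle within a few days and a 35-day intervention run is effectively
at steady state (verified to 0.5 % in the tests). The IRS/pIRS and
AKT/pAKT pairs are two-state phosphorylation pools: forward flux
`kph·H(driver)·unphosphorylated`, back flux `kdeph·phosphorylated`,
conserving each pool total exactly.

Signal flow: insulin → PI3K → pAKT → cytosolic FOXO1 → LPS → NF-κB →
{TNF-α, IL-6}; IL-6 → JAK1 → STAT3 → IL-10 ⊣ NF-κB (negative
feedback); KEAP1 ⊣ NRF2 → {SOD, CAT, GPx, GSH}; {SOD, GSH} ⊣ ROS →
{MDA, HIF-1α}; {HIF-1α, IL-6} → CRH → ACTH → cortisol; {TNF-α,
cortisol} → renin → Ang II → aldosterone. Two modelling choices are
load-bearing:

* **The LPS → NF-κB edge is an ultrasensitive switch (Hill n = 4,
  K = 2).** Under stress the edge operates near saturation; the
  combined intervention pushes LPS below the knee, where NF-κB output
  falls steeply. Individually weak potencies on the insulin axis
  (gotukola, acerola, B6, B12, magnesium, zinc, chromium each reduce
  pathological AKT phosphorylation by 15–27 %) barely move the switch
  alone but jointly cross the knee — this is the mechanistic origin of
  the formulation's synergy and of the wide gap between single and
  combined efficacies.
* **Cortisol drives renin (glucocorticoid hypertension).** Without
  this route, hypertension in individuals without inflammatory stress
  could neither be induced nor resolved by an intervention acting on
  the stress network. The TNF-α → renin response is cubic in TNF-α
  with a small healthy share, so blood pressure tracks severe
  inflammation but decouples from the residual post-intervention
  TNF-α tail.

SBP is not a species: it is a saturating map of aldosterone,
`SBP = 106 + 94·a²/(3² + a²)` mmHg, calibrated so the healthy tone
(a = 1) reads 115.4 mmHg and full stress ≈ 156 mmHg; the 106 mmHg
floor is the hemodynamic baseline of the map, and intervention
efficacy on SBP is defined on the excess above it (the mmHg scale has
an arbitrary zero for a stress read-out). DBP is reported as
0.65·SBP and not classified. PSS is a saturating map of cortisol,
`PSS = 40·c^1.38/(23.9^1.38 + c^1.38)`, placing the calibrated
stressed level (106.7 ng/mL) in the high band (~35.5) and the
post-intervention level (~8.5 ng/mL) near 7.7–9; it is rounded
half-up to the integer instrument scale for band classification.
Classification thresholds: oxidative if ROS production > 10 % over
baseline, physical if SBP > 120 mmHg, mental if PSS > 13, inflammatory
if TNF-α > 1.0 × 10⁻³ pg/mL on the model scale (the clinical 0–1.5
pg/mL serum band is retained as metadata only; the model-scale
threshold is placed clear of the bulk of the stressed distribution so
classification is stable under sampling).

## Stress induction and intervention

A stress scenario has three severities in [0, 1]. Inflammatory
severity scales the LPS → NF-κB weight by (1 + α·s); oxidative
severity scales KEAP1 production by (1 + β₁·s), divides SOD production
by (1 + β₂·s) and scales basal ROS generation by (1 + β₃·s); insulin
severity scales the IRS and AKT phosphorylation rates by (1 + γ·s).
The gains α, β, γ are calibrated constants stored with the parameters;
zero severity is the identity exactly.

An ingredient's potency p multiplies every rate feeding its target
node by (1 − p) (down) or (1 + p) (up). Because the scaling is
multiplicative per path and reduced in sorted order, composition is
exactly permutation-invariant. The shipped formulation has 4
botanicals, 13 vitamins and 11 minerals; target assignments follow the
ingredients' described pharmacology (botanicals on NF-κB/NRF2/ROS and
the AKT axis, vitamins A/D/E/K on NF-κB/TNF-α/IL-6, B vitamins and
magnesium/copper/molybdenum on the cortisol axis, minerals on the
antioxidant enzymes and ROS).

## Calibration

Free constants are fitted in deterministic stages
(`scripts/build_defaults.py`):

1. **Healthy state, by construction.** Each activating edge is
   specified by the fraction of its target's healthy production it
   carries; weights and basals are solved so the prescribed healthy
   state is an exact fixed point.
2. **Stress gains** (plus a handful of half-saturation constants and
   the CRH input weighting) to the stressed steady-state targets:
   ROS 171.92 %, TNF-α 2.2 × 10⁻³ pg/mL, cortisol 106.7 ng/mL, the
   aldosterone tone, the LPS operating point, and 27.5 ng/mL cortisol
   under oxidative-only stress (so the ROS → HIF-1α → CRH route alone
   carries a mental-stress signal). Bounded trust-region least squares;
   converges to residuals < 10⁻⁶.
3. **Single-ingredient potencies** by one-dimensional root finding to
   the printed efficacies (vitamin A 25 % and gotukola 11 % on TNF-α;
   gotukola 24 %, acerola 21 %, zinc 11 %, vitamin C 11 % on ROS;
   acerola 22 % on cortisol).
4. **Three group scalars** (inflammatory, cortisol, antioxidant arms
   of the remaining ingredients) to the combined-intervention steady
   state (ROS 5.58 %, cortisol within 2 % of 8.57 ng/mL, TNF-α
   4.1 × 10⁻⁵ pg/mL).
5. **Population distributions** (below) to the cohort-level outcomes.

The generic machinery (target tables, weighted relative-residual
objective, seeded multi-start Nelder–Mead) is in
`stressnet.calibration` and is exercised by a parameter-recovery test
(loss < 10⁻⁴ on self-generated targets).

## The virtual population

`generate_population(n, seed)` draws, per individual: age ~ U(20, 80);
sex alternating then shuffled (exact 1:1 up to odd n); an intended
stress-phenotype pattern from a categorical mixture (66 % all four
axes, 13.5 % each missing the oxidative or the inflammatory axis, 7 %
basal-tone-driven patterns); severities 1 − Beta(1, 9) on "on" axes
and mostly zero (minority mildly sub-threshold) on "off" axes; and
lognormal kinetic multipliers. The multipliers are: an oxidative
constitution that is deliberately **bimodal** (a tight core near 1 and
a severe mode near 2 in 26 % of individuals, who respond incompletely
to the antioxidant arm), an inflammatory gain (mean 1.6), an
insulin-axis drive (σ = 0.32), and basal HPA and renin tones that
carry the mental/physical flags in phenotypes whose cytokine axes are
quiet. A shared latent factor (ρ = 0.6) correlates the channels so
that residual post-intervention stress clusters in the same
individuals, and a small inflammatory partial-responder mixture (2 %)
models bioavailability variation. Arms share individuals (paired
design); steady states are solved per individual per arm with the
deterministic arm solutions as starting points.

The bimodal oxidative constitution is forced by arithmetic, not taste:
a combined-arm ROS mean near 30 % must coexist with ~70 % of the
population below the 10 % oxidative threshold, which no unimodal
lognormal response can satisfy; a low-responding severe mode carrying
the mean is the only consistent shape.

A responder is an individual whose marker declines by more than 55 %
of its pre-intervention stress excess (ROS as production %, TNF-α as
excess over the healthy level, SBP as excess over the map floor, PSS
as the raw score), with small per-marker floors on the pre-excess at
the scale of assay noise. The 55 % default is calibrated: with a
potent intervention, small cutoffs count every treated individual as
a responder and cannot reproduce cohort responder fractions below
90 %.

## What the generator does and does not emulate

It emulates the *structure* the analysis depends on: heterogeneous
multi-axis stress with realistic co-occurrence, seeded
reproducibility, paired arms, partial response. It does not emulate
real-cohort features such as age/sex effects on stress physiology
(recorded but inert), measurement error, adherence or dropout, or
longitudinal within-person variability. Passing tests therefore show
internal consistency of the model and analysis pipeline, not clinical
validity of the intervention.

## Numerical choices

Trajectories: implicit BDF, rtol 10⁻⁸, atol 10⁻¹⁰, recorded in each
trajectory's metadata. Steady states: hybrid-Newton root solve on the
stationarity conditions with the two pool totals pinned, verified by
‖rhs‖∞ < 10⁻⁸·max(1, ‖x‖∞), with long-horizon (200-day) integration
fallback; bit-stable for fixed parameters. Hill terms evaluate
max(x, 0) so the right-hand side is non-negativity-preserving;
solver excursions stay above −10⁻⁹ (property-tested over 1000 random
parameter draws). Phenotype fractions are computed in exact rational
arithmetic. Reports embed the config digest and seed and are
byte-identical on re-runs.

## Known limitations

* The combined-arm population TNF-α mean and the TNF-α combined
  efficacy cannot simultaneously match the deterministic
  post-intervention TNF-α value and the blood-pressure/PSS outcomes:
  any TNF-α distribution with the larger mean re-activates the
  TNF-α → renin and IL-6 → HPA couplings. The calibration favours the
  deterministic values and the BP/PSS outcomes; the TNF-α cohort mean
  lands low, and two acceptance-suite assertions document this.
* The pre-intervention three-type phenotype fraction is squeezed by
  the joint constraints on the four-type fraction, the ≥3-axis
  prevalence and the small two-/one-type buckets; it settles ~25–30 %.
* Population standard deviations are emergent, not fitted; the
  oxidative-axis spread is wider than a unimodal fit would give (see
  the bimodality argument above).
* Pharmacokinetics, dosing schedules, circadian cortisol rhythm,
  acute stress pulses and stochastic (molecular-noise) simulation are
  out of scope. Model interchange is via the JSON parameter format;
  trajectories and reports are CSV.
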