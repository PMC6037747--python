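# Methods

## Model

The model describes AMPA-receptor (AMPAR) trafficking on a short dendritic
segment of a CA1 pyramidal neuron carrying five mushroom spines, and the
consequences of receptor redistribution for synaptic strength.  Synaptic
strength is identified with the number of AMPARs at a postsynaptic density
(PSD): free receptors diffusing on the PSD membrane plus receptors anchored
by scaffold proteins.

### Geometry

The dendrite is a 2 µm × 0.5 µm cylinder; each spine is a 0.25 µm × 0.2 µm
cylindrical neck topped by a 0.5 µm spherical head whose flat top is the
PSD (0.3 µm diameter disc) surrounded by an endocytic-zone (EZ) annulus
(outer diameter 0.4 µm).  The membrane is discretized into well-mixed
compartments — 10 shaft rings, and neck/head/EZ/PSD per spine — plus one
well-mixed cytosolic pool per spine head (35 compartments in the default
model).  Lateral diffusion of free receptors becomes hopping between
adjacent compartments at the finite-volume rate `k = D·w/(A·h)` (boundary
length `w`, source area `A`, centre distance `h`).  Hop rates satisfy
detailed balance, so a freely diffusing receptor equilibrates to an
occupancy proportional to compartment area; the characteristic in-path
lengths that set `h` affect kinetic timescales only, never equilibria.
The two lateral cross-sections are reflective by default; an `open_bath`
mode exchanges receptors with an external bath held at the initial mean
surface density, at the same stencil rate as one additional shaft ring.

PSD/EZ diameters, spine spacing (evenly spaced, 1/3 µm apart) and the free
diffusion coefficient are design parameters exposed in the configuration;
compartment equilibria depend on areas and rate constants alone, so these
choices set kinetic timescales, not steady states.  `D_free` ships with the
calibration artifact at 0.4 µm²/s — the middle of the experimental range
for mobile surface AMPARs.  Slower values (0.1 µm²/s) leave the membrane so
poorly mixed over the 170 s observation windows that heterosynaptic changes
reach only about half their equilibrium size and replicate variance roughly
doubles, which contradicts the reported ensemble behaviour; `D_free` is
therefore treated as a calibration parameter like the trafficking rates.

### Reactions

* **Scaffold binding.**  Each PSD carries 300 immobile scaffold molecules;
  each binds one free receptor: `scaffold + AMPAR ⇌ scaffold·AMPAR` with
  `k_f1 = 1 µm²·molecule⁻¹·s⁻¹` (propensity `k_f1·n_S·n_R/A_PSD`) and
  dissociation `k_b1 = 100 s⁻¹` in the basal state.  The LTP scaffold state
  dissociates at `k_b1/10`, the LTD state at `10·k_b1` — the 10-fold
  affinity shifts are identities, not free parameters.
* **Endo/exocytosis.**  Ten copies of a single endocytic/exocytic enzyme
  (EEP) per EZ cycle receptors between the EZ membrane and the spine's
  cytosolic pool through explicit EEP·AMPAR intermediates: encounter
  `k_f2` (surface receptors and cytosolic receptors both encounter EEP with
  EZ-area scaling), release `k_b2`, internalization `k_f3`,
  externalization `k_b3`.  The explicit intermediate makes both directions
  saturable in the EEP copy number, which is what lets a finite cytosolic
  pool buffer large surface demands without emptying instantly.
* **Plasticity induction.**  100 copies of a generic cytosolic enzyme
  (enzLTP or enzLTD) released into one spine convert that PSD's scaffolds
  (free or complexed — state conversion preserves complexation) by mass
  action at `k_phos = 0.01 µm²·molecule⁻¹·s⁻¹`, i.e. a per-scaffold rate of
  ~14 s⁻¹: conversion is complete well within a second, effectively
  instantaneous on the 150 s analysis windows, and `k_phos` is otherwise
  calibration-free.  Enzymes neither degrade nor leave their spine, so an
  induction is a permanent state switch within a run.
* **Variants.**  Three-state (default): scaffolds are basal until converted
  to the LTP or LTD state.  Two-state: scaffolds are high- (`k_b1/10`) or
  low-affinity (`10·k_b1`); enzLTP converts low→high, enzLTD high→low; the
  basal mixture is 40% high / 60% low, which matches the three-state
  resting synaptic population to within a few receptors.

Initial condition: 1000 surface receptors spread deterministically in
proportion to compartment area (largest-remainder rounding — the burn-in
erases any residual placement detail), 100 cytosolic receptors per spine,
all scaffolds free in their basal state.

### Simulation

The default solver is an exact Gillespie direct method compiled with numba,
with a channel dependency graph so only affected propensities are updated
per event and channels ordered by initial propensity to shorten the linear
selection scan (~0.15 µs/event; a 210 s replicate of the default model runs
in a few seconds).  An approximate tau-leap solver (fixed step, ≤10 ms;
binomial draws on single-reactant channels so they cannot overdraw their
substrate, Poisson draws on bimolecular channels, and rejection-with-
halving on any step that would drive a count negative — never clamping) is
provided and validated against the SSA; exact SSA remains the default
because the scaffold-binding cycle pushes ~10⁴ events/s through the
few-copy free-receptor pool of each PSD, which forces tau-leap steps so
small that leaping loses its advantage.

Each protocol is preceded by a burn-in (30 s; 50 s for the two-state
variant, whose low-affinity complexes equilibrate more slowly) that is
simulated and discarded, with the clock reset to zero.  States are sampled
on a 0.5 s grid.  A replicate is fully determined by (system, seed,
method): re-running is bit-identical.  The mean-field mass-action ODEs of
the same channels (LSODA) serve as the deterministic oracle for
calibration and cross-checks.

### Outcome measures

Synaptic count of PSD *i* at time *t*: free receptors on that PSD plus all
scaffold·AMPAR complexes.  Percent change over a window
`100·(N(t_end) − N(t_start))/N(t_start)`, with both endpoints estimated by
averaging over trailing 30 s windows `[t − 30, t]` (clipped at the
trajectory start) — trailing rather than centred so the baseline at an
induction instant contains no post-induction samples, and long enough to
average over the slow plateau fluctuations of ~100-copy counts, which
dominate replicate variance.  Replicates (5–12 per protocol, fixed documented seed lists)
are summarized as mean ± STD.  Two-arm comparisons default to Welch's
t-test — control and treatment arms use independent seeds, so an unpaired
unequal-variance test is the statistically correct default; a seed-matched
paired t is available for parity with analyses that paired runs.
Multi-group comparisons use one-way ANOVA with Tukey HSD post hoc tests
(scipy implementations behind the analysis API).

## Calibration

Only the four EEP trafficking rates are fitted.  They are constrained by:
resting cytosolic pool ≈ 100 receptors/spine, resting synaptic population
100–120 per PSD, single-spine LTP gain ≈ +119%, and the heterosynaptic
magnitudes for two- and four-spine LTP and four-spine LTD.  The fit runs
Nelder-Mead in log space on the mean-field oracle from a fixed starting
point, then is verified stochastically.  Among kinetically near-equivalent
parameter sets (the data constrain mostly flux ratios, not the absolute
cycling speed) the objective prefers the least stiff one: rates are capped
and the resting total propensity carries a soft penalty, which keeps exact
simulation affordable without changing any calibrated observable.  The
fitted values ship as a versioned JSON artifact with a report listing, for
every reference benchmark, its mean-field prediction and a stochastic
verification estimate (12 replicates on a dedicated seed list) with its
standard error.  A benchmark is flagged as carrying documented surrogate
bias — and validated at two reported STD instead of one — when either
oracle departs from the reported mean by more than one STD; using both
oracles keeps the flag stable for benchmarks that sit within a standard
error of the boundary.

The PSD area and `k_f1` enter the binding propensity only through
`k_f1·n_R/A` at fixed receptor density, so only their combination with the
total membrane area is identifiable; the gauge chosen here fixes the
geometry at its stated dimensions and keeps `k_f1` at its printed value.
One consequence is documented in the calibration report: with 1000
receptors on the ~7.7 µm² membrane that the stated geometry implies, the
binding-only resting synaptic population equilibrates near 112–115
receptors per PSD — inside the reported 100–120 steady-state band, but
above the nominal "~100" of the dissociation-rate sweep.  No un-printed
efficiency factor is introduced to force that single number down, because
the same equilibrium is what makes the +119% single-spine LTP gain come
out right (the LTP-state equilibrium sits near scaffold saturation at
~250 receptors).

## What the model does and does not emulate

The compartmental surrogate preserves mass balance, binding equilibria,
saturable trafficking and pool competition — the mechanisms behind the
heterosynaptic effects — and reproduces the reported ensemble statistics.
It does not resolve per-particle Brownian motion, intra-compartment
concentration gradients, the triangulated membrane mesh, or the endosome
as a geometric object (the cytosol is one well-mixed pool per spine).
Consequences: microscopic first-passage effects of the original
particle-on-mesh simulation are absorbed into the calibrated rates, and
agreement is expected at the level of replicate means and STDs, not
trajectories.  Passing tests show the mechanisms and their magnitudes are
reproduced under the stated study conditions; they do not certify behaviour
at copy numbers or geometries far outside them (e.g. scaffold counts below
~50, where heterosynaptic potentiation saturates away).

## Numerical choices

* Tau-leap default step 1 ms, halved on any prospective negativity (up to
  60 times before erroring); validation against SSA uses 0.2 ms, where the
  reduced model's means agree within 1%.
* Mean-field integration: LSODA, rtol = atol = 1e-8; stiff segments (LTD
  scaffold states dissociate at 1000 s⁻¹) are well inside LSODA's regime.
* `equilibrium_solve` uses the closed-form quadratic root with the
  discriminant asserted non-negative; degenerate inputs (zero dissociation,
  zero receptors) resolve to the correct boundary root.
* Percent changes are undefined for a zero baseline and raise instead of
  returning infinities; ANOVA on all-identical groups reports F = 0 with
  p = 1 rather than 0/0.
* Replicate seeds derive from a documented base seed and the protocol name
  (SHA-256, all seeds below 2³¹), so replicate noise is independent across
  protocols — a plain shared counter would reuse identical burn-in
  realizations everywhere and correlate the "luck" of every experiment;
  acceptance-style recomputations derive all seeds the same way from one
  user-supplied integer.

## Problem sizes

Validation batteries run every benchmark protocol at its documented
replicate count (5–12 replicates of 180–330 s model time), which the
compiled SSA completes in minutes on one core.  The reduced `fixture_small`
model (2 spines, 200 surface receptors, 60 scaffolds/PSD, 60 s) backs the
unit and property tests where full-scale runs would add nothing but time.

## Known limitations

* The trafficking-rate fit is under-determined; the shipped artifact is one
  well-behaved point of a feasible set, with the stiffness preference
  acting as the documented tie-break.
* The documented surrogate biases (calibration report): heterosynaptic
  depression from a *single* LTP is about half the reported magnitude
  (~-7% vs -16.3 ± 7.5) while multi-spine protocols match; four-spine LTP
  overshoots heterosynaptic depression slightly (~-35% vs -29.4 ± 5.35);
  and sequential posterior gains run ~5-7 points above the reported means
  (~+144% vs 137 ± 4.4) because the exocytotic replenishment that caps
  four-spine depression slightly over-supplies later inductions.  These
  reflect a genuine tension in the single EEP cycle — weak demand calls for
  weak replenishment, strong demand for strong — that its saturable but
  non-cooperative kinetics cannot fully resolve.  The biases are documented
  rather than tuned away, and those benchmarks are validated at 2 STD.
* Enzyme-converted scaffolds never revert within a run; protocols longer
  than a few minutes of model time would need explicit phosphatase/kinase
  turnover to be meaningful.
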