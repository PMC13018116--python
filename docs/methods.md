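# Methods

## The model

`lupusim` simulates the onset of lupus nephritis in the kidneys of
lupus-prone NZB/W F1 mice as a network of interacting innate immune-cell
populations. Nine cell-state variables (resting and activated tissue helper
ILC, tissue macrophages, intermediate parietal epithelial cells, vessel NK
cells, monocytes, capillary endothelial cells, tissue damage and
immune-complex deposits), four tissue cytokines and an algebraic type-I
interferon (IFN-I) concentration evolve by ordinary differential equations
built from four elementary processes, each carrying one literature-anchored
rate (per day): activation (α = 4.8), infiltration (β = 2.4), proliferation
(γ = 2.4) and removal (δ = 0.24). Cytokines are secreted (q = 1.44), taken
up by receptor-mediated endocytosis (λ = 14.4, saturating in the cytokine
level) and degraded (η = 0.24). All gating uses cubic Hill functions
h[x, K] = x³/(K³ + x³); composite drives are capped at one so that no
per-capita rate exceeds its maximum. Abundances and concentrations are
dimensionless intrinsic units; the public interface reports weeks of age
(7 days per week exactly).

IFN-I is treated as a fast (quasi-steady-state) species:

    c = min{ q0 + q1·1(19 ≤ t ≤ 23 wk) + q2·(ζ4 h[x9,K2] + ζ1 h[x8,K2]), 1 }

combining a baseline level `q0`, the poly(I:C) stimulus `q1` applied in
weeks 19–23 of age, and damage- (ζ1) and immune-complex- (ζ4) induced
release. Five positive feedback loops close the amplification circuit:
F1 damage→IFN-I (ζ1), F2 damage→tILC activation (ζ2), F3 IC→macrophage
recruitment (ζ3), F4 IC→IFN-I (ζ4), F5 IC→monocyte recruitment (ζ5).
The lupus-prone genotype differs from wild type in a single constant:
μ2 > 0 enables delayed production of immune complexes from tissue damage;
under `genotype="wt"` the immune-complex pool is identically zero, so the
wild-type run coincides exactly with the {F3, F4, F5} knockout — a
structural identity the test-suite asserts.

### Delays

Delays are represented by the linear chain trick: a cascade `R[k, n]` of n
first-order stages at rate k, whose impulse response is the Erlang density
with mean n/k and standard deviation √n/k. Damage-driven immune-complex
production passes through `R[μ2, 3]`; the chain output (the third stage) is
the delayed damage signal that the IC production rate μ2 multiplies. The
chain state is stored contiguously after the named cell variables — the
layout `x1..x9, y1..y_n, c1..c4` is part of the public contract
(`lupusim.model.state_names`).

### Interventions

Poly(I:C) stimulation is the indicator term in the IFN-I expression.
Depletion (the anti-asialoGM1 experiment and its vessel-NK analogue)
multiplies the tILC carrying capacity and/or the vNK infiltration rate by
(1 − κ) during the depletion window; the default κ = 0.8 for weeks 19–25
reproduces an ~80% reduction in the targeted activity. Feedback knockouts
zero the corresponding ζ weight for the whole run.

## Time origin and burn-in

Reported trajectories start at week 12 of age, the age of unstimulated
control animals. Internally every run starts at week 4 from a small seeded
resting-ILC pool (1% of carrying capacity; an exactly-zero pool is a
degenerate fixed point of logistic growth) and relaxes for eight weeks.
The epithelial/endothelial pools fill to their basal steady state within
days and the tILC pool reaches carrying capacity; under the NZB/W genotype
the immune-complex ratchet already creeps upward during the burn-in, so the
two genotypes differ slightly at week 12, before any stimulus — a genuine
feature of a genotype with a damage-to-autoantibody pathway.

## Calibration of the free parameters

The seven kinetic rates above are fixed. The remaining constants — Hill
half-saturations K1–K3, carrying capacity ω, feedback weights ζ1, ζ2, ζ4
(ζ3 = ζ5 = 0.2 are held fixed in the default preset), the IFN→monocyte
drive θ, damage kinetics μ1 (fixed at 1/42 per day, the six-week damage
acquisition scale) and ν1, immune-complex kinetics μ2, ν2, and the IFN-I
levels q0, q1, q2 — are not identifiable from first principles and are
fixed by a constraint-based calibration (`lupusim.analysis
.calibrate_defaults`), not by fitting time series. The constraint set
pins qualitative disease behaviour:

* C1 — the stimulated NZB/W run shows a two-peak IFN-I response, the first
  peak inside the stimulation window (weeks 19–23) and the secondary,
  feedback-driven peak at weeks 25–27;
* C2 — the stimulated wild-type run is a single transient: damage recovers
  to below 10% of its peak by week 35;
* C3 — the untreated NZB/W run reaches the pre-ESRD damage level about 7.6
  weeks before the ESRD level;
* C4/C5 — virtual-cohort fractions reaching pre-ESRD at week 25 of ~92%
  (stimulated), ~26% (tissue-ILC depletion) and ~15% (untreated hybrid);
* C6 — ζ3 = ζ5 = 0.2 exactly.

The shipped default parameter record in `lupusim.params` is the versioned
output of this procedure (a Nelder-Mead search over the free parameters
against the constraint set, followed by robustness probes under ±10%
parameter perturbations so that the cohort constraints hold under
log-normal parameter noise and not only at the default point).
`calibrate_defaults` re-verifies the shipped preset and can search its
neighbourhood deterministically given a seed.

Two structural choices deserve mention. First, the damage variable is a
fast-relaxing burden index: ν1 is of order one per day, so damage tracks
the weighted effector burden μ1(x3+x5+x6)/ν1 with little lag, while the
slow (six-week, μ1 = 1/42 d⁻¹) accumulation physiology lives in the
effector and immune-complex kinetics. This is forced by the shared Hill
constant K2: the damage and immune-complex gates must operate on the same
scale as the cell-state gates. Second, the immune-complex pool is a slow
ratchet: ν2 ≪ μ2, so deposits accumulate over months and are the only slow
memory in the model. Spontaneous (untreated) disease onset is a slow
passage of this ratchet across the ignition threshold of the feedback
circuit; its extreme parameter sensitivity is not a numerical nuisance but
the model's explanation of the wide (weeks 20–44) spread of spontaneous
onset ages.

### Feedback presets

At uniform immune-complex feedback strength the direct IC→myeloid routes
(F3/F5) dominate the topology; the default preset down-scales them to
ζ3 = ζ5 = 0.2 to put the ILC-mediated amplification route in charge, which
is the configuration used for every depletion and cohort analysis. The
`uniform_feedback` preset (ζ3 = ζ5 = ζ4) is retained for topology-focused
feedback-knockout analyses.

## Outcome definitions

The ESRD (end-stage renal disease) reference is computed from the default
stimulated NZB/W run over a fixed 60-week horizon: the ESRD damage value is
95% of that run's maximal damage and the reference time-to-ESRD is its
first crossing. Pre-ESRD — the proteinuria proxy — is 70% of the ESRD
damage value, evaluated at week 25 (the age at which the animal experiments
read out proteinuria). Threshold crossings are located by linear
interpolation on the output grid (0.1 week). Runs that never cross within
the horizon are censored, never coerced to a number.

## Virtual cohorts

A cohort member multiplies every perturbable parameter — all rates, weights,
Hill constants and IFN levels, but never structural integers or window
times — by exp(ε), ε ~ Normal(0, 0.1) i.i.d., i.e. multiplicative
log-normal noise centred on the default with ~10% coefficient of variation.
(A "log-normal distribution with zero mean" is taken to mean zero mean in
log space; a literally zero-mean log-normal does not exist.) Each member
runs the scenario to week 26 and is classified by damage(25 wk) ≥ pre-ESRD.
Seeding uses `numpy.random.SeedSequence` spawning: member i always receives
the i-th child stream, so enlarging a cohort never changes earlier members.

## The hybrid stochastic model

Spontaneous acute inflammatory episodes are a telegraph process: off→on
switching is a Poisson process with rate `k_off`, and the on→off recovery
is a multi-step response-time reaction `R[k_on, n_on]`, making on-durations
Erlang with mean τ_on = n_on/k_on and CV 1/√n_on. (The rate of the off→on
reaction is named `k_off` after the state it terminates; the naming is kept
for consistency with the model's published description.) Paths are sampled
exactly by the stochastic simulation algorithm starting in the off-state;
drawing each on-duration from a Gamma(n_on, 1/k_on) is distributionally
identical to summing n_on exponential stage times. Between switches the
ODE system is integrated unchanged except that the immune-complex equation
gains the event source: dx9/dt = μ2(ξ·X_on + y_out) − ν2 x9. The solver
restarts at every switch, so the discontinuous forcing is never smoothed
across a step; the state is continuous there.

The default event process (τ_on = 2 weeks, τ_off = 12 weeks, CV = 0.5,
ξ = 0.02) is itself a calibration output, targeted at the untreated onset
window (roughly weeks 20–44) and the observed spontaneous pre-ESRD fraction
at week 25; the value the model actually attains is recomputed by the
acceptance script, not assumed. Because
immune complexes decay slowly, event-driven deposits accumulate across
episodes; disease fires when, by chance, deposits exceed what degradation
can clear — the model's reading of spontaneous, environmentally triggered
onset. The onset-delay statistic t_stoch is the hybrid time-to-ESRD minus
the reference (stimulated deterministic) time-to-ESRD; hybrid runs that
never reach ESRD within the horizon are censored.

The switching-frequency scan (`resonance_scan`) varies the switching
frequency at fixed long-run on-fraction and fixed CV. Because a single
long episode can push the ratchet over threshold while fast switching
averages into a weak constant forcing, the mean onset delay is minimised at
an intermediate frequency — a stochastic-resonance-like optimum that the
acceptance suite checks lies strictly inside the scanned grid.

## Numerical choices

* Integrator: LSODA (automatic Adams/BDF switching) via
  `scipy.integrate.solve_ivp`; defaults rtol 1e-8, atol 1e-11. Halving the
  tolerances changes no state component by more than 1e-6.
* The right-hand side is compiled with numba when available (pure-NumPy
  fallback, identical arithmetic).
* Discontinuous controls (stimulus window, depletion window, telegraph
  switches) are handled by splitting the integration at every boundary;
  indicator values are resolved per segment, never inside a step.
* Stopping at ESRD uses solve_ivp event detection (rising crossing of the
  reference damage), not grid search.
* Negative-state protection: gate inputs are clamped at zero inside the
  right-hand side; trajectories are asserted non-negative to −1e-9.
* IFN-I peak detection: local maxima on the output grid after rounding to
  10 decimals, plateaus (the hard cap at 1) compressed to their first
  point, and a trajectory stopped at ESRD while still rising contributes
  its endpoint as a final maximum.
* Problem sizes: virtual cohorts use N = 1000 members (binomial s.e. ≤
  1.6 points); the resonance scan uses a 5-point frequency grid; the
  sensitivity scan covers all 24 scalar parameters at ±20%.
* When the tILC pool exceeds its (depleted) carrying capacity, the literal
  logistic contraction would push the resting pool below zero; the
  contraction is therefore applied per-capita to the resting compartment,
  which coincides with the literal form whenever the pool is within
  capacity and preserves non-negativity during depletion.

## What the simulations do and do not show

All quantitative claims are about the calibrated model, not about mice:
the synthetic cohorts emulate between-animal variability as independent
log-normal rate perturbations, which ignores covariation between rates,
litter effects and measurement error in proteinuria scoring. The
calibration pins qualitative behaviour; parameter values are not unique,
and quantities far from the constraint set (absolute cell counts, cytokine
concentrations) carry no biological units. The model has no adaptive
immune compartment beyond the implicit immune-complex chain, no spatial
kidney structure, and treats depletion as a clean multiplicative control.
Within those limits the simulations reproduce the two-peak interferon
response, wild-type recovery, the ~7.6-week pre-ESRD→ESRD interval, the
cohort fractions under stimulation and depletion, and the
timing-dependence of depletion therapy.
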