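# Methods

## The model

`mtswitch` simulates a single, coarse-grained microtubule as an ordered
sequence of tubulin subunits, each in a GTP (`T`) or GDP (`D`) chemical
state, evolving by four Poissonian event channels:

| event | condition | rate | default |
|---|---|---|---|
| attach a `T` subunit | tip is `T` (or filament empty) | u = k·C | k = 3.2 μM⁻¹s⁻¹ |
| attach a `T` subunit | tip is `D` | u′ = k′·C | k′/k ∈ [0, 1], study parameter |
| detach tip subunit | tip is `T` | w_T | 24 s⁻¹ |
| detach tip subunit | tip is `D` | w_D | 290 s⁻¹ |
| hydrolyse `T` → `D` | any `T`, any position | r per subunit | 0.5 s⁻¹ |

Hydrolysis is *random* (position-independent), so the filament carries a
stabilising GTP cap at the tip plus interior GTP remnants.  Because
w_T ≪ w_D, loss of the cap triggers rapid shrinkage (catastrophe), and
re-capping — via attachment onto the GDP tip at the reduced rate u′ or via
exposure of a buried remnant — produces rescue.  The ratio k′/k is the
control knob for dynamic instability: at k′/k ≪ 1 a GDP tip is nearly dead
and the filament exhibits long, macroscopically distinct growth and
shrinkage phases.

Simulation is an exact stochastic simulation algorithm (Gillespie): at each
step the total propensity a₀ = u(or u′) + w + r·n_T determines an
exponential waiting time, and the event is chosen proportionally to its
propensity.  The inner loop is JIT-compiled (numba) and tracks the set of
GTP positions so hydrolysis-target selection, tip updates and propensity
updates are O(1) per event (~10⁷ events/s); a transparent pure-Python
per-event API (`compute_rates` / `gillespie_step`) exposes the identical
rules for exact small-system studies and is validated against a directly
enumerated master-equation solution (below).

### Length calibration

The model is single-track, but velocities and the catastrophe criterion are
expressed in physical units.  We use δ = 8/13 nm ≈ 0.615 nm of length per
subunit: one 8-nm dimer layer distributed over the 13 protofilaments the
coarse-grained description absorbs.  With the default rates this gives
growth speeds of ~5–20 nm/s, shrinkage at w_D·δ ≈ 178 nm/s, and μm-scale
catastrophe excursions, all in the experimentally familiar range.  δ is a
configurable field of `KineticParams`.

### Concentration protocols

Free-tubulin concentration is either constant or ramped:
C(t) = clamp(C₀ + γ·max(0, t − t_hold), C_min, C_max).  Ramps re-evaluate
C(t) at each event using the waiting time drawn from the current
propensities.  This is a (very mild) approximation to the time-inhomogeneous
algorithm: with γ ≤ 0.2 μM/s and waiting times ≲ 30 ms, the concentration
drift per event is < 0.01 μM.

### Initial conditions — three deliberate regimes

The initial state is not part of the published model description, and it
matters.  We use three documented defaults:

* **Generic simulation** (`SimConfig`): 2000 GDP subunits + 50 GTP cap, a
  convenient ~1.2 μm seed.
* **Steady-state velocity statistics** (`velocity_analysis`): a 100,000
  subunit (~60 μm) GDP seed.  Near the transition a filament in its
  shrinkage phase loses length at ~178 nm/s; with a short seed it hits zero
  within seconds, re-nucleates, and the negative-velocity macrostate is
  truncated — p(v) then loses its −w_D·δ mode entirely and the apparent
  critical concentration shifts by ~2 μM.  The long seed lets shrinkage
  phases run at full speed for the whole trace.  (With it, the two
  operational definitions of C* below agree with each other to ~10%.)
* **Catastrophe statistics** (`catastrophe_analysis`): an *empty* nucleation
  site.  Each filament assembles its cap and remnants from scratch, so the
  "age" clock starts with growth as in seed/dilution experiments.  Starting
  pre-capped removes the early-time suppression of F(t) and collapses the
  fitted step number from n ≈ 4 to n ≈ 1.35.

A 50-s burn-in is discarded from all velocity statistics.

## Velocity analysis

The order parameter is the coarse-grained velocity
v = (L(t+T) − L(t))/T over non-overlapping windows of duration T
(overlapping windows would correlate samples and bias the fourth moment).
From pooled ensemble samples we compute ⟨v⟩, σ² = ⟨v²⟩ − ⟨v⟩², the scaled
variance Tσ², and the Binder cumulant BC = 1 − ⟨v⁴⟩/(3⟨v²⟩²) with *raw*
moments: BC → 2/3 for a delta-like distribution, 0 for a zero-mean
Gaussian, and negative at a two-peak coexistence with unequal weights — the
standard finite-size diagnostic of a discontinuous transition.

p(v) is a Gaussian KDE with Silverman bandwidth; a *mode* is a local
maximum with prominence ≥ 5% of the global maximum (ties and plateaus count
once, a peakless density counts as one mode).  This operationalises the
visual bimodality criterion reproducibly; the 5% floor makes the
coexistence-edge estimate below conservative, since a negative mode
carrying a few percent of the mass is declared absent.

**Critical concentration.**  Two operational definitions, both by
stochastic bisection over C:

* *zero-crossing*: the sign change of the ensemble-mean T=200 s velocity.
  A sign call requires |⟨v⟩| > 2·SEM, otherwise the ensemble is doubled
  (up to 8×) before branching.
* *coexistence-edge*: the smallest C at which the T=20 s p(v) has lost its
  negative mode (upper edge of the growth/shrinkage coexistence region).

With the default rates and k′/k = 0.01 these give ≈ 11.6 μM and ≈ 10.4 μM
respectively; for k′/k = 1 the zero crossing is ≈ 9.4 μM.

**Velocity jump.**  `velocity_jump` reports |⟨v⟩(C*+δC) − ⟨v⟩(C*−δC)| with
propagated SEM.  Note that the *time-averaged* ⟨v⟩(C) crossover for
k′/k = 0.01 is ≈ 2.5 μM wide (plateau-to-plateau swing ≈ 0.145 μm/s), so
mean differences over small δC understate the switch.  The
paper-style "jump between macroscopic velocity states" is better measured
as the separation of the two modes of the bimodal T=20 s distribution just
inside the coexistence region (≈ 0.17 μm/s with defaults); the acceptance
script reports that quantity.

**Hysteresis.**  Each leg holds the ensemble at one end of [C_low, C_high]
for 50 s, then ramps at ±γ.  Instantaneous velocities are averaged in
0.25-μM concentration bins over ≥ 100 filaments per leg, and
loop_area = |∫(v_up − v_down) dC|.  Faster ramps leave less time to hop the
kinetic barrier between the coexisting states, so the loop area grows
with γ.

## Catastrophe analysis

A catastrophe is scored directly from the kymograph: the first sample at
which length ≤ running maximum − 500 nm (≈ 813 subunits at the default δ).
The event time is the detection time, not back-dated to the peak, which
shifts times by the ~3 s the drop itself takes.  Only the first event per
filament enters F(t); traces with no event are right-censored at the
horizon.

* F(t) is the Kaplan–Meier product-limit estimate (plain ECDF mode is
  available and identical when nothing is censored).
* The age-dependent catastrophe frequency is the hazard
  f_c(t) = (dF/dt)/(1 − F), with dF/dt a centred finite difference over a
  10-s sliding window; windows with fewer than 5 events are suppressed and
  standard errors scale as f_c/√(events in window).
* The multi-step diagnostic is 1 − R² of a straight-line fit to
  log(1 − F) vs t over 0.02 < F < 0.98: ≈ 10⁻³ for exponential
  (single-step) data, ≳ 10⁻² for gamma-shaped multi-step data.
* The catastrophe-time density is fitted by a gamma distribution
  (shape n, rate r) by maximum likelihood on the raw times, with censored
  observations contributing survival-function terms — distributionally
  equivalent to least squares on a binned dF/dt (a binned mode is provided
  as a cross-check) but bin-free and censoring-aware.  n is reported as a
  real number; 95% CIs come from the observed information in log-parameter
  space.  The shape n is read as the minimum number of independent
  equal-rate steps required to trigger catastrophe.

With defaults at k′/k = 0.01, C = 11 μM: median first-catastrophe time
≈ 240 s, n ≈ 4, and an f_c(t) that rises several-fold from young to old
filaments before saturating.

## Two-state baseline

The four-parameter telegraph model (growth v_g / shrinkage v_s, switching
rates f_cat, f_res) is implemented event-driven with a reflecting
zero-length boundary (absorbing optional) and the exact stationary mean
v̄ = (v_g f_res − v_s f_cat)/(f_cat + f_res) as its oracle.  Since the
Walker-experiment parameter-vs-C functions are not available here, the
concentration sweep takes a user-supplied parameter table (piecewise-linear
in C).  Coarse-graining this model at T = 200 s ≫ switching times yields
unimodal velocity distributions and a smooth ⟨v⟩(C) — the contrast case for
the emergent switching of the microscopic model.

## Numerical and design notes

* **Determinism.**  Every trace is reproducible from (params, protocol,
  config): per-filament streams are spawned from the master seed via
  `SeedSequence`, so ensembles are independent of execution order.
* **Empty filament.**  Attachment onto an empty filament uses the GTP-tip
  rate k·C (a nucleation site); `stop_on_empty` optionally truncates the
  trace instead (flagged censored).
* **Degenerate inputs.**  Zero-variance velocity samples give BC = 2/3 (the
  delta-distribution value) and a single-spike density; all-censored
  catastrophe sets give F ≡ 0 with a warning; gamma fitting requires ≥ 3
  uncensored events.
* **Problem sizes.**  Default analysis ensembles are 100–500 filaments with
  traces of 450–2000 s — large enough that the bisection estimates above
  are reproducible across seeds to well within their reported half-widths,
  and small enough to run on a laptop in minutes.

## Known limitations

* The generator emulates a single filament in an infinite tubulin bath;
  there is no concentration depletion, no mechanics, no lateral
  protofilament structure, and no tip-specific hydrolysis.  Passing tests
  therefore validate the kinetic model and its statistics, not those
  extensions.
* Catastrophes (500-nm drops) are only frequent within ~1–2 μM of the
  critical concentration; the catastrophe battery is not meaningful far
  from C*.
* In this implementation, near-critical bimodality of the T=20 s velocity
  distribution disappears for k′/k ≳ 0.03: for larger ratios the GDP-tip
  attachment flux u′ = k′C rescues shrinkage within a couple of seconds, so
  no macroscopic shrinkage state survives coarse-graining (we scanned
  C ∈ [6, 10.5] and T ∈ [2, 100] s at k′/k = 0.2–0.5).  Published accounts
  of this model class place the disappearance nearer k′/k ≈ 0.4; we have
  not found a reading of the stated kinetics that reproduces that boundary,
  and report the measured one instead.
* The hysteresis ramp uses the per-event concentration update described
  above; for |γ| ≫ 1 μM/s a time-inhomogeneous scheme would be needed.
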