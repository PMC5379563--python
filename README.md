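# mtswitch

Kinetic Monte-Carlo simulation of single-microtubule dynamic instability,
plus the statistical machinery to characterise the macroscopic switching
transition between its growth and shrinkage phases.

A microtubule in a bath of GTP-tubulin at concentration *C* polymerises at
*u = kC* onto a GTP-bound tip and at *u′ = k′C* onto a GDP-bound tip,
depolymerises at *w_T* (GTP tip) or *w_D* ≫ *w_T* (GDP tip), and any GTP
subunit hydrolyses to GDP at a uniform rate *r* (random hydrolysis).  When
*k′/k* ≪ 1 this produces dynamic instability — long growth phases ended by
catastrophes, rapid shrinkage ended by rescues — and, at the ensemble
level, an abrupt switch of the coarse-grained velocity
*v = (L(t+T) − L(t))/T* from a mean-growth to a mean-shrinkage state as *C*
crosses a critical concentration *C*\*.  The package treats that switch
with the toolkit of discontinuous phase transitions:

* **`kmc_engine`** — exact Gillespie simulation (numba-JIT kernel,
  ~10⁷ events/s) of the filament under constant or ramped concentration;
  deterministic, seedable ensembles; length-vs-time traces.
* **`velocity_analysis`** — coarse-velocity distributions and cumulants
  (⟨v⟩, σ², *T*σ², Binder cumulant 1 − ⟨v⁴⟩/3⟨v²⟩²), KDE mode counting for
  bimodality, critical-concentration bisection (mean-velocity zero crossing
  or coexistence edge), velocity jump, and hysteresis loops under
  concentration ramps.
* **`catastrophe_analysis`** — catastrophes scored directly from
  kymographs (≥ 500 nm drop from the running maximum), censoring-aware
  survival curves *F(t)*, age-dependent catastrophe frequency
  *f_c = (dF/dt)/(1 − F)*, and gamma fits of the catastrophe-time density
  whose shape *n* is the minimum number of rate-limiting steps.
* **`two_state_model`** — the classic four-parameter growth/shrinkage
  telegraph model with its closed-form mean velocity, as the smooth
  baseline that shows *no* abrupt switching.
* **`cli_io`** — TOML configs, TSV trace files with JSON metadata headers
  (bit-exact round trip), run manifests, and the `mtswitch` command line.

Default kinetic parameters: *k* = 3.2 μM⁻¹s⁻¹, *w_T* = 24 s⁻¹,
*w_D* = 290 s⁻¹, *r* = 0.5 s⁻¹, with δ = 8/13 nm of length per subunit.
See `docs/methods.md` for the model, estimators, and design choices.

## Worked example

```python
import numpy as np
from mtswitch import KineticParams, ConcentrationProtocol, SimConfig, simulate_ensemble
from mtswitch.velocity_analysis import (
    ensemble_velocities, cumulants, velocity_distribution, mode_velocities,
    critical_concentration,
)

params = KineticParams.with_ratio(0.01)       # k'/k = 0.01, defaults otherwise

# Coarse velocities (T = 20 s) at C = 9.5 uM, 150 filaments
samples = ensemble_velocities(params, C=9.5, T_window=20.0,
                              n_filaments=150, duration=450.0, seed=72)
summary = cumulants(samples)
modes = mode_velocities(velocity_distribution(samples))
print(f"<v> = {summary.mean_v:+.4f} um/s, BC = {summary.binder:+.3f}")
print("modes (um/s):", np.round(modes, 3))

# Critical concentration, k'/k = 1, zero crossing of <v> at T = 200 s
cstar = critical_concentration(KineticParams.with_ratio(1.0), T_window=200.0,
                               mode="zero-crossing", bracket=(7.0, 12.0),
                               n_filaments=200, seed=23)
print(f"C* = {cstar.estimate:.2f} +/- {cstar.half_width:.2f} uM")
```

prints

```
<v> = -0.1026 um/s, BC = +0.453
modes (um/s): [-0.168 -0.003]
C* = 9.42 +/- 0.08 uM
```

The two modes are the coexisting macroscopic states: shrinkage at
≈ −0.17 μm/s (the depolymerisation speed *w_D*·δ) and growth near
+0.005 μm/s — the bimodality that marks the discontinuous character of the
transition.  For *k′/k* = 1 the same analysis gives a single mode at every
concentration and a smooth crossover with zero crossing at 9.4 μM.

The same pipelines are scriptable from the shell:

```sh
mtswitch --seed 3 --out-dir runs/ simulate --config config.toml --n 100
mtswitch --out-dir runs/ velocity-stats --trace-dir runs/ --T 20 --burn-in 50
mtswitch --out-dir runs/ catastrophe-stats --trace-dir runs/ --threshold-nm 500
mtswitch --out-dir runs/ critical-concentration --kratio 0.01 --mode coexistence-edge
mtswitch --out-dir runs/ hysteresis --gamma 0.1 --c-range 8:13
```

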