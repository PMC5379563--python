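"""Coarse-grained velocity statistics and switching-transition diagnostics.

The order parameter of the macroscopic growth/shrinkage transition is the
coarse-grained velocity ``v = (L(t+T) - L(t)) / T`` measured over windows of
macroscopic duration ``T``.  This module computes, from ensembles of
length-vs-time traces:

* velocity samples, their cumulants (⟨v⟩, σ², the scaled variance Tσ², and
  the Binder cumulant ``BC = 1 - ⟨v⁴⟩/(3⟨v²⟩²)``),
* kernel-density estimates of p(v) and a reproducible mode count
  (bimodality = coexistence of macroscopic growth and shrinkage),
* the critical concentration C* under two operational definitions
  (zero crossing of ⟨v⟩; upper edge of the bimodal coexistence region),
* the velocity jump across the transition, and
* hysteresis loops under finite-rate concentration ramps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

from .kmc_engine import (
    ConcentrationProtocol,
    KineticParams,
    SimConfig,
    Trace,
    simulate_ensemble,
)

__all__ = [
    "VelocitySamples",
    "CumulantSummary",
    "VelocityDensity",
    "CriticalConcentration",
    "HysteresisResult",
    "BracketingError",
    "coarse_velocities",
    "pooled_velocities",
    "cumulants",
    "velocity_distribution",
    "count_modes",
    "mode_velocities",
    "has_negative_mode",
    "ensemble_velocities",
    "mean_velocity_curve",
    "critical_concentration",
    "velocity_jump",
    "hysteresis_loop",
]


@dataclass
class VelocitySamples:
    """Non-overlapping coarse-grained velocity samples from one or more traces."""

    v: np.ndarray          # μm/s
    T_window: float        # s
    t_start: np.ndarray    # window start times, s


@dataclass
class CumulantSummary:
    mean_v: float      # ⟨v⟩, μm/s
    var_v: float       # σ² = ⟨v²⟩ − ⟨v⟩², (μm/s)²
    scaled_var: float  # T σ²
    binder: float      # 1 − ⟨v⁴⟩ / (3⟨v²⟩²), raw moments
    n_samples: int
    se_mean: float


@dataclass
class VelocityDensity:
    grid: np.ndarray     # μm/s
    density: np.ndarray  # normalised p(v)
    bandwidth: float


@dataclass
class CriticalConcentration:
    estimate: float    # μM
    half_width: float  # μM, bisection bracket half-width
    mode: str          # "zero-crossing" | "coexistence-edge"


@dataclass
class HysteresisResult:
    c_grid: np.ndarray   # shared concentration-bin centers, μM
    v_up: np.ndarray     # mean velocity along the ramp-up leg, μm/s
    v_down: np.ndarray   # mean velocity along the ramp-down leg, μm/s
    loop_area: float     # |∮ v dC|, μM·μm/s
    gamma: float         # ramp rate used, μM/s


class BracketingError(RuntimeError):
    """The bisection bracket does not straddle the transition."""


def coarse_velocities(
    trace: Trace, T_window: float, burn_in: float = 50.0
) -> VelocitySamples:
    """Velocities over non-overlapping windows of length ``T_window`` after
    ``burn_in``.  Returns an empty sample set for too-short traces."""
    dt = trace.sample_dt
    if not math.isfinite(dt):
        return VelocitySamples(np.empty(0), T_window, np.empty(0))
    m = int(round(T_window / dt))
    if abs(m * dt - T_window) > 1e-9 * max(1.0, T_window):
        raise ValueError("sample_dt must divide T_window")
    i0 = int(math.ceil(burn_in / dt - 1e-9))
    n_win = (len(trace.times) - 1 - i0) // m
    if n_win <= 0:
        return VelocitySamples(np.empty(0), T_window, np.empty(0))
    idx = i0 + m * np.arange(n_win + 1)
    v = np.diff(trace.lengths_nm[idx]) / T_window / 1000.0  # nm/s -> μm/s
    return VelocitySamples(v=v, T_window=T_window, t_start=trace.times[idx[:-1]])


def pooled_velocities(
    traces: list[Trace], T_window: float, burn_in: float = 50.0
) -> VelocitySamples:
    parts = [coarse_velocities(tr, T_window, burn_in) for tr in traces]
    v = np.concatenate([p.v for p in parts]) if parts else np.empty(0)
    t0 = np.concatenate([p.t_start for p in parts]) if parts else np.empty(0)
    return VelocitySamples(v=v, T_window=T_window, t_start=t0)


def cumulants(samples: VelocitySamples) -> CumulantSummary:
    """Moments of the velocity sample.  The Binder cumulant uses raw
    (non-central) second and fourth moments; a degenerate sample gives the
    delta-distribution value 2/3."""
    v = np.asarray(samples.v, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 velocity samples")
    mean = float(np.mean(v))
    var = float(np.mean(v**2) - mean**2)
    var = max(var, 0.0)
    m2 = float(np.mean(v**2))
    m4 = float(np.mean(v**4))
    denom = 3.0 * m2 * m2  # can underflow to 0 for subnormal samples
    binder = 2.0 / 3.0 if denom == 0.0 or var == 0.0 else 1.0 - m4 / denom
    return CumulantSummary(
        mean_v=mean,
        var_v=var,
        scaled_var=samples.T_window * var,
        binder=binder,
        n_samples=int(v.size),
        se_mean=float(np.sqrt(var / v.size)),
    )


def velocity_distribution(
    samples: VelocitySamples | np.ndarray, n_grid: int = 512
) -> VelocityDensity:
    """Gaussian-kernel density of p(v) with Silverman bandwidth."""
    v = samples.v if isinstance(samples, VelocitySamples) else np.asarray(samples)
    v = np.asarray(v, dtype=float)
    if v.size == 0:
        raise ValueError("no velocity samples")
    if v.size < 2 or np.std(v) == 0.0:
        # degenerate support: single spike
        c = float(v[0])
        w = max(abs(c), 1e-6) * 1e-3
        grid = np.array([c - w, c, c + w])
        dens = np.array([0.0, 1.0 / w, 0.0])
        return VelocityDensity(grid=grid, density=dens, bandwidth=w)
    kde = gaussian_kde(v, bw_method="silverman")
    bw = float(kde.factor * np.std(v, ddof=1))
    grid = np.linspace(v.min() - 3 * bw, v.max() + 3 * bw, n_grid)
    return VelocityDensity(grid=grid, density=kde(grid), bandwidth=bw)


_PROMINENCE_FRAC = 0.05  # a mode must rise 5% of the global maximum


def _mode_indices(density: VelocityDensity) -> np.ndarray:
    peaks, _ = find_peaks(
        density.density, prominence=_PROMINENCE_FRAC * float(np.max(density.density))
    )
    return peaks


def count_modes(density: VelocityDensity) -> int:
    """Number of local maxima with prominence ≥ 5% of the global maximum;
    a peakless (flat or monotone) density counts as one mode."""
    return max(1, len(_mode_indices(density)))


def mode_velocities(density: VelocityDensity) -> np.ndarray:
    """Velocities of the detected modes (global maximum if none qualify)."""
    idx = _mode_indices(density)
    if len(idx) == 0:
        idx = np.array([int(np.argmax(density.density))])
    return density.grid[idx]


def has_negative_mode(density: VelocityDensity) -> bool:
    return bool(np.any(mode_velocities(density) < 0.0))


#: Initial GDP-seed length (subunits) for steady-state velocity measurement.
#: Long enough (~60 μm) that macroscopic shrinkage phases run at the full
#: depolymerisation speed for the whole trace instead of being truncated at
#: zero length, which would smear the negative velocity mode.
MEASUREMENT_SEED_N_D = 100_000


def ensemble_velocities(
    params: KineticParams,
    C: float,
    T_window: float,
    n_filaments: int,
    duration: float,
    burn_in: float = 50.0,
    seed: int = 0,
    sample_dt: float = 1.0,
    init_n_D: int = MEASUREMENT_SEED_N_D,
    init_n_T: int = 50,
) -> VelocitySamples:
    """Pooled coarse velocities from a fresh constant-C ensemble."""
    protocol = ConcentrationProtocol(kind="constant", C0=C)
    config = SimConfig(
        duration=duration,
        sample_dt=sample_dt,
        seed=0,
        init_n_D=init_n_D,
        init_n_T=init_n_T,
    )
    traces = simulate_ensemble(params, protocol, config, n_filaments, seed)
    return pooled_velocities(traces, T_window, burn_in)


def mean_velocity_curve(
    params: KineticParams,
    C_grid: np.ndarray,
    T_window: float,
    n_filaments: int = 200,
    duration: float | None = None,
    burn_in: float = 50.0,
    seed: int = 0,
) -> list[tuple[float, CumulantSummary]]:
    """⟨v⟩ and higher cumulants per concentration, independent ensembles."""
    C_grid = np.asarray(C_grid, dtype=float)
    if np.any(np.diff(C_grid) < 0):
        raise ValueError("C_grid must be sorted ascending")
    if duration is None:
        duration = burn_in + 2 * T_window
    seeds = np.random.SeedSequence(seed).generate_state(len(C_grid)) & 0x7FFFFFFF
    out = []
    for C, s in zip(C_grid, seeds):
        samples = ensemble_velocities(
            params, float(C), T_window, n_filaments, duration, burn_in, int(s)
        )
        out.append((float(C), cumulants(samples)))
    return out


def _sign_call(
    params, C, T_window, n_filaments, duration, burn_in, seed, max_scale
):
    """Sign of ⟨v⟩(C) with SEM-aware doubling: a call needs |⟨v⟩| > 2 SEM,
    else the ensemble is doubled (up to ``max_scale``x)."""
    n = n_filaments
    rep = 0
    while True:
        samples = ensemble_velocities(
            params, C, T_window, n, duration, burn_in, seed + rep
        )
        summ = cumulants(samples)
        if abs(summ.mean_v) > 2.0 * summ.se_mean or n >= max_scale * n_filaments:
            return 1.0 if summ.mean_v > 0 else -1.0
        n *= 2
        rep += 1


def critical_concentration(
    params: KineticParams,
    T_window: float,
    mode: str = "zero-crossing",
    bracket: tuple[float, float] = (5.0, 15.0),
    n_filaments: int = 200,
    duration: float | None = None,
    burn_in: float = 50.0,
    tol: float = 0.1,
    seed: int = 0,
    max_scale: int = 8,
    check_bracket: bool = True,
) -> CriticalConcentration:
    """Critical concentration by stochastic bisection.

    ``mode="zero-crossing"``: C where the ensemble-mean coarse velocity
    changes sign.  ``mode="coexistence-edge"``: smallest C at which p(v)
    (at window ``T_window``) has lost its negative mode — the upper edge of
    the growth/shrinkage coexistence region.
    """
    lo, hi = float(bracket[0]), float(bracket[1])
    if lo >= hi:
        raise ValueError("bracket must satisfy lo < hi")
    if duration is None:
        duration = burn_in + (2 * T_window if mode == "zero-crossing" else 400.0)

    if mode == "zero-crossing":
        def predicate(C, s):  # True once past the transition (growing)
            return _sign_call(
                params, C, T_window, n_filaments, duration, burn_in, s, max_scale
            ) > 0
    elif mode == "coexistence-edge":
        def predicate(C, s):  # True once the negative mode is gone
            samples = ensemble_velocities(
                params, C, T_window, n_filaments, duration, burn_in, s
            )
            return not has_negative_mode(velocity_distribution(samples))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    seeds = iter(
        int(s) for s in np.random.SeedSequence(seed).generate_state(64) & 0x7FFFFFFF
    )
    if check_bracket:
        if predicate(lo, next(seeds)):
            raise BracketingError(f"lower bracket C={lo} is already past the transition")
        if not predicate(hi, next(seeds)):
            raise BracketingError(f"upper bracket C={hi} is below the transition")
    while hi - lo > 2 * tol:
        mid = 0.5 * (lo + hi)
        if predicate(mid, next(seeds)):
            hi = mid
        else:
            lo = mid
    return CriticalConcentration(
        estimate=0.5 * (lo + hi), half_width=0.5 * (hi - lo), mode=mode
    )


def velocity_jump(
    params: KineticParams,
    C_star: float,
    dC: float,
    T_window: float,
    n_filaments: int = 200,
    duration: float | None = None,
    burn_in: float = 50.0,
    seed: int = 0,
) -> tuple[float, float]:
    """|⟨v⟩(C*+dC) − ⟨v⟩(C*−dC)| with the propagated standard error."""
    if dC <= 0:
        raise ValueError("dC must be > 0")
    if duration is None:
        duration = burn_in + 2 * T_window
    hi = cumulants(
        ensemble_velocities(
            params, C_star + dC, T_window, n_filaments, duration, burn_in, seed
        )
    )
    lo = cumulants(
        ensemble_velocities(
            params, C_star - dC, T_window, n_filaments, duration, burn_in, seed + 1
        )
    )
    jump = abs(hi.mean_v - lo.mean_v)
    se = math.hypot(hi.se_mean, lo.se_mean)
    return jump, se


def _ramp_leg(
    params, C_start, C_end, gamma_signed, n_filaments, seed, t_hold, bin_edges,
    sample_dt,
):
    duration = t_hold + abs((C_end - C_start) / gamma_signed)
    protocol = ConcentrationProtocol(
        kind="ramp",
        C0=C_start,
        gamma=gamma_signed,
        C_min=min(C_start, C_end),
        C_max=max(C_start, C_end),
        t_hold=t_hold,
    )
    config = SimConfig(
        duration=duration,
        sample_dt=sample_dt,
        seed=0,
        init_n_D=MEASUREMENT_SEED_N_D,
        init_n_T=50,
    )
    traces = simulate_ensemble(params, protocol, config, n_filaments, seed)
    sums = np.zeros(len(bin_edges) - 1)
    counts = np.zeros(len(bin_edges) - 1, dtype=np.int64)
    for tr in traces:
        v = np.diff(tr.lengths_nm) / sample_dt / 1000.0
        t_mid = tr.times[:-1] + 0.5 * sample_dt
        c_mid = protocol.concentration(t_mid)
        which = np.digitize(c_mid, bin_edges) - 1
        ok = (which >= 0) & (which < len(sums))
        np.add.at(sums, which[ok], v[ok])
        np.add.at(counts, which[ok], 1)
    with np.errstate(invalid="ignore"):
        vbar = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return vbar, counts


def hysteresis_loop(
    params: KineticParams,
    C_low: float,
    C_high: float,
    gamma: float,
    n_filaments: int = 100,
    seed: int = 0,
    bin_width: float = 0.25,
    t_hold: float = 50.0,
    sample_dt: float = 1.0,
) -> HysteresisResult:
    """Ramp-up and ramp-down velocity curves at finite rate ``gamma``.

    Each leg starts from an ensemble equilibrated at its end of the
    concentration range (constant-C hold of ``t_hold``), then ramps across
    [C_low, C_high] at ±gamma.  Instantaneous velocities are averaged in
    concentration bins of ``bin_width``; ``loop_area = |∫(v_up − v_down)dC|``.
    """
    if not C_low < C_high:
        raise ValueError("need C_low < C_high")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    edges = np.arange(C_low, C_high + bin_width * 0.5, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    v_up, n_up = _ramp_leg(
        params, C_low, C_high, +gamma, n_filaments, seed, t_hold, edges, sample_dt
    )
    v_dn, n_dn = _ramp_leg(
        params, C_high, C_low, -gamma, n_filaments, seed + 1, t_hold, edges, sample_dt
    )
    ok = (n_up > 0) & (n_dn > 0)
    area = abs(np.trapezoid((v_up - v_dn)[ok], centers[ok])) if ok.sum() >= 2 else 0.0
    return HysteresisResult(
        c_grid=centers, v_up=v_up, v_down=v_dn, loop_area=float(area), gamma=gamma
    )
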