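"""Exact stochastic simulation of single-microtubule dynamic instability.

The model: a single coarse-grained filament in a bath of GTP-tubulin at
concentration ``C``.  Subunits attach to a GTP-bound tip at rate ``u = k*C``
and to a GDP-bound tip at the (usually much lower) rate ``u' = k'*C``;
the tip subunit detaches at ``w_T`` (GTP) or ``w_D`` (GDP, with
``w_T << w_D``); and any GTP subunit anywhere in the filament hydrolyses to
GDP at a uniform per-subunit rate ``r`` (random hydrolysis).  The interplay
of the stabilising GTP cap, interior GTP remnants, and the reduced
polymerisation onto GDP tips (``k'/k`` small) produces dynamic instability:
alternating growth phases and rapid-shrinkage catastrophes.

Two simulation surfaces are provided:

* a transparent per-event API (:class:`FilamentState`, :func:`compute_rates`,
  :func:`gillespie_step`) suitable for small exact studies, and
* :func:`simulate_trace` / :func:`simulate_ensemble`, which run a compiled
  kernel and return uniformly sampled length-vs-time traces (kymographs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterator, Sequence

import numpy as np

from . import _kernel

__all__ = [
    "DELTA_NM",
    "KineticParams",
    "ConcentrationProtocol",
    "SimConfig",
    "FilamentState",
    "EventRates",
    "Trace",
    "compute_rates",
    "gillespie_step",
    "simulate_trace",
    "simulate_ensemble",
    "spawn_seeds",
]

#: Filament length gained per subunit, in nm.  One 8-nm tubulin dimer layer
#: distributed over the 13 protofilaments that the single-track model
#: coarse-grains away.
DELTA_NM = 8.0 / 13.0


@dataclass(frozen=True)
class KineticParams:
    """Microscopic rate constants of the random-hydrolysis model.

    Defaults are the experimentally motivated set used throughout:
    k = 3.2 μM⁻¹s⁻¹, w_T = 24 s⁻¹, w_D = 290 s⁻¹, r = 0.5 s⁻¹.
    """

    k: float = 3.2            # attachment onto a GTP tip, μM⁻¹ s⁻¹
    k_prime: float = 3.2      # attachment onto a GDP tip, μM⁻¹ s⁻¹
    w_T: float = 24.0         # GTP-subunit detachment, s⁻¹
    w_D: float = 290.0        # GDP-subunit detachment, s⁻¹
    r_hyd: float = 0.5        # hydrolysis per GTP subunit, s⁻¹
    delta: float = DELTA_NM   # nm of length per subunit

    def __post_init__(self) -> None:
        for name in ("k", "k_prime", "w_T", "w_D", "r_hyd"):
            if getattr(self, name) < 0:
                raise ValueError(f"rate {name!r} must be >= 0")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")

    @classmethod
    def with_ratio(cls, kratio: float, **kwargs) -> "KineticParams":
        """Default parameter set with ``k' = kratio * k``."""
        base = cls(**kwargs)
        return cls(
            k=base.k,
            k_prime=kratio * base.k,
            w_T=base.w_T,
            w_D=base.w_D,
            r_hyd=base.r_hyd,
            delta=base.delta,
        )

    @property
    def kratio(self) -> float:
        return self.k_prime / self.k if self.k > 0 else math.nan


@dataclass(frozen=True)
class ConcentrationProtocol:
    """Free-tubulin concentration as a function of time.

    ``C(t) = clamp(C0 + gamma * max(0, t - t_hold), C_min, C_max)``.
    ``t_hold`` keeps the concentration at ``C0`` for an initial
    equilibration window before a ramp starts.
    """

    kind: str = "constant"      # "constant" | "ramp"
    C0: float = 10.0            # μM
    gamma: float = 0.0          # signed ramp rate, μM s⁻¹
    C_min: float = 0.0          # μM
    C_max: float = math.inf     # μM
    t_hold: float = 0.0         # s

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "ramp"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.C0 < 0 or self.C_min < 0:
            raise ValueError("concentrations must be >= 0")
        if self.kind == "constant" and self.gamma != 0.0:
            raise ValueError("constant protocol requires gamma == 0")

    def concentration(self, t: float | np.ndarray) -> float | np.ndarray:
        tau = np.maximum(0.0, np.asarray(t, dtype=float) - self.t_hold)
        c = np.clip(self.C0 + self.gamma * tau, self.C_min, self.C_max)
        return float(c) if np.isscalar(t) else c


@dataclass(frozen=True)
class SimConfig:
    duration: float                # simulated time, s
    sample_dt: float = 1.0         # trace sampling interval, s
    seed: int = 0
    init_n_D: int = 2000           # initial GDP seed
    init_n_T: int = 50             # initial GTP cap
    stop_on_empty: bool = False

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.sample_dt <= 0:
            raise ValueError("duration and sample_dt must be > 0")
        if self.init_n_D < 0 or self.init_n_T < 0:
            raise ValueError("initial subunit counts must be >= 0")


@dataclass
class EventRates:
    """Propensities (s⁻¹) of the three event channels."""

    attach: float
    detach: float
    hydrolyze_total: float

    @property
    def total(self) -> float:
        return self.attach + self.detach + self.hydrolyze_total


@dataclass
class FilamentState:
    """Ordered subunit sequence from seed end to tip; 'T' = GTP, 'D' = GDP."""

    subunits: list[str] = field(default_factory=list)
    t_now: float = 0.0

    @classmethod
    def initial(cls, n_D: int, n_T: int) -> "FilamentState":
        return cls(subunits=["D"] * n_D + ["T"] * n_T)

    @property
    def n_total(self) -> int:
        return len(self.subunits)

    @property
    def n_T(self) -> int:
        return self.subunits.count("T")

    @property
    def tip(self) -> str | None:
        return self.subunits[-1] if self.subunits else None


def compute_rates(state: FilamentState, params: KineticParams, C: float) -> EventRates:
    """Event propensities for the current filament state at concentration C.

    An empty filament re-nucleates at the GTP-tip rate ``k*C``.
    """
    if C < 0:
        raise ValueError("concentration must be >= 0")
    if state.n_total == 0:
        return EventRates(attach=params.k * C, detach=0.0, hydrolyze_total=0.0)
    if state.tip == "T":
        attach, detach = params.k * C, params.w_T
    else:
        attach, detach = params.k_prime * C, params.w_D
    return EventRates(
        attach=attach, detach=detach, hydrolyze_total=params.r_hyd * state.n_T
    )


def gillespie_step(
    state: FilamentState, rates: EventRates, rng: np.random.Generator
) -> tuple[str, float]:
    """Draw one exact-SSA event and apply it to ``state`` in place.

    Returns ``(event, waiting_time)`` with event in
    {"attach", "detach", "hydrolyze"}.  Raises if no event is possible.
    """
    total = rates.total
    if total <= 0:
        raise RuntimeError("absorbing state: total propensity is zero")
    wait = rng.exponential(1.0 / total)
    x = rng.random() * total
    if x < rates.attach:
        state.subunits.append("T")
        event = "attach"
    elif x < rates.attach + rates.detach:
        state.subunits.pop()
        event = "detach"
    else:
        t_positions = [i for i, s in enumerate(state.subunits) if s == "T"]
        pos = t_positions[rng.integers(len(t_positions))]
        state.subunits[pos] = "D"
        event = "hydrolyze"
    state.t_now += wait
    return event, wait


@dataclass
class Trace:
    """Uniformly sampled length-vs-time record of one filament."""

    times: np.ndarray            # s, uniform at sample_dt
    lengths_nm: np.ndarray       # nm = n_total * delta
    metadata: dict
    censored: bool = False       # True if truncated (filament emptied)

    @property
    def sample_dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else math.nan

    @property
    def duration(self) -> float:
        return float(self.times[-1]) if len(self.times) else 0.0


def _protocol_c_bound(protocol: ConcentrationProtocol, duration: float) -> float:
    c_end = protocol.concentration(duration)
    return float(max(protocol.concentration(0.0), c_end))


def _metadata(params, protocol, config, seed) -> dict:
    return {
        "params": asdict(params),
        "protocol": {
            k: (v if math.isfinite(v) else None) if isinstance(v, float) else v
            for k, v in asdict(protocol).items()
        },
        "sim": asdict(config),
        "seed": int(seed),
    }


def simulate_trace(
    params: KineticParams,
    protocol: ConcentrationProtocol,
    config: SimConfig,
) -> Trace:
    """Run one filament with the compiled Gillespie kernel.

    Identical (params, protocol, config) give bit-identical traces.  If the
    filament empties under ``stop_on_empty`` the trace is truncated and
    flagged ``censored``.
    """
    n_samples = int(round(config.duration / config.sample_dt)) + 1
    c_ub = _protocol_c_bound(protocol, config.duration)
    init_total = config.init_n_D + config.init_n_T
    capacity = init_total + int(params.k * c_ub * config.duration * 1.2) + 1024

    c_max = protocol.C_max if math.isfinite(protocol.C_max) else 1e300
    for _ in range(8):
        lengths = np.zeros(n_samples, dtype=np.int64)
        counts = np.zeros(3, dtype=np.int64)
        status, n_filled = _kernel.run_kmc(
            int(config.seed) & 0x7FFFFFFF,
            float(config.duration),
            float(config.sample_dt),
            n_samples,
            params.k,
            params.k_prime,
            params.w_T,
            params.w_D,
            params.r_hyd,
            protocol.C0,
            protocol.gamma,
            protocol.C_min,
            c_max,
            protocol.t_hold,
            config.init_n_D,
            config.init_n_T,
            config.stop_on_empty,
            capacity,
            lengths,
            counts,
        )
        if status != _kernel.OVERFLOW:
            break
        capacity *= 2
    else:  # pragma: no cover - would need pathological growth
        raise RuntimeError("filament outgrew the simulation buffer repeatedly")

    censored = status in (_kernel.EMPTIED, _kernel.ABSORBED)
    n_keep = n_filled if censored else n_samples
    times = np.arange(n_keep, dtype=float) * config.sample_dt
    trace = Trace(
        times=times,
        lengths_nm=lengths[:n_keep].astype(float) * params.delta,
        metadata=_metadata(params, protocol, config, config.seed),
        censored=censored,
    )
    trace.metadata["event_counts"] = {
        "attach": int(counts[0]),
        "detach": int(counts[1]),
        "hydrolyze": int(counts[2]),
    }
    return trace


def spawn_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic independent per-filament seeds (< 2**31)."""
    ss = np.random.SeedSequence(int(master_seed))
    return (ss.generate_state(n, dtype=np.uint32) & 0x7FFFFFFF).astype(np.int64)


def simulate_ensemble(
    params: KineticParams,
    protocol: ConcentrationProtocol,
    config: SimConfig,
    n_filaments: int,
    master_seed: int,
) -> list[Trace]:
    """Independent filaments with per-filament streams spawned from
    ``master_seed``; the result does not depend on execution order."""
    if n_filaments < 1:
        raise ValueError("n_filaments must be >= 1")
    seeds = spawn_seeds(master_seed, n_filaments)
    traces = []
    for s in seeds:
        cfg = SimConfig(
            duration=config.duration,
            sample_dt=config.sample_dt,
            seed=int(s),
            init_n_D=config.init_n_D,
            init_n_T=config.init_n_T,
            stop_on_empty=config.stop_on_empty,
        )
        traces.append(simulate_trace(params, protocol, cfg))
    return traces
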