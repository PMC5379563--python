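"""Engine-level checks: propensities, event bookkeeping, closed-form limits,
and an exact master-equation oracle on a length-capped toy filament."""

import itertools

import numpy as np
import pytest

from mtswitch.kmc_engine import (
    DELTA_NM,
    ConcentrationProtocol,
    EventRates,
    FilamentState,
    KineticParams,
    SimConfig,
    compute_rates,
    gillespie_step,
    simulate_ensemble,
    simulate_trace,
)


class TestComputeRates:
    def test_gtp_tip_default_rates(self, default_params):
        state = FilamentState(subunits=["D"] * 5 + ["T"] * 5)
        r = compute_rates(state, default_params, C=10.0)
        assert r.attach == pytest.approx(32.0)
        assert r.detach == pytest.approx(24.0)
        assert r.hydrolyze_total == pytest.approx(2.5)

    def test_gdp_tip_rates(self):
        params = KineticParams(k_prime=0.032)
        state = FilamentState(subunits=["T", "D"])
        r = compute_rates(state, params, C=10.0)
        assert r.attach == pytest.approx(0.32)
        assert r.detach == pytest.approx(290.0)

    def test_dead_gdp_tip(self):
        params = KineticParams(k_prime=0.0)
        state = FilamentState(subunits=["D"])
        assert compute_rates(state, params, C=50.0).attach == 0.0

    def test_empty_filament_nucleates_like_gtp_tip(self, default_params):
        r = compute_rates(FilamentState(), default_params, C=5.0)
        assert r.attach == pytest.approx(default_params.k * 5.0)
        assert r.detach == 0.0
        assert r.hydrolyze_total == 0.0

    def test_negative_concentration_rejected(self, default_params):
        with pytest.raises(ValueError):
            compute_rates(FilamentState(subunits=["T"]), default_params, C=-1.0)


class TestGillespieStep:
    def test_single_open_channel(self):
        params = KineticParams(k_prime=0.0, r_hyd=0.5)
        state = FilamentState(subunits=["D", "D"])
        rates = compute_rates(state, params, C=10.0)
        rng = np.random.default_rng(0)
        event, wait = gillespie_step(state, rates, rng)
        assert event == "detach"
        assert wait > 0
        assert state.n_total == 1

    def test_hydrolysis_bookkeeping(self):
        state = FilamentState(subunits=["T", "D", "T", "T"])
        rates = EventRates(attach=0.0, detach=0.0, hydrolyze_total=1.5)
        gillespie_step(state, rates, np.random.default_rng(1))
        assert state.n_T == 2
        assert state.n_total == 4

    def test_event_fractions_match_propensities(self):
        rates = EventRates(attach=3.0, detach=2.0, hydrolyze_total=5.0)
        state = FilamentState(subunits=["T"] * 2000)
        rng = np.random.default_rng(2)
        n = 3000
        counts = {"attach": 0, "detach": 0, "hydrolyze": 0}
        for _ in range(n):
            event, _ = gillespie_step(state, rates, rng)
            counts[event] += 1
        for name, p in [("attach", 0.3), ("detach", 0.2), ("hydrolyze", 0.5)]:
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(counts[name] - n * p) < 3 * sigma

    def test_absorbing_state_raises(self):
        state = FilamentState()
        with pytest.raises(RuntimeError):
            gillespie_step(state, EventRates(0.0, 0.0, 0.0), np.random.default_rng(3))


class TestSimulateTrace:
    def test_birth_death_growth_slope(self):
        # r_hyd=0, k'=k: pure birth-death of GTP subunits, drift (kC-w_T)*delta
        params = KineticParams(r_hyd=0.0)
        trace = simulate_trace(
            params, ConcentrationProtocol(C0=10.0), SimConfig(duration=400.0, seed=11)
        )
        slope = np.polyfit(trace.times, trace.lengths_nm, 1)[0]
        expected = (params.k * 10.0 - params.w_T) * DELTA_NM  # ~4.92 nm/s
        # diffusive error on the fitted slope over duration t: sqrt(2D/t)-ish
        sigma = np.sqrt((params.k * 10.0 + params.w_T) * DELTA_NM**2 / 400.0) * 3
        assert slope == pytest.approx(expected, abs=3 * sigma)
        assert trace.metadata["event_counts"]["hydrolyze"] == 0

    def test_all_gdp_shrinkage_speed(self, default_params):
        trace = simulate_trace(
            default_params,
            ConcentrationProtocol(C0=0.0),
            SimConfig(duration=4.0, sample_dt=0.1, seed=12, init_n_D=3000, init_n_T=0),
        )
        slope = np.polyfit(trace.times, trace.lengths_nm, 1)[0]
        assert slope == pytest.approx(-default_params.w_D * DELTA_NM, rel=0.10)

    def test_same_seed_identical_traces(self, default_params):
        cfg = SimConfig(duration=60.0, seed=99)
        prot = ConcentrationProtocol(C0=9.0)
        t1 = simulate_trace(default_params, prot, cfg)
        t2 = simulate_trace(default_params, prot, cfg)
        assert np.array_equal(t1.lengths_nm, t2.lengths_nm)

    def test_stop_on_empty_truncates_and_flags(self, default_params):
        trace = simulate_trace(
            default_params,
            ConcentrationProtocol(C0=0.0),
            SimConfig(duration=100.0, seed=13, init_n_D=50, init_n_T=0,
                      stop_on_empty=True),
        )
        assert trace.censored
        assert trace.duration < 100.0

    def test_conservation_of_event_counts(self, growth_trace):
        counts = growth_trace.metadata["event_counts"]
        n0 = (
            growth_trace.metadata["sim"]["init_n_D"]
            + growth_trace.metadata["sim"]["init_n_T"]
        )
        n_end = round(growth_trace.lengths_nm[-1] / DELTA_NM)
        assert counts["attach"] - counts["detach"] == n_end - n0

    def test_ramp_concentration_clamps(self):
        prot = ConcentrationProtocol(
            kind="ramp", C0=8.0, gamma=0.2, C_min=8.0, C_max=10.0, t_hold=5.0
        )
        assert prot.concentration(0.0) == 8.0
        assert prot.concentration(5.0) == 8.0
        assert prot.concentration(10.0) == pytest.approx(9.0)
        assert prot.concentration(1000.0) == 10.0


class TestEnsemble:
    def test_reproducible_from_master_seed(self, default_params):
        cfg = SimConfig(duration=30.0)
        prot = ConcentrationProtocol(C0=10.0)
        a = simulate_ensemble(default_params, prot, cfg, 2, master_seed=5)
        b = simulate_ensemble(default_params, prot, cfg, 2, master_seed=5)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.lengths_nm, tb.lengths_nm)
        assert not np.array_equal(a[0].lengths_nm, a[1].lengths_nm)

    def test_ensemble_mean_slope_birth_death(self):
        params = KineticParams(r_hyd=0.0)
        cfg = SimConfig(duration=100.0)
        traces = simulate_ensemble(
            params, ConcentrationProtocol(C0=10.0), cfg, 60, master_seed=8
        )
        finals = np.array([tr.lengths_nm[-1] - tr.lengths_nm[0] for tr in traces])
        v = finals / 100.0
        expected = (params.k * 10.0 - params.w_T) * DELTA_NM
        sem = v.std(ddof=1) / np.sqrt(len(v))
        assert abs(v.mean() - expected) < 3 * sem

    def test_filament_increments_uncorrelated(self, default_params):
        cfg = SimConfig(duration=100.0)
        traces = simulate_ensemble(
            default_params, ConcentrationProtocol(C0=10.0), cfg, 2, master_seed=17
        )
        da = np.diff(traces[0].lengths_nm)
        db = np.diff(traces[1].lengths_nm)
        r = np.corrcoef(da, db)[0, 1]
        assert abs(r) < 3.5 / np.sqrt(len(da))


# ---------------------------------------------------------------------------
# Master-equation oracle: toy model with length capped at 3 subunits.  The
# stationary distribution over all T/D-sequence microstates from a long
# Gillespie run must match the directly enumerated stationary solution of
# the generator matrix.

TOY = KineticParams(k=1.0, k_prime=0.4, w_T=1.2, w_D=2.0, r_hyd=0.7)
TOY_C = 1.5
CAP = 3


def _toy_states():
    states = [()]
    for n in range(1, CAP + 1):
        states.extend(itertools.product("TD", repeat=n))
    return states


def _toy_generator(states):
    index = {s: i for i, s in enumerate(states)}
    Q = np.zeros((len(states), len(states)))

    def add(src, dst, rate):
        Q[index[src], index[dst]] += rate

    for s in states:
        rates = compute_rates(FilamentState(subunits=list(s)), TOY, TOY_C)
        if len(s) < CAP:
            add(s, s + ("T",), rates.attach)
        if len(s) > 0:
            add(s, s[:-1], rates.detach)
        for i, x in enumerate(s):
            if x == "T":
                add(s, s[:i] + ("D",) + s[i + 1 :], TOY.r_hyd)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def test_capped_toy_matches_enumerated_stationary_distribution():
    states = _toy_states()
    index = {s: i for i, s in enumerate(states)}
    Q = _toy_generator(states)
    # stationary distribution: left null vector of Q
    w, vec = np.linalg.eig(Q.T)
    pi = np.real(vec[:, np.argmin(np.abs(w))])
    pi = pi / pi.sum()
    assert np.all(pi > -1e-12)

    occupancy = np.zeros(len(states))
    state = FilamentState()
    rng = np.random.default_rng(12345)
    for _ in range(500_000):
        rates = compute_rates(state, TOY, TOY_C)
        if state.n_total >= CAP:
            rates.attach = 0.0  # cap: attachment blocked at maximum length
        key_before = tuple(state.subunits)
        _, wait = gillespie_step(state, rates, rng)
        occupancy[index[key_before]] += wait
    occupancy /= occupancy.sum()

    tv = 0.5 * np.abs(occupancy - pi).sum()
    assert tv < 0.02
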