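"""JIT-compiled Gillespie kernel for the single-filament model.

The kernel operates on flat integer arrays: the filament is a stack of
subunit chemical states (1 = GTP, 0 = GDP) plus an index set of the GTP
positions so that random-hydrolysis target selection and tip bookkeeping
are O(1) per event.  The Python-facing state machinery lives in
``kmc_engine``; this module is an implementation detail.
"""

import numpy as np
from numba import njit

# status codes returned by the kernel
OK = 0
EMPTIED = 1          # filament reached zero length with stop_on_empty set
ABSORBED = 2         # total propensity hit zero (no event possible)
OVERFLOW = 3         # capacity exhausted; caller retries with a larger buffer


@njit(cache=True)
def run_kmc(
    seed,
    duration,
    sample_dt,
    n_samples,
    k_T,
    k_D,
    w_T,
    w_D,
    r_hyd,
    C0,
    gamma,
    C_min,
    C_max,
    t_hold,
    init_n_D,
    init_n_T,
    stop_on_empty,
    capacity,
    lengths_out,
    counts_out,
):
    """Simulate one filament; fill ``lengths_out`` with subunit counts.

    Returns (status, n_filled).  ``counts_out`` receives the event tallies
    (attach, detach, hydrolysis).  Concentration follows
    C(t) = clamp(C0 + gamma * max(0, t - t_hold), C_min, C_max).
    """
    np.random.seed(seed)

    states = np.zeros(capacity, dtype=np.uint8)
    t_pos = np.empty(capacity, dtype=np.int64)
    pos_in_t = np.full(capacity, -1, dtype=np.int64)

    n_total = 0
    n_T = 0
    for _ in range(init_n_D):
        states[n_total] = 0
        n_total += 1
    for _ in range(init_n_T):
        states[n_total] = 1
        t_pos[n_T] = n_total
        pos_in_t[n_total] = n_T
        n_T += 1
        n_total += 1

    t = 0.0
    next_i = 0
    lengths_out[next_i] = n_total
    next_i += 1

    status = OK
    while True:
        # current concentration
        tau = t - t_hold
        if tau < 0.0:
            tau = 0.0
        C = C0 + gamma * tau
        if C < C_min:
            C = C_min
        elif C > C_max:
            C = C_max

        if n_total == 0:
            if stop_on_empty:
                status = EMPTIED
                break
            attach = k_T * C  # nucleation treated as a GTP-tip-like site
            detach = 0.0
        else:
            if states[n_total - 1] == 1:
                attach = k_T * C
                detach = w_T
            else:
                attach = k_D * C
                detach = w_D
        hyd = r_hyd * n_T
        total = attach + detach + hyd
        if total <= 0.0:
            status = ABSORBED
            break

        t_new = t + (-np.log(np.random.random()) / total)

        # record samples passed by this waiting interval (pre-event length)
        while next_i < n_samples and next_i * sample_dt < t_new:
            lengths_out[next_i] = n_total
            next_i += 1
        if t_new >= duration:
            t = duration
            break
        t = t_new

        x = np.random.random() * total
        if x < attach:
            if n_total >= capacity:
                return OVERFLOW, next_i
            states[n_total] = 1
            t_pos[n_T] = n_total
            pos_in_t[n_total] = n_T
            n_T += 1
            n_total += 1
            counts_out[0] += 1
        elif x < attach + detach:
            pos = n_total - 1
            if states[pos] == 1:
                j = pos_in_t[pos]
                n_T -= 1
                last = t_pos[n_T]
                t_pos[j] = last
                pos_in_t[last] = j
                pos_in_t[pos] = -1
            n_total -= 1
            counts_out[1] += 1
        else:
            j = np.int64(np.random.random() * n_T)
            if j >= n_T:
                j = n_T - 1
            pos = t_pos[j]
            states[pos] = 0
            n_T -= 1
            last = t_pos[n_T]
            t_pos[j] = last
            pos_in_t[last] = j
            pos_in_t[pos] = -1
            counts_out[2] += 1

    if status == OK:
        while next_i < n_samples:
            lengths_out[next_i] = n_total
            next_i += 1
    return status, next_i
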