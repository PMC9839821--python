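"""Numba-jitted Gillespie kernels.

All kernels consume the compiled network encoding produced by
``ReactionNetwork.arrays()``: stoichiometry ``S`` (n_reactions x n_species),
rate constants ``c`` and up to two propensity factors per reaction, each a
function of one species count selected by ``(f_spec, f_kind)``:

    kind 1: N_s        kind 2: (N_s - 1)/2        kind 3: omega - N_s

Waiting times are exponential with rate equal to the total propensity and the
next reaction is chosen proportionally to its propensity (direct method).
Each kernel seeds its own Mersenne stream, so a call is a pure function of
its arguments.

Termination reason codes: 0 = t_max reached, 1 = absorbed (total propensity
zero), 2 = event-capacity limit hit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

REASON_TMAX = 0
REASON_ABSORBED = 1
REASON_CAPACITY = 2


@njit(cache=True, inline="always")
def _fill_propensities(x, omega, c, f_spec, f_kind, a):
    a0 = 0.0
    for r in range(c.shape[0]):
        ar = c[r]
        for k in range(2):
            kind = f_kind[r, k]
            if kind == 1:
                ar *= x[f_spec[r, k]]
            elif kind == 2:
                ar *= 0.5 * (x[f_spec[r, k]] - 1.0)
            elif kind == 3:
                ar *= omega - x[f_spec[r, k]]
        if ar < 0.0:
            ar = 0.0
        a[r] = ar
        a0 += ar
    return a0


@njit(cache=True, inline="always")
def _draw_reaction(a, a0):
    u = np.random.random() * a0
    acc = 0.0
    r = 0
    for j in range(a.shape[0]):
        acc += a[j]
        if u < acc:
            r = j
            break
        r = j
    return r


@njit(cache=True, inline="always")
def _exp_waiting_time(a0):
    u = np.random.random()
    while u <= 0.0:
        u = np.random.random()
    return -np.log(u) / a0


@njit(cache=True)
def run_trajectory(S, c, f_spec, f_kind, omega, x0, t_max, max_events, seed):
    """Full jump trajectory: (times, states, reason, t_end)."""
    np.random.seed(seed)
    ns = x0.shape[0]
    x = x0.copy()
    a = np.empty(c.shape[0])
    times = np.empty(max_events + 1)
    states = np.empty((max_events + 1, ns), dtype=np.int64)
    times[0] = 0.0
    states[0] = x
    t = 0.0
    n = 0
    reason = REASON_TMAX
    while True:
        a0 = _fill_propensities(x, omega, c, f_spec, f_kind, a)
        if a0 <= 0.0:
            reason = REASON_ABSORBED
            break
        dt = _exp_waiting_time(a0)
        if t + dt > t_max:
            t = t_max
            reason = REASON_TMAX
            break
        if n >= max_events:
            reason = REASON_CAPACITY
            break
        t += dt
        r = _draw_reaction(a, a0)
        for i in range(ns):
            x[i] += S[r, i]
        n += 1
        times[n] = t
        states[n] = x
    return times[: n + 1], states[: n + 1], reason, t


@njit(cache=True)
def first_extinction_batch(S, c, f_spec, f_kind, omega, x0, t_max, seeds):
    """First time any species count reaches zero, per replicate.

    Returns (times, species): species is the 0-based index that hit zero,
    or -1 if no extinction occurred before t_max (time then equals t_max).
    """
    nrep = seeds.shape[0]
    ns = x0.shape[0]
    a = np.empty(c.shape[0])
    t_out = np.empty(nrep)
    s_out = np.full(nrep, -1, dtype=np.int64)
    for k in range(nrep):
        np.random.seed(seeds[k])
        x = x0.copy()
        t = 0.0
        while True:
            a0 = _fill_propensities(x, omega, c, f_spec, f_kind, a)
            if a0 <= 0.0:
                break
            dt = _exp_waiting_time(a0)
            if t + dt > t_max:
                t = t_max
                break
            t += dt
            r = _draw_reaction(a, a0)
            hit = -1
            for i in range(ns):
                x[i] += S[r, i]
                if S[r, i] < 0 and x[i] == 0:
                    hit = i
            if hit >= 0:
                s_out[k] = hit
                break
        t_out[k] = t
    return t_out, s_out


@njit(cache=True)
def absorption_batch(S, c, f_spec, f_kind, omega, x0, t_max, seeds):
    """Run each replicate until total propensity vanishes (or t_max).

    Returns (t_end, reason, final_states, extinction_times) where
    ``extinction_times[k, i]`` is the first time species i reached zero
    (inf if it never did).
    """
    nrep = seeds.shape[0]
    ns = x0.shape[0]
    a = np.empty(c.shape[0])
    t_end = np.empty(nrep)
    reason = np.empty(nrep, dtype=np.int64)
    finals = np.empty((nrep, ns), dtype=np.int64)
    ext = np.full((nrep, ns), np.inf)
    for k in range(nrep):
        np.random.seed(seeds[k])
        x = x0.copy()
        t = 0.0
        for i in range(ns):
            if x[i] == 0:
                ext[k, i] = 0.0
        while True:
            a0 = _fill_propensities(x, omega, c, f_spec, f_kind, a)
            if a0 <= 0.0:
                reason[k] = REASON_ABSORBED
                break
            dt = _exp_waiting_time(a0)
            if t + dt > t_max:
                t = t_max
                reason[k] = REASON_TMAX
                break
            t += dt
            r = _draw_reaction(a, a0)
            for i in range(ns):
                x[i] += S[r, i]
                if S[r, i] < 0 and x[i] == 0 and ext[k, i] == np.inf:
                    ext[k, i] = t
        t_end[k] = t
        finals[k] = x
    return t_end, reason, finals, ext


@njit(cache=True, inline="always")
def _init_sides(x, orient, side):
    """Oriented side of each Poincare-section plane; on-plane states start at -1."""
    for i in range(3):
        d = orient * (x[(i + 1) % 3] - x[(i + 2) % 3])
        if d > 0:
            side[i] = 1
        else:
            side[i] = -1


@njit(cache=True)
def cycles_batch(S, c, f_spec, f_kind, omega, x0, t_max, seeds, n_cycles, orient):
    """Collect completed-circuit durations (cycle lengths) per replicate.

    A crossing of section P_i (plane N_{i+1} = N_{i+2} within the triangle
    where N_i >= max of the others) is recorded when the oriented coordinate
    orient*(N_{i+1} - N_{i+2}) changes from negative to nonnegative at a jump.
    A circuit visits the three sections in the cyclic order set by ``orient``;
    its duration is the time between successive anchor-section crossings after
    both other sections were crossed in order.
    """
    nrep = seeds.shape[0]
    a = np.empty(c.shape[0])
    out = np.full((nrep, n_cycles), np.nan)
    counts = np.zeros(nrep, dtype=np.int64)
    step = 1 if orient > 0 else 2  # cyclic increment of the section index
    side = np.empty(3, dtype=np.int64)
    for k in range(nrep):
        np.random.seed(seeds[k])
        x = x0.copy()
        t = 0.0
        _init_sides(x, orient, side)
        armed = False
        s0 = 0
        legs = 0
        t_anchor = 0.0
        # initial on-section event (e.g. start at (Omega, 0, 0) on P_1)
        for i in range(3):
            d = orient * (x[(i + 1) % 3] - x[(i + 2) % 3])
            if d == 0 and x[i] >= x[(i + 1) % 3] and x[i] >= x[(i + 2) % 3]:
                side[i] = 1
                armed = True
                s0 = i
                legs = 0
                t_anchor = 0.0
                break
        while counts[k] < n_cycles:
            a0 = _fill_propensities(x, omega, c, f_spec, f_kind, a)
            if a0 <= 0.0:
                break
            dt = _exp_waiting_time(a0)
            if t + dt > t_max:
                break
            t += dt
            r = _draw_reaction(a, a0)
            for i in range(3):
                x[i] += S[r, i]
            for i in range(3):
                i1 = (i + 1) % 3
                i2 = (i + 2) % 3
                d = orient * (x[i1] - x[i2])
                if side[i] < 0 and d >= 0:
                    side[i] = 1
                    if x[i] >= x[i1] and x[i] >= x[i2]:
                        # crossing of section i completed
                        if not armed:
                            armed = True
                            s0 = i
                            legs = 0
                            t_anchor = t
                        elif i == (s0 + step * (legs + 1)) % 3:
                            legs += 1
                            if legs == 3:
                                out[k, counts[k]] = t - t_anchor
                                counts[k] += 1
                                t_anchor = t
                                legs = 0
                elif side[i] > 0 and d < 0:
                    side[i] = -1
    return out, counts


@njit(cache=True)
def survivor_samples(S, c, f_spec, f_kind, omega, x0, seeds, n_samples, sample_dt,
                     burn_reaction_times, max_events):
    """Strided samples of the sole survivor's count after the second extinction.

    Each replicate is run until exactly one species remains nonzero, burned in
    for ``burn_reaction_times`` mean reaction times (measured at the extinction
    state), then the surviving count is recorded every ``sample_dt`` time
    units, which estimates the time-weighted stationary occupancy.

    Returns (survivor_index, samples[nrep, n_samples], ok_flags).
    """
    nrep = seeds.shape[0]
    ns = x0.shape[0]
    a = np.empty(c.shape[0])
    samples = np.zeros((nrep, n_samples), dtype=np.int64)
    surv_out = np.full(nrep, -1, dtype=np.int64)
    ok = np.zeros(nrep, dtype=np.int64)
    for k in range(nrep):
        np.random.seed(seeds[k])
        x = x0.copy()
        t = 0.0
        surv = -1
        t_next = np.inf
        got = 0
        events = 0
        while got < n_samples and events < max_events:
            a0 = _fill_propensities(x, omega, c, f_spec, f_kind, a)
            if a0 <= 0.0:
                break
            if surv < 0:
                nz = 0
                last = -1
                for i in range(ns):
                    if x[i] > 0:
                        nz += 1
                        last = i
                if nz == 1:
                    surv = last
                    t_next = t + burn_reaction_times / a0
            dt = _exp_waiting_time(a0)
            # record samples that fall inside the current holding interval
            while surv >= 0 and t_next <= t + dt and got < n_samples:
                samples[k, got] = x[surv]
                got += 1
                t_next += sample_dt
            t += dt
            r = _draw_reaction(a, a0)
            for i in range(ns):
                x[i] += S[r, i]
            events += 1
        surv_out[k] = surv
        ok[k] = 1 if got == n_samples else 0
    return surv_out, samples, ok


def warmup() -> None:
    """Compile all kernels on a tiny problem (one-time cost per process)."""
    S = np.array([[1], [-1]], dtype=np.int64)
    c = np.array([1.0, 1.0])
    f_spec = np.zeros((2, 2), dtype=np.int64)
    f_kind = np.array([[1, 0], [1, 0]], dtype=np.int64)
    x0 = np.array([1], dtype=np.int64)
    seeds = np.array([1], dtype=np.int64)
    run_trajectory(S, c, f_spec, f_kind, 0, x0, 0.1, 16, 1)
    first_extinction_batch(S, c, f_spec, f_kind, 0, x0, 0.1, seeds)
    absorption_batch(S, c, f_spec, f_kind, 0, x0, 0.1, seeds)
    S3 = np.zeros((1, 3), dtype=np.int64)
    S3[0, 0] = 1
    c3 = np.array([1.0])
    fs3 = np.zeros((1, 2), dtype=np.int64)
    fk3 = np.array([[0, 0]], dtype=np.int64)
    x3 = np.array([1, 0, 0], dtype=np.int64)
    cycles_batch(S3, c3, fs3, fk3, 0, x3, 0.1, seeds, 1, 1)
    survivor_samples(S, c, f_spec, f_kind, 0, x0, seeds, 1, 0.1, 1.0, 100)
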