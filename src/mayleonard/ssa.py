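"""Exact stochastic simulation (Gillespie direct method) and ensemble running.

The simulator is exact: waiting times are exponential with rate equal to the
total propensity and reactions fire with probability proportional to their
propensities.  Identical ``(network, initial, t_max, seed)`` always produce
an identical trajectory; ensemble replicate ``k`` uses the derived seed
``(base_seed + k) mod 2**31``, so replicates are order-independent.

Poincare-section crossings on the integer lattice use the discrete rule: with
``D = N_{i+1} - N_{i+2}`` and the model's fixed orientation, a crossing of
P_i occurs at a jump where the oriented ``D`` passes from negative to
nonnegative (a landing exactly on the plane counts as having crossed) and
additionally ``N_i >= max(N_{i+1}, N_{i+2})`` so that only the section's
triangle, not its mirror through the diagonal, registers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _engine
from .models import ReactionNetwork, _check_state
from .meanfield import section_orientation

__all__ = [
    "JumpTrajectory",
    "ExtinctionRecord",
    "CrossingRecord",
    "gillespie",
    "extinction_events",
    "section_crossings",
    "ensemble",
    "ensemble_first_extinction",
    "ensemble_cycles",
    "replicate_seeds",
]

_REASONS = {0: "t_max", 1: "absorbed", 2: "capacity"}


def replicate_seeds(base_seed: int, n_reps: int) -> np.ndarray:
    """Derived per-replicate seeds: (base + k) mod 2**31."""
    return (int(base_seed) + np.arange(n_reps, dtype=np.int64)) % (2**31)


@dataclass
class JumpTrajectory:
    """A jump process realization: state is piecewise constant between jumps."""

    times: np.ndarray          # jump times, starting at 0
    states: np.ndarray         # (n_jumps + 1, n_species), state after each jump
    t_end: float
    reason: str                # t_max | absorbed | stop_predicate
    seed: int
    network: ReactionNetwork

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def state_at(self, t: float) -> np.ndarray:
        """State at time t (right-continuous step function)."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return self.states[max(i, 0)]

    def to_csv(self, path) -> None:
        cols = [f"N{i + 1}" for i in range(self.states.shape[1])]
        df = pd.DataFrame(self.states, columns=cols)
        df.insert(0, "t", self.times)
        df.to_csv(path, index=False)


@dataclass
class ExtinctionRecord:
    """First-zero times per species (1-based indices), sorted by time."""

    events: list               # (species 1..n, time)
    survivors: tuple           # species (1-based) never reaching zero


@dataclass
class CrossingRecord:
    """Section crossing events (1-based section indices) and cycle lengths."""

    events: list               # (section 1..3, jump time)
    cycles: np.ndarray         # completed-circuit durations


def gillespie(net: ReactionNetwork, initial, t_max: float, seed: int,
              stop_predicate=None, max_events: int = 1 << 16) -> JumpTrajectory:
    """Exact SSA trajectory from ``initial`` until ``t_max``, absorption, or stop.

    ``stop_predicate`` is a function of the state vector; the trajectory is
    truncated at the first jump where it holds.  ``max_events`` is a capacity
    hint only: the run is transparently retried with a larger buffer.
    """
    x0 = _check_state(net, initial)
    if t_max <= 0:
        raise ValueError("t_max must be positive")
    S, c, fs, fk = net.arrays()
    w = net.engine_omega()
    hard_cap = 1 << 23
    while True:
        times, states, reason, t_end = _engine.run_trajectory(
            S, c, fs, fk, w, x0, float(t_max), int(max_events), int(seed) % (2**31)
        )
        if stop_predicate is not None:
            # identical seed reproduces the prefix, so checking the recorded
            # chunk before enlarging the buffer is exact
            hold = np.fromiter((bool(stop_predicate(s)) for s in states), dtype=bool)
            if hold.any():
                k = int(np.argmax(hold))
                return JumpTrajectory(times[: k + 1], states[: k + 1],
                                      float(times[k]), "stop_predicate",
                                      int(seed), net)
        if reason != _engine.REASON_CAPACITY:
            break
        if max_events >= hard_cap:
            raise RuntimeError(
                f"trajectory exceeded {hard_cap} events before t_max or stop; "
                "reduce t_max or supply a stop_predicate that triggers earlier"
            )
        max_events = min(4 * max_events, hard_cap)
    return JumpTrajectory(times, states, t_end, _REASONS[reason], int(seed), net)


def extinction_events(traj: JumpTrajectory) -> ExtinctionRecord:
    """First time each species count reaches zero (species never at zero omitted)."""
    events = []
    survivors = []
    for i in range(traj.states.shape[1]):
        zero = traj.states[:, i] == 0
        if zero.any():
            events.append((i + 1, float(traj.times[np.argmax(zero)])))
        else:
            survivors.append(i + 1)
    events.sort(key=lambda e: e[1])
    return ExtinctionRecord(events, tuple(survivors))


def section_crossings(traj: JumpTrajectory, omega: float) -> CrossingRecord:
    """Discrete Poincare-section crossings of a 3-species jump trajectory.

    ``omega`` must match the network bound for bounded networks; it fixes the
    section triangles' scale but the integer rule itself only uses the counts.
    """
    if traj.states.shape[1] != 3:
        raise ValueError("section crossings are defined for 3-species trajectories")
    if traj.network.state_bounds is not None and omega != traj.network.state_bounds:
        raise ValueError("omega does not match the network's state bound")
    orient = _trajectory_orientation(traj)
    events = []
    x = traj.states[0]
    side = np.where(orient * (np.roll(x, -1) - np.roll(x, -2)) > 0, 1, -1)
    for i in range(3):
        i1, i2 = (i + 1) % 3, (i + 2) % 3
        if x[i1] == x[i2] and x[i] >= max(x[i1], x[i2]):
            side[i] = 1
            events.append((i + 1, float(traj.times[0])))
            break
    for k in range(1, len(traj.times)):
        x = traj.states[k]
        for i in range(3):
            i1, i2 = (i + 1) % 3, (i + 2) % 3
            d = orient * (x[i1] - x[i2])
            if side[i] < 0 and d >= 0:
                side[i] = 1
                if x[i] >= max(x[i1], x[i2]):
                    events.append((i + 1, float(traj.times[k])))
            elif side[i] > 0 and d < 0:
                side[i] = -1
    from .meanfield import _circuit_durations

    return CrossingRecord(events, _circuit_durations(events, orient))


def _trajectory_orientation(traj: JumpTrajectory) -> int:
    return _trajectory_orientation_from_net(traj.network)


def ensemble(net: ReactionNetwork, initial, n_reps: int, base_seed: int,
             reducers: dict, t_max: float, **gillespie_kwargs):
    """Run ``n_reps`` seeded trajectories and apply named reducers to each.

    Returns ``(summary, raw)``: ``raw`` is a DataFrame with one row per
    replicate and one column per reducer (plus ``seed`` and ``error``);
    ``summary`` holds mean / variance / standard error per numeric reducer.
    A reducer failure flags the replicate rather than dropping it.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    seeds = replicate_seeds(base_seed, n_reps)
    rows = []
    for k, sd in enumerate(seeds):
        traj = gillespie(net, initial, t_max, int(sd), **gillespie_kwargs)
        row = {"rep": k, "seed": int(sd), "error": ""}
        for name, fn in reducers.items():
            try:
                row[name] = fn(traj)
            except Exception as exc:  # noqa: BLE001 - flagged, not dropped
                row[name] = np.nan
                row["error"] = f"{name}: {exc}"
        rows.append(row)
    raw = pd.DataFrame(rows)
    stats = {}
    for name in reducers:
        vals = pd.to_numeric(raw[name], errors="coerce").dropna()
        if len(vals):
            stats[name] = {
                "mean": vals.mean(),
                "var": vals.var(ddof=1) if len(vals) > 1 else 0.0,
                "se": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0,
                "n": len(vals),
            }
    summary = pd.DataFrame(stats).T
    return summary, raw


def ensemble_first_extinction(net: ReactionNetwork, initial, n_reps: int,
                              base_seed: int, t_max: float) -> pd.DataFrame:
    """First-extinction time and species for each replicate (fast path).

    ``species`` is 1-based; 0 marks replicates with no extinction by t_max.
    """
    x0 = _check_state(net, initial)
    S, c, fs, fk = net.arrays()
    seeds = replicate_seeds(base_seed, n_reps)
    t, s = _engine.first_extinction_batch(S, c, fs, fk, net.engine_omega(),
                                          x0, float(t_max), seeds)
    return pd.DataFrame({"rep": np.arange(n_reps), "seed": seeds,
                         "time": t, "species": np.where(s >= 0, s + 1, 0)})


def ensemble_cycles(net: ReactionNetwork, initial, n_reps: int, base_seed: int,
                    n_cycles: int, t_max: float) -> list[np.ndarray]:
    """Per-replicate completed cycle lengths (fast path; replicates may fall
    short of ``n_cycles`` if ``t_max`` is hit first)."""
    x0 = _check_state(net, initial)
    if net.n_species != 3:
        raise ValueError("cycle collection is defined for 3-species networks")
    orient = _trajectory_orientation_from_net(net)
    S, c, fs, fk = net.arrays()
    seeds = replicate_seeds(base_seed, n_reps)
    out, counts = _engine.cycles_batch(S, c, fs, fk, net.engine_omega(), x0,
                                       float(t_max), seeds, int(n_cycles), orient)
    return [out[k, : counts[k]] for k in range(n_reps)]


def _trajectory_orientation_from_net(net: ReactionNetwork) -> int:
    if net.params is None:
        raise ValueError(
            "network carries no model parameters; build it with "
            "mayleonard.models.build_*_network to enable section detection"
        )
    return section_orientation(net.params)
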