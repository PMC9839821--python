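"""Exact stochastic simulation: determinism, oracles, crossing detection."""

import numpy as np
import pytest

import mayleonard as ml
from mayleonard import ssa
from mayleonard.models import Reaction, ReactionNetwork

MIN = ml.MinimalParams(r=1, alpha=0.8, beta=1.3, omega=30)
TP = ml.ThreePoolParams(tau=1, gamma=2.4, mu=1e-2, omega=5)


def yule_network(r: float) -> ReactionNetwork:
    return ReactionNetwork(1, (Reaction({0: 1}, {0: 2}, r, "birth"),))


class TestGillespie:
    def test_seed_determinism(self):
        net = ml.build_minimal_network(MIN)
        a = ssa.gillespie(net, (10, 10, 13), 20.0, seed=5)
        b = ssa.gillespie(net, (10, 10, 13), 20.0, seed=5)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.states, b.states)
        c = ssa.gillespie(net, (10, 10, 13), 20.0, seed=6)
        assert not np.array_equal(a.times, c.times)

    def test_zero_propensity_state_is_absorbed(self):
        net = ml.build_gv_network(ml.GVParams(b=2, d=1, alpha=0.8, beta=1.3, omega=8))
        traj = ssa.gillespie(net, (0, 0, 0), 10.0, seed=1)
        assert traj.reason == "absorbed"
        assert len(traj.times) == 1

    def test_single_enabled_reaction_first_jump(self):
        net = ml.build_minimal_network(MIN)
        for seed in range(5):
            traj = ssa.gillespie(net, (0, 0, 1), 1.0, seed=seed)
            assert tuple(traj.states[1]) == (0, 0, 2)

    def test_jumps_match_reaction_stoichiometry(self):
        net = ml.build_three_pool_network(TP)
        traj = ssa.gillespie(net, (5, 0, 0), 200.0, seed=11)
        steps = np.diff(traj.states, axis=0)
        S = {tuple(row) for row in net.stoichiometry}
        assert {tuple(s) for s in steps} <= S
        assert traj.states.min() >= 0 and traj.states.max() <= 5

    def test_yule_ensemble_mean_matches_exponential_growth(self):
        """Pure-birth ensemble mean of N(t) vs the closed form N0*exp(r*t)."""
        net = yule_network(1.0)
        n0, t, n_reps = 5, 1.5, 400
        summary, raw = ssa.ensemble(
            net, (n0,), n_reps, 321,
            {"N_t": lambda tr: tr.state_at(t)[0]}, t_max=t + 0.01,
        )
        expected = n0 * np.exp(t)
        assert abs(summary.loc["N_t", "mean"] - expected) < 3 * summary.loc["N_t", "se"]

    def test_stop_predicate_truncates(self):
        net = yule_network(1.0)
        traj = ssa.gillespie(net, (1,), 50.0, seed=2,
                             stop_predicate=lambda s: s[0] >= 10)
        assert traj.reason == "stop_predicate"
        assert traj.final_state[0] == 10

    def test_capacity_retry_is_transparent(self):
        net = yule_network(1.0)
        a = ssa.gillespie(net, (1,), 8.0, seed=3, max_events=4)
        b = ssa.gillespie(net, (1,), 8.0, seed=3)
        assert np.array_equal(a.times, b.times)


class TestExtinctionRecords:
    def test_handcrafted_trajectory(self):
        net = ml.build_minimal_network(MIN)
        times = np.array([0.0, 2.0, 5.0, 7.0])
        states = np.array([[3, 2, 1], [3, 1, 1], [3, 0, 1], [3, 0, 2]])
        traj = ssa.JumpTrajectory(times, states, 7.0, "t_max", 0, net)
        rec = ssa.extinction_events(traj)
        assert rec.events == [(2, 5.0)]
        assert rec.survivors == (1, 3)

    def test_minimal_model_leaves_one_survivor(self):
        net = ml.build_minimal_network(MIN)
        traj = ssa.gillespie(net, (10, 10, 13), 500.0, seed=8)
        rec = ssa.extinction_events(traj)
        assert len(rec.events) == 2
        assert len(rec.survivors) == 1
        assert traj.final_state[rec.survivors[0] - 1] > 0

    def test_gv_model_total_extinction(self):
        net = ml.build_gv_network(ml.GVParams(b=2, d=1, alpha=0.8, beta=1.3, omega=8))
        traj = ssa.gillespie(net, (3, 3, 3), 1e9, seed=9)
        assert traj.reason == "absorbed"
        rec = ssa.extinction_events(traj)
        assert len(rec.events) == 3
        assert rec.survivors == ()


class TestSectionCrossings:
    def _lattice_loop_trajectory(self, omega: int, revolutions: int):
        """Single-step path (W,0,0)->(0,W,0)->(0,0,W)->(W,0,0), unit-time steps."""
        net = ml.build_three_pool_network(
            ml.ThreePoolParams(tau=1, gamma=2.4, mu=1e-2, omega=omega))
        x = np.array([omega, 0, 0])
        states = [x.copy()]
        for _ in range(revolutions):
            for up, down in [(1, None), (None, 0), (2, None), (None, 1),
                             (0, None), (None, 2)]:
                for _ in range(omega):
                    x = x.copy()
                    if up is not None:
                        x[up] += 1
                    else:
                        x[down] -= 1
                    states.append(x)
        states = np.array(states)
        times = np.arange(len(states), dtype=float)
        return ssa.JumpTrajectory(times, states, times[-1], "t_max", 0, net)

    def test_one_crossing_per_section_per_revolution(self):
        omega, revs = 4, 3
        traj = self._lattice_loop_trajectory(omega, revs)
        rec = ssa.section_crossings(traj, omega)
        assert rec.events[0] == (1, 0.0)  # start state lies on P_1
        sections = [s for s, _ in rec.events]
        assert sections == [1] + [2, 3, 1] * revs
        assert np.allclose(rec.cycles, 6 * omega)

    def test_confined_path_crosses_nothing(self):
        net = ml.build_three_pool_network(
            ml.ThreePoolParams(tau=1, gamma=2.4, mu=1e-2, omega=9))
        states = np.array([[7, 4, 1], [7, 5, 1], [8, 5, 1], [8, 5, 2], [7, 5, 2]])
        times = np.arange(5.0)
        traj = ssa.JumpTrajectory(times, states, 4.0, "t_max", 0, net)
        rec = ssa.section_crossings(traj, 9)
        # sector N_1 > N_2 > N_3 never touches P_2 or P_3
        assert all(s == 1 for s, _ in rec.events)

    def test_posthoc_matches_fast_kernel(self):
        from mayleonard import _engine

        net = ml.build_three_pool_network(TP)
        traj = ssa.gillespie(net, (5, 0, 0), 1500.0, seed=99)
        rec = ssa.section_crossings(traj, 5)
        S, c, fs, fk = net.arrays()
        out, counts = _engine.cycles_batch(
            S, c, fs, fk, 5, np.array([5, 0, 0], dtype=np.int64), 1500.0,
            np.array([99]), 10_000, 1)
        assert counts[0] == len(rec.cycles)
        assert np.allclose(out[0, : counts[0]], rec.cycles)

    def test_omega_mismatch_rejected(self):
        net = ml.build_three_pool_network(TP)
        traj = ssa.gillespie(net, (5, 0, 0), 1.0, seed=1)
        with pytest.raises(ValueError):
            ssa.section_crossings(traj, 7)


class TestEnsemble:
    def test_single_replicate_reproduces_gillespie(self):
        net = ml.build_minimal_network(MIN)
        summary, raw = ssa.ensemble(net, (10, 10, 13), 1, 77,
                                    {"t_end": lambda t: t.t_end}, 30.0)
        direct = ssa.gillespie(net, (10, 10, 13), 30.0, ssa.replicate_seeds(77, 1)[0])
        assert raw.loc[0, "t_end"] == direct.t_end

    def test_first_extinction_symmetry_small(self):
        p = ml.MinimalParams(r=1, alpha=0.8, beta=1.3, omega=6)
        net = ml.build_minimal_network(p)
        df = ssa.ensemble_first_extinction(net, (2, 2, 2), 3000, 5150, 1e9)
        frac = df["species"].value_counts(normalize=True)
        se = np.sqrt((1 / 3) * (2 / 3) / len(df))
        for s in (1, 2, 3):
            assert abs(frac[s] - 1 / 3) < 3 * se

    def test_reducer_failure_is_flagged(self):
        net = yule_network(1.0)

        def bad(traj):
            raise RuntimeError("boom")

        summary, raw = ssa.ensemble(net, (1,), 3, 1, {"bad": bad}, 1.0)
        assert (raw["error"] != "").all()
        assert raw["bad"].isna().all()

    def test_minimal_model_origin_unreachable_structurally(self):
        """No reaction of the minimal net can take a nonzero state to (0,0,0)."""
        net = ml.build_minimal_network(MIN)
        from mayleonard.models import propensities

        for i in range(3):
            unit = np.zeros(3, dtype=np.int64)
            unit[i] = 1
            a = propensities(net, unit)
            S = net.stoichiometry
            for r in np.nonzero(a > 0)[0]:
                assert not np.all(unit + S[r] == 0)
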