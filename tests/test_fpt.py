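"""Generator assembly and first-passage solves against closed-form oracles."""

import numpy as np
import pytest

import mayleonard as ml
from mayleonard import fpt
from mayleonard.models import Reaction, ReactionNetwork, single_species_minimal_network

MIN = ml.MinimalParams(r=1, alpha=0.8, beta=1.3, omega=6)


def birth_death_chain(b: float, d: float) -> ReactionNetwork:
    """Linear birth-death chain: rates b*N up, d*N down."""
    return ReactionNetwork(1, (
        Reaction({0: 1}, {0: 2}, b, "birth"),
        Reaction({0: 1}, {}, d, "death"),
    ))


class TestGenerator:
    def test_row_sums_vanish(self):
        net = ml.build_minimal_network(MIN)
        for absorbing in (None, "any_zero", "origin"):
            G = fpt.build_generator(net, 12, absorbing=absorbing)
            rowsum = np.abs(np.asarray(G.Q.sum(axis=1)).ravel())
            assert rowsum.max() <= 1e-12

    def test_absorbing_rows_are_zero(self):
        net = ml.build_minimal_network(MIN)
        G = fpt.build_generator(net, 12, absorbing="any_zero")
        sub = G.Q[G.absorbing_idx]
        assert abs(sub).max() == 0.0

    def test_lattice_size_with_origin_absorbing(self):
        net = ml.build_gv_network(ml.GVParams(b=2, d=1, alpha=0.8, beta=1.3, omega=4))
        G = fpt.build_generator(net, 8, absorbing="origin")
        assert len(G.states) == 9**3
        assert G.absorbing.sum() == 1

    def test_single_species_state_one_has_no_death_transition(self):
        net = single_species_minimal_network(1.0, 6.0)
        G = fpt.build_generator(net, 12, absorbing=None)
        row = G.Q[1].toarray().ravel()
        assert row[0] == 0.0       # homocide needs two individuals
        assert row[2] > 0.0        # birth is enabled

    def test_minimal_origin_has_no_inbound_transition(self):
        net = ml.build_minimal_network(MIN)
        G = fpt.build_generator(net, 12, absorbing=None)
        col = G.Q[:, G.index_map.index((0, 0, 0))].toarray().ravel()
        col[G.index_map.index((0, 0, 0))] = 0.0
        assert abs(col).max() == 0.0

    def test_index_map_bijection(self):
        imap = fpt.LatticeIndexMap(5, 3)
        states = imap.all_states()
        assert len(states) == 6**3
        for idx in [0, 17, 215]:
            assert imap.index(imap.state(idx)) == idx


class TestHitting:
    def test_gamblers_ruin_closed_form(self):
        """Linear birth-death chain absorbed at 0 or M: classical ruin probability."""
        b, d, M = 1.0, 2.0, 12
        net = birth_death_chain(b, d)
        states = np.arange(M + 1)
        mask = (states == 0) | (states == M)
        G = fpt.build_generator(net, M, absorbing=mask)
        top = states == M
        bottom = states == 0
        sol = fpt.hitting_probabilities(G, targets=[top, bottom])
        q = d / b
        for k in range(1, M):
            exact = (1 - q**k) / (1 - q**M)
            assert sol.hitting[k, 0] == pytest.approx(exact, abs=1e-10)

    def test_absorbing_start_hits_own_class(self, gen12):
        sol = fpt.hitting_probabilities(gen12)
        i = gen12.index_map.index((0, 5, 5))
        assert sol.hitting[i].tolist() == [1.0, 0.0, 0.0]

    def test_symmetric_start_is_equally_likely(self, gen12, symmetric12):
        sol = fpt.hitting_probabilities(gen12)
        probs = [sol.hitting_probability(symmetric12, lab) for lab in sol.class_labels]
        assert np.allclose(probs, 1 / 3, atol=1e-8)

    def test_adjoint_route_matches_backward_route(self, gen12, symmetric12):
        """Absorption distribution (adjoint solve) sums to the per-plane
        hitting probabilities (backward solve)."""
        dist = fpt.absorption_distribution(gen12, symmetric12)
        sol = fpt.hitting_probabilities(gen12)
        for j, lab in enumerate(sol.class_labels):
            mass = dist[gen12.absorbing_class == j].sum()
            assert mass == pytest.approx(
                sol.hitting_probability(symmetric12, lab), abs=1e-9)


class TestMeanTimes:
    def test_pure_death_chain_harmonic_sum(self):
        d = 0.7
        net = ReactionNetwork(1, (Reaction({0: 1}, {}, d, "death"),))
        G = fpt.build_generator(net, 20, absorbing="origin")
        sol = fpt.mean_absorption_time(G)
        for N in (1, 5, 20):
            exact = sum(1.0 / (k * d) for k in range(1, N + 1))
            assert sol.mean_time((N,)) == pytest.approx(exact, rel=1e-10)

    def test_absorbing_state_has_zero_time(self, tau12, gen12):
        assert tau12.mean_time((0, 3, 9)) == 0.0

    def test_cyclic_equivariance(self, gen12, tau12):
        """Mean extinction times are invariant under cyclic species permutation."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(1, 13, 3)
            t0 = tau12.mean_time(x)
            assert tau12.mean_time(np.roll(x, 1)) == pytest.approx(t0, rel=1e-9)
            assert tau12.mean_time(np.roll(x, 2)) == pytest.approx(t0, rel=1e-9)

    def test_plane_slice_symmetry_and_argmax(self, gen12, tau12, minimal12):
        states, vals = fpt.plane_slice(gen12, tau12.mean_times)
        assert states.sum(axis=1).tolist() == [12] * len(states)
        # three-fold rotational symmetry on the slice
        lookup = {tuple(s): v for s, v in zip(states, vals)}
        for s, v in lookup.items():
            assert lookup[tuple(np.roll(s, 1))] == pytest.approx(v, rel=1e-9)
        # maximum nearest the interior equilibrium Omega*r/(1+alpha+beta)*(1,1,1)
        eq = minimal12.omega * minimal12.r / (1 + minimal12.alpha + minimal12.beta)
        argmax = states[np.argmax(vals)]
        assert np.all(np.abs(argmax - eq) <= 1.0)

    def test_constant_field_slices_to_constant(self, gen12):
        states, vals = fpt.plane_slice(gen12, np.full(len(gen12.states), 3.14))
        assert np.all(vals == 3.14)

    def test_empty_plane_raises(self, gen12):
        with pytest.raises(ValueError):
            fpt.plane_slice(gen12, np.zeros(len(gen12.states)), total=1000)


class TestStationary:
    def test_gv_stationary_is_point_mass_at_origin(self):
        net = ml.build_gv_network(ml.GVParams(b=2, d=1, alpha=0.8, beta=1.3, omega=4))
        G = fpt.build_generator(net, 8, absorbing=None)
        pi = fpt.stationary_distribution(G, initial=np.array([2, 2, 2]))
        assert pi[G.index_map.index((0, 0, 0))] == 1.0

    def test_single_species_chain_matches_truncated_poisson(self):
        from mayleonard.stats import truncated_poisson

        r_omega = 10.0
        n_max = 60
        net = single_species_minimal_network(r_omega, 1.0)
        G = fpt.build_generator(net, n_max, absorbing=None)
        pi = fpt.stationary_distribution(G, initial=np.array([1]))
        tp = truncated_poisson(r_omega, 1.0, n_max)
        exact = np.zeros(n_max + 1)
        exact[tp.support] = tp.pmf
        assert 0.5 * np.abs(pi - exact).sum() < 1e-10

    def test_origin_only_chain_is_trivial_point_mass(self):
        net = single_species_minimal_network(1.0, 1.0)
        G = fpt.build_generator(net, 10, absorbing=None)
        pi = fpt.stationary_distribution(G, initial=np.array([0]))
        assert pi[0] == 1.0

    def test_ambiguous_reducible_chain_raises(self):
        # pure-death 2-species chain: both axes are closed classes
        net = ReactionNetwork(2, (
            Reaction({0: 1}, {}, 1.0, "death"),
            Reaction({1: 1}, {}, 1.0, "death"),
        ))
        G = fpt.build_generator(net, 4, absorbing=None)
        pi = fpt.stationary_distribution(G, initial=np.array([2, 2]))
        assert pi[G.index_map.index((0, 0))] == 1.0  # unique closed class: origin
        with pytest.raises(fpt.SolverError):
            fpt.stationary_distribution(
                fpt.build_generator(ml.build_minimal_network(MIN), 8, absorbing=None),
                initial=np.array([2, 2, 2]))  # three single-species closed classes


class TestSecondExtinction:
    def test_masses_sum_to_one_and_order(self, minimal12, symmetric12):
        entry = fpt.first_extinction_entry_distribution(minimal12, symmetric12)
        dens = fpt.conditional_second_extinction(minimal12, entry)
        total = dens.mass_species2_second + dens.mass_species1_second
        assert total == pytest.approx(1.0, abs=1e-8)
        assert dens.mass_species2_second > 0.5

    def test_symmetric_competition_gives_equal_masses(self):
        p = ml.MinimalParams(r=1, alpha=1.0, beta=1.0, omega=6)
        entry = (np.array([[3, 3]]), np.array([1.0]))
        dens = fpt.conditional_second_extinction(p, entry, n_max=12)
        assert dens.mass_species2_second == pytest.approx(0.5, abs=1e-9)

    def test_invalid_entry_distribution_rejected(self, minimal12):
        with pytest.raises(ValueError):
            fpt.conditional_second_extinction(
                minimal12, (np.array([[0, 3]]), np.array([1.0])))
        with pytest.raises(ValueError):
            fpt.conditional_second_extinction(
                minimal12, (np.array([[2, 3]]), np.array([0.5])))


class TestSegment:
    @pytest.mark.parametrize("s, omega, expected", [
        (0.0, 30, (30, 0, 0)),
        (1.0, 30, (10, 10, 10)),
        (0.5, 30, (20, 5, 5)),
        (0.0, 12, (12, 0, 0)),
        (1.0, 12, (4, 4, 4)),
    ])
    def test_printed_segment_examples(self, s, omega, expected):
        assert tuple(fpt.segment_initial_state(s, omega)) == expected

    def test_out_of_range_s_rejected(self):
        with pytest.raises(ValueError):
            fpt.segment_initial_state(1.5, 30)
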