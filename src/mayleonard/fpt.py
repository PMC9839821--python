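"""Exact first-passage analysis on the truncated lattice.

The continuous-time Markov chain of a reaction network, truncated to the
lattice ``{0..n_max}**n_species``, is assembled as a sparse infinitesimal
generator ``Q``: ``Q[x, y]`` is the propensity of the unique reaction taking
``x`` to ``y`` and the diagonal holds minus the row sum.  Transitions that
would leave the lattice are deleted ("adjoint reflecting" truncation), the
unique choice that conserves probability without inventing transitions; the
truncation level defaults to ``2 * Omega`` in the extinction workflows.

With the coordinate planes ``N_i = 0`` (or only the origin) marked absorbing,
the backward equations on the transient block give

* hitting probabilities: ``Q_TT h = -R 1_s`` for each absorbing class ``s``;
* mean absorption times:  ``Q_TT tau = -1``;

and the adjoint (Green's function) solve ``Q_TT^T rho = -e_x0`` gives the
full distribution of the absorption location from one initial state in a
single factorized solve.  Stationary distributions of non-absorbing chains
are obtained from the closed communicating class reachable from an initial
state.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import breadth_first_order, connected_components
from scipy.sparse.linalg import splu

from .models import (
    MinimalParams,
    ReactionNetwork,
    build_minimal_network,
    minimal_pair_network,
)

__all__ = [
    "LatticeIndexMap",
    "Generator",
    "FirstPassageSolution",
    "SecondExtinctionDensities",
    "SolverError",
    "build_generator",
    "hitting_probabilities",
    "mean_absorption_time",
    "absorption_distribution",
    "conditional_second_extinction",
    "first_extinction_entry_distribution",
    "stationary_distribution",
    "segment_initial_state",
    "plane_slice",
]

_ROWSUM_TOL = 1e-12
_RESIDUAL_TOL = 1e-10


class SolverError(RuntimeError):
    """A linear solve failed or its residual is out of tolerance."""


@dataclass(frozen=True)
class LatticeIndexMap:
    """Bijection between lattice states and linear indices (row-major)."""

    n_max: int
    n_species: int

    @property
    def n_states(self) -> int:
        return (self.n_max + 1) ** self.n_species

    def index(self, state) -> int:
        state = np.asarray(state, dtype=np.int64)
        if np.any(state < 0) or np.any(state > self.n_max):
            raise ValueError(f"state {state} outside lattice 0..{self.n_max}")
        return int(np.ravel_multi_index(tuple(state), (self.n_max + 1,) * self.n_species))

    def state(self, idx: int) -> np.ndarray:
        return np.array(np.unravel_index(idx, (self.n_max + 1,) * self.n_species))

    def all_states(self) -> np.ndarray:
        shape = (self.n_max + 1,) * self.n_species
        return np.indices(shape).reshape(self.n_species, -1).T.astype(np.int64)


@dataclass
class Generator:
    """Sparse truncated-lattice generator with absorbing-state bookkeeping."""

    Q: sp.csr_matrix
    index_map: LatticeIndexMap
    states: np.ndarray              # (n_states, n_species)
    absorbing: np.ndarray           # bool mask
    absorbing_class: np.ndarray     # int class per state (-1 for transient)
    class_labels: tuple
    network: ReactionNetwork

    @property
    def transient_idx(self) -> np.ndarray:
        return np.nonzero(~self.absorbing)[0]

    @property
    def absorbing_idx(self) -> np.ndarray:
        return np.nonzero(self.absorbing)[0]

    @cached_property
    def _blocks(self):
        T, A = self.transient_idx, self.absorbing_idx
        Qcsr = self.Q.tocsr()
        QTT = Qcsr[T][:, T].tocsc()
        R = Qcsr[T][:, A].tocsr()
        return QTT, R

    @cached_property
    def _lu(self):
        QTT, _ = self._blocks
        if QTT.shape[0] == 0:
            raise SolverError("no transient states")
        try:
            return splu(QTT)
        except RuntimeError as exc:  # singular
            raise SolverError(
                f"transient block is singular (absorbing set unreachable?): {exc}"
            ) from exc

    def solve_backward(self, rhs: np.ndarray) -> np.ndarray:
        """Solve ``Q_TT x = rhs`` on the transient block."""
        return self._lu.solve(rhs)

    def solve_adjoint(self, rhs: np.ndarray) -> np.ndarray:
        """Solve ``Q_TT^T x = rhs`` on the transient block."""
        return self._lu.solve(rhs, trans="T")


@dataclass
class FirstPassageSolution:
    """Mean absorption times and/or hitting distributions per initial state."""

    generator: Generator
    mean_times: np.ndarray | None = None       # full lattice; 0 on absorbing
    hitting: np.ndarray | None = None          # (n_states, n_classes)
    class_labels: tuple = ()
    residual: float = 0.0

    def mean_time(self, state) -> float:
        return float(self.mean_times[self.generator.index_map.index(state)])

    def hitting_probability(self, state, class_label) -> float:
        j = self.class_labels.index(class_label)
        return float(self.hitting[self.generator.index_map.index(state), j])


def _resolve_absorbing(spec, states: np.ndarray):
    """Boolean mask + class labels for an absorbing specification."""
    n_states, ns = states.shape
    if spec is None:
        return np.zeros(n_states, dtype=bool), np.full(n_states, -1), ()
    if isinstance(spec, str):
        if spec == "any_zero":
            mask = np.any(states == 0, axis=1)
            cls = np.full(n_states, -1, dtype=np.int64)
            cls[mask] = np.argmax(states[mask] == 0, axis=1)
            labels = tuple(f"N{i + 1}=0" for i in range(ns))
            return mask, cls, labels
        if spec == "origin":
            mask = np.all(states == 0, axis=1)
            cls = np.where(mask, 0, -1)
            return mask, cls, ("origin",)
        raise ValueError(f"unknown absorbing spec {spec!r}")
    if callable(spec):
        mask = np.fromiter((bool(spec(s)) for s in states), dtype=bool, count=n_states)
    else:
        mask = np.asarray(spec, dtype=bool)
        if mask.shape != (n_states,):
            raise ValueError("absorbing mask has wrong length")
    cls = np.where(mask, 0, -1)
    return mask, cls, ("absorbing",)


def build_generator(net: ReactionNetwork, n_max: int,
                    absorbing="any_zero") -> Generator:
    """Assemble the truncated generator of ``net`` on ``{0..n_max}**n_species``.

    ``absorbing`` is ``"any_zero"`` (coordinate planes, one class per plane),
    ``"origin"``, ``None`` (no absorbing zeroing), a boolean mask, or a
    predicate on states.  Rates out of absorbing states are zeroed; rates that
    would leave the lattice are deleted.
    """
    if n_max < 1:
        raise ValueError("n_max must be at least 1")
    if net.state_bounds is not None and n_max > net.state_bounds:
        n_max = net.state_bounds  # three-pool chain never leaves [0, Omega]
    imap = LatticeIndexMap(n_max, net.n_species)
    states = imap.all_states()
    n_states = imap.n_states
    mask, cls, labels = _resolve_absorbing(absorbing, states)

    S, c, f_spec, f_kind = net.arrays()
    w = net.engine_omega()
    rows, cols, vals = [], [], []
    strides = (n_max + 1) ** np.arange(net.n_species - 1, -1, -1)
    lin = states @ strides
    for r in range(len(c)):
        a = np.full(n_states, c[r])
        for k in (0, 1):
            kind = f_kind[r, k]
            x = states[:, f_spec[r, k]]
            if kind == 1:
                a = a * x
            elif kind == 2:
                a = a * 0.5 * (x - 1)
            elif kind == 3:
                a = a * (w - x)
        np.maximum(a, 0.0, out=a)
        tgt = states + S[r]
        ok = (a > 0) & ~mask & np.all((tgt >= 0) & (tgt <= n_max), axis=1)
        if not ok.any():
            continue
        rows.append(lin[ok])
        cols.append(tgt[ok] @ strides)
        vals.append(a[ok])
    if rows:
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
    else:
        rows = cols = np.zeros(0, dtype=np.int64)
        vals = np.zeros(0)
    Q = sp.coo_matrix((vals, (rows, cols)), shape=(n_states, n_states)).tocsr()
    diag = -np.asarray(Q.sum(axis=1)).ravel()
    Q = (Q + sp.diags(diag)).tocsr()
    rowsum = np.abs(np.asarray(Q.sum(axis=1)).ravel()).max() if n_states else 0.0
    if rowsum > _ROWSUM_TOL:
        raise SolverError(f"generator rows do not sum to zero (max |sum| = {rowsum:g})")
    return Generator(Q, imap, states, mask, cls, labels, net)


def hitting_probabilities(G: Generator, targets=None) -> FirstPassageSolution:
    """Probability of being absorbed in each target class, per initial state.

    ``targets`` defaults to the generator's absorbing classes (one per
    coordinate plane for ``"any_zero"``); alternatively a list of boolean
    masks partitioning the absorbing set.  Realizes the first-passage
    location problem as the standard transient-block backward solve.
    """
    A = G.absorbing_idx
    if len(A) == 0:
        raise SolverError("absorbing set is empty")
    QTT, R = G._blocks
    T = G.transient_idx
    if targets is None:
        labels = []
        masks = []
        for cl in np.unique(G.absorbing_class[A]):
            masks.append(G.absorbing_class[A] == cl)
            labels.append(G.class_labels[cl])
    else:
        masks = [np.asarray(m)[A] if len(np.asarray(m)) == len(G.states) else np.asarray(m)
                 for m in targets]
        labels = [f"target{j}" for j in range(len(masks))]
    n_states = len(G.states)
    H = np.zeros((n_states, len(masks)))
    residual = 0.0
    for j, m in enumerate(masks):
        b = np.asarray(R @ m.astype(float)).ravel()
        h = G.solve_backward(-b)
        residual = max(residual, float(np.abs(QTT @ h + b).max()))
        H[T, j] = h
        H[A[m], j] = 1.0
    row = H.sum(axis=1)
    bad = np.abs(row[T] - 1.0).max() if len(T) else 0.0
    if bad > 1e-8:
        raise SolverError(f"hitting rows deviate from 1 by {bad:g}")
    return FirstPassageSolution(G, hitting=H, class_labels=tuple(labels),
                                residual=residual)


def mean_absorption_time(G: Generator) -> FirstPassageSolution:
    """Mean time to the absorbing set from every transient state (``L tau = -1``)."""
    QTT, _ = G._blocks
    T = G.transient_idx
    if len(G.absorbing_idx) == 0:
        raise SolverError("absorbing set is empty")
    tau_T = G.solve_backward(-np.ones(len(T)))
    residual = float(np.abs(QTT @ tau_T + 1.0).max())
    if residual > _RESIDUAL_TOL * max(1.0, np.abs(tau_T).max()):
        raise SolverError(f"mean-time solve residual {residual:g} out of tolerance")
    if np.any(tau_T < -1e-9):
        raise SolverError("negative mean absorption time: absorbing set unreachable "
                          "from some transient state")
    tau = np.zeros(len(G.states))
    tau[T] = np.maximum(tau_T, 0.0)
    return FirstPassageSolution(G, mean_times=tau, residual=residual)


def absorption_distribution(G: Generator, initial) -> np.ndarray:
    """Distribution of the absorption location from one initial state.

    Returns a full-lattice vector supported on the absorbing set, computed by
    the adjoint Green's-function solve (a single factorized solve); equivalent
    to assembling per-state hitting probabilities from the backward problem.
    """
    T = G.transient_idx
    i0 = G.index_map.index(initial)
    out = np.zeros(len(G.states))
    if G.absorbing[i0]:
        out[i0] = 1.0
        return out
    pos = np.searchsorted(T, i0)
    e = np.zeros(len(T))
    e[pos] = 1.0
    rho = G.solve_adjoint(-e)   # expected occupation times before absorption
    _, R = G._blocks
    flux = np.asarray(R.T @ rho).ravel()
    total = flux.sum()
    if abs(total - 1.0) > 1e-8:
        raise SolverError(f"absorption distribution mass {total:.12g} != 1")
    out[G.absorbing_idx] = flux
    return out


def stationary_distribution(G: Generator, initial=None) -> np.ndarray:
    """Stationary probability vector of the (non-absorbing-zeroed) chain.

    For reducible chains the distribution is taken on the unique closed
    communicating class reachable from ``initial``; multiple reachable closed
    classes raise an error.  Returns a full-lattice vector.
    """
    Q = G.Q.tocsr()
    adj = sp.csr_matrix(
        (np.ones_like(Q.data), Q.indices, Q.indptr), shape=Q.shape
    )
    adj.setdiag(0)
    adj.eliminate_zeros()
    n_comp, comp = connected_components(adj, directed=True, connection="strong")
    # closed components: no off-diagonal rate leaves the component
    coo = adj.tocoo()
    leaves = np.zeros(n_comp, dtype=bool)
    cross = comp[coo.row] != comp[coo.col]
    leaves[np.unique(comp[coo.row[cross]])] = True
    closed = ~leaves
    if initial is not None:
        i0 = G.index_map.index(initial)
        reach = breadth_first_order(adj, i0, directed=True, return_predecessors=False)
        reach_comps = np.unique(comp[reach])
        candidates = [cc for cc in reach_comps if closed[cc]]
    else:
        candidates = np.nonzero(closed)[0].tolist()
    if len(candidates) != 1:
        raise SolverError(
            f"{len(candidates)} closed communicating classes "
            f"{'reachable from the initial state' if initial is not None else 'found'}; "
            "supply an initial state that determines a unique one"
        )
    C = np.nonzero(comp == candidates[0])[0]
    pi = np.zeros(len(G.states))
    if len(C) == 1:
        pi[C[0]] = 1.0
        return pi
    QCC = Q[C][:, C]
    M = QCC.T.tolil()
    M[0, :] = 1.0
    b = np.zeros(len(C))
    b[0] = 1.0
    from scipy.sparse.linalg import spsolve

    v = spsolve(M.tocsc(), b)
    resid = float(np.abs(QCC.T @ v).max())
    if np.any(v < -1e-9) or resid > 1e-8 * max(1.0, np.abs(v).max()):
        raise SolverError(f"ambiguous null space (residual {resid:g})")
    v = np.maximum(v, 0.0)
    pi[C] = v / v.sum()
    return pi


@dataclass
class SecondExtinctionDensities:
    """Conditional densities of the survivor pair at the second extinction.

    Conditioned on species 3 having gone extinct first: ``density_n1[k]`` is
    the probability that species 2 goes extinct second with ``N_1 = k``
    remaining, and ``density_n2[k]`` the probability that species 1 goes
    extinct second with ``N_2 = k`` remaining.  The two total masses sum to 1.
    """

    density_n1: np.ndarray
    density_n2: np.ndarray

    @property
    def mass_species2_second(self) -> float:
        return float(self.density_n1.sum())

    @property
    def mass_species1_second(self) -> float:
        return float(self.density_n2.sum())


def first_extinction_entry_distribution(params: MinimalParams, initial,
                                        n_max: int | None = None):
    """Hitting distribution on the plane ``N_3 = 0`` from ``initial``.

    Returns ``(pair_states, weights)``: the (N_1, N_2) coordinates of the
    entry states (both >= 1) and their probabilities renormalized to 1
    (conditioning on species 3 going extinct first).
    """
    if n_max is None:
        n_max = int(round(2 * params.omega))
    net = build_minimal_network(params)
    G = build_generator(net, n_max, absorbing="any_zero")
    dist = absorption_distribution(G, initial)
    on_plane = (G.states[:, 2] == 0) & (G.states[:, 0] >= 1) & (G.states[:, 1] >= 1)
    w = dist[on_plane]
    if w.sum() <= 0:
        raise SolverError("no mass on the plane N_3 = 0")
    return G.states[on_plane][:, :2], w / w.sum()


def conditional_second_extinction(params: MinimalParams, entry,
                                  n_max: int | None = None) -> SecondExtinctionDensities:
    """Second-extinction densities of the two-species subsystem on ``N_3 = 0``.

    ``entry`` is ``(pair_states, weights)``: a distribution over states
    ``(N_1, N_2)`` with both counts >= 1, summing to 1 (e.g. from
    :func:`first_extinction_entry_distribution`).  Builds the two-species
    minimal generator, absorbs on ``N_1 = 0`` and ``N_2 = 0``, and averages
    the absorption distribution over the entry distribution with a single
    adjoint solve.
    """
    if n_max is None:
        n_max = int(round(2 * params.omega))
    pair_states, weights = entry
    pair_states = np.asarray(pair_states, dtype=np.int64)
    weights = np.asarray(weights, dtype=np.float64)
    if pair_states.ndim != 2 or pair_states.shape[1] != 2:
        raise ValueError("entry states must be (k, 2)")
    if np.any(pair_states < 1):
        raise ValueError("entry states must have N_1, N_2 >= 1")
    if abs(weights.sum() - 1.0) > 1e-8 or np.any(weights < 0):
        raise ValueError("entry weights must be a probability distribution")
    net2 = minimal_pair_network(params)
    G2 = build_generator(net2, n_max, absorbing="any_zero")
    T = G2.transient_idx
    w_vec = np.zeros(len(G2.states))
    for (n1, n2), wt in zip(pair_states, weights):
        w_vec[G2.index_map.index((n1, n2))] += wt
    rho = G2.solve_adjoint(-w_vec[T])
    _, R = G2._blocks
    flux = np.zeros(len(G2.states))
    flux[G2.absorbing_idx] = np.asarray(R.T @ rho).ravel()
    total = flux.sum()
    if abs(total - 1.0) > 1e-8:
        raise SolverError(f"conditional densities mass {total:.12g} != 1")
    dens1 = np.zeros(n_max + 1)  # N_1 remaining when N_2 hits 0
    dens2 = np.zeros(n_max + 1)  # N_2 remaining when N_1 hits 0
    st = G2.states
    m = (st[:, 1] == 0) & (st[:, 0] >= 1)
    dens1[st[m, 0]] = flux[m]
    m = (st[:, 0] == 0) & (st[:, 1] >= 1)
    dens2[st[m, 1]] = flux[m]
    return SecondExtinctionDensities(dens1, dens2)


def segment_initial_state(s: float, omega: float) -> np.ndarray:
    """Integer state on the segment from (Omega,0,0) to (Omega/3)(1,1,1).

    The segment point ``[Omega(1-s) + Omega*s/3, Omega*s/3, Omega*s/3]`` is
    rounded componentwise to the nearest integer (halves away from zero).
    """
    if not 0.0 <= s <= 1.0:
        raise ValueError("s must lie in [0, 1]")
    p = np.array([omega * (1 - s) + omega * s / 3, omega * s / 3, omega * s / 3])
    return np.floor(p + 0.5).astype(np.int64)


def plane_slice(G: Generator, fld: np.ndarray, total: float | None = None):
    """Restrict a per-state field to the plane ``N_1 + ... = total``.

    ``total`` defaults to the network's system size Omega (the plane through
    the interior reference point).  Returns ``(states, values)``.
    """
    if total is None:
        params = G.network.params
        if params is None:
            raise ValueError("no parameters attached; pass `total` explicitly")
        total = params.omega
    mask = G.states.sum(axis=1) == int(round(total))
    if not mask.any():
        raise ValueError(f"plane sum={total} does not intersect the lattice")
    return G.states[mask], np.asarray(fld)[mask]
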