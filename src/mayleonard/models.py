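"""Reaction networks and mean-field drifts for stochastic May-Leonard models.

Three cyclically symmetric three-species competition systems are provided,
each as an exact discrete-state reaction network together with its
deterministic mean-field drift:

* **General-variance (GV) model** -- individual birth (rate ``b``) and death
  (rate ``d``) per capita, homocidal (within-species) competition, and two
  heterocidal (between-species) competition channels of strengths ``alpha``
  and ``beta``.  For a fixed net growth rate ``r = b - d`` the short-time
  variance of the growth process scales with ``b + d``, hence "general
  variance".
* **Minimal model** -- the GV model with the individual death channel removed
  (``d = 0``, ``b = r``): the minimum-variance network consistent with the
  same mean field.  Total extinction becomes structurally unreachable.
* **Three-pool model** -- a central-pattern-generator variant: each "species"
  is the number of active cells in a neural pool of fixed size ``Omega``,
  with self-activation, cyclic inhibition (pool ``i`` inhibited by pool
  ``i+1``) and slow endogenous activation ``mu`` that prevents permanent
  silencing of any pool.

Species are indexed 0, 1, 2 internally with cyclic (mod 3) index arithmetic;
user-facing output is 1-based.  For bounded networks (three-pool) reactant
species indices ``n_species + i`` denote the *complement* count
``Omega - N_i`` (inactive cells); the simulated state vector always holds the
active counts only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "ParameterError",
    "DomainError",
    "GVParams",
    "MinimalParams",
    "ThreePoolParams",
    "Reaction",
    "ReactionNetwork",
    "build_gv_network",
    "build_minimal_network",
    "build_three_pool_network",
    "single_species_minimal_network",
    "minimal_pair_network",
    "propensities",
    "drift",
    "params_to_dict",
    "params_from_dict",
]

# factor kinds used in the compiled propensity encoding
_KIND_NONE = 0   # multiplicative identity
_KIND_N = 1      # N_s
_KIND_PAIR = 2   # (N_s - 1) / 2, paired with a _KIND_N factor for 2A -> ...
_KIND_COMP = 3   # Omega - N_s  (bounded networks only)


class ParameterError(ValueError):
    """A model parameter violates its invariant."""


class DomainError(ValueError):
    """A state or point lies outside the model's domain."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class GVParams:
    """Parameters of the general-variance model.

    b, d : per-capita birth / death rates (1/time), b > 0, d >= 0, b - d > 0
    alpha : competition strength of species i+1 on i (dimensionless)
    beta  : competition strength of species i+2 on i (dimensionless)
    omega : system size (single-species carrying capacity; positive real)
    """

    b: float
    d: float
    alpha: float
    beta: float
    omega: float

    def __post_init__(self) -> None:
        _require(self.b > 0, "birth rate b must be positive")
        _require(self.d >= 0, "death rate d must be nonnegative")
        _require(self.b - self.d > 0, "net growth rate b - d must be positive")
        _require(self.alpha >= 0, "alpha must be nonnegative")
        _require(self.beta >= 0, "beta must be nonnegative")
        _require(self.omega > 0, "system size omega must be positive")

    @property
    def r(self) -> float:
        """Net per-capita growth rate b - d."""
        return self.b - self.d


@dataclass(frozen=True)
class MinimalParams:
    """Parameters of the minimal (minimum-variance) model.

    r : net growth rate (1/time), r > 0; alpha, beta, omega as in GVParams.
    """

    r: float
    alpha: float
    beta: float
    omega: float

    def __post_init__(self) -> None:
        _require(self.r > 0, "growth rate r must be positive")
        _require(self.alpha >= 0, "alpha must be nonnegative")
        _require(self.beta >= 0, "beta must be nonnegative")
        _require(self.omega > 0, "system size omega must be positive")


@dataclass(frozen=True)
class ThreePoolParams:
    """Parameters of the three-pool central-pattern-generator model.

    tau   : time constant (time), tau > 0
    gamma : inhibition strength (dimensionless), gamma >= 0
    mu    : endogenous activation rate (dimensionless), mu >= 0
    omega : cells per pool (positive integer; bounds the state space)
    """

    tau: float
    gamma: float
    mu: float
    omega: int

    def __post_init__(self) -> None:
        _require(self.tau > 0, "time constant tau must be positive")
        _require(self.gamma >= 0, "inhibition strength gamma must be nonnegative")
        _require(self.mu >= 0, "endogenous activation mu must be nonnegative")
        _require(
            float(self.omega) == int(self.omega) and self.omega >= 1,
            "pool size omega must be a positive integer",
        )
        object.__setattr__(self, "omega", int(self.omega))


@dataclass(frozen=True)
class Reaction:
    """One reaction channel: reactant/product stoichiometries and a rate constant.

    Keys of ``reactants``/``products`` are species indices; for a network with
    ``n`` counted species and a finite bound, index ``n + i`` denotes the
    complement ``Omega - N_i``.  Total reactant order is at most 2 and every
    reaction changes each counted species by -1, 0 or +1.
    """

    reactants: Mapping[int, int]
    products: Mapping[int, int]
    rate_constant: float
    label: str = ""

    def __post_init__(self) -> None:
        _require(self.rate_constant >= 0, "rate constant must be nonnegative")
        order = sum(self.reactants.values())
        _require(order <= 2, "total reactant order must be at most 2")
        for st in list(self.reactants.values()) + list(self.products.values()):
            _require(st >= 0, "stoichiometries must be nonnegative")

    def net_change(self, n_species: int) -> np.ndarray:
        """Net change of the counted state vector (complement indices folded in)."""
        dx = np.zeros(n_species, dtype=np.int64)
        for sp, st in self.reactants.items():
            if sp < n_species:
                dx[sp] -= st
        for sp, st in self.products.items():
            if sp < n_species:
                dx[sp] += st
        return dx


@dataclass(frozen=True)
class ReactionNetwork:
    """An ordered collection of reactions over ``n_species`` counted species.

    ``state_bounds`` is the per-species upper bound Omega for bounded networks
    (three-pool) and None for the unbounded GV/minimal networks.
    """

    n_species: int
    reactions: tuple[Reaction, ...]
    state_bounds: int | None = None
    params: object = field(default=None, repr=False, compare=False)
    _compiled: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for rx in self.reactions:
            for sp in list(rx.reactants) + list(rx.products):
                limit = 2 * self.n_species if self.state_bounds is not None else self.n_species
                _require(0 <= sp < limit, f"species index {sp} out of range")
            dx = rx.net_change(self.n_species)
            _require(
                np.all(np.abs(dx) <= 1),
                "every reaction must change each species by at most one",
            )

    # -- compiled arrays for the propensity kernel ------------------------------

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(S, c, f_spec, f_kind)`` encoding stoichiometry and propensities.

        ``S[r]`` is the net state change of reaction ``r``; the propensity is
        ``c[r]`` times up to two factors, each a function of one species count
        selected by ``(f_spec[r, k], f_kind[r, k])``.
        """
        if "S" not in self._compiled:
            nr = len(self.reactions)
            S = np.zeros((nr, self.n_species), dtype=np.int64)
            c = np.zeros(nr, dtype=np.float64)
            f_spec = np.zeros((nr, 2), dtype=np.int64)
            f_kind = np.full((nr, 2), _KIND_NONE, dtype=np.int64)
            for r, rx in enumerate(self.reactions):
                S[r] = rx.net_change(self.n_species)
                c[r] = rx.rate_constant
                k = 0
                for sp, st in rx.reactants.items():
                    if sp < self.n_species:
                        if st >= 1:
                            f_spec[r, k], f_kind[r, k] = sp, _KIND_N
                            k += 1
                        if st == 2:
                            f_spec[r, k], f_kind[r, k] = sp, _KIND_PAIR
                            k += 1
                    else:
                        _require(st == 1, "complement reactant order must be 1")
                        f_spec[r, k], f_kind[r, k] = sp - self.n_species, _KIND_COMP
                        k += 1
            self._compiled.update(S=S, c=c, f_spec=f_spec, f_kind=f_kind)
        z = self._compiled
        return z["S"], z["c"], z["f_spec"], z["f_kind"]

    @property
    def stoichiometry(self) -> np.ndarray:
        return self.arrays()[0]

    def engine_omega(self) -> int:
        """Bound passed to the simulation kernels (0 when unbounded)."""
        return int(self.state_bounds) if self.state_bounds is not None else 0


def _cyc(i: int, k: int) -> int:
    return (i + k) % 3


def build_gv_network(params: GVParams) -> ReactionNetwork:
    """General-variance reaction net: 15 reactions (5 templates x 3 species).

    birth ``A_i -> 2A_i`` (c = b); death ``A_i -> 0`` (c = d); homocidal
    ``2A_i -> A_i`` (c = 2/Omega); heterocidal ``A_i + A_{i+1} -> A_{i+1}``
    (c = alpha/Omega) and ``A_i + A_{i+2} -> A_{i+2}`` (c = beta/Omega).
    """
    w = params.omega
    rx: list[Reaction] = []
    for i in range(3):
        rx.append(Reaction({i: 1}, {i: 2}, params.b, "birth"))
    for i in range(3):
        rx.append(Reaction({i: 1}, {}, params.d, "death"))
    for i in range(3):
        rx.append(Reaction({i: 2}, {i: 1}, 2.0 / w, "homocidal"))
    for i in range(3):
        j = _cyc(i, 1)
        rx.append(Reaction({i: 1, j: 1}, {j: 1}, params.alpha / w, "heterocidal"))
    for i in range(3):
        j = _cyc(i, 2)
        rx.append(Reaction({i: 1, j: 1}, {j: 1}, params.beta / w, "heterocidal"))
    return ReactionNetwork(3, tuple(rx), params=params)


def build_minimal_network(params: MinimalParams) -> ReactionNetwork:
    """Minimal reaction net: the GV net with the death channel removed (12 reactions)."""
    w = params.omega
    rx: list[Reaction] = []
    for i in range(3):
        rx.append(Reaction({i: 1}, {i: 2}, params.r, "birth"))
    for i in range(3):
        rx.append(Reaction({i: 2}, {i: 1}, 2.0 / w, "homocidal"))
    for i in range(3):
        j = _cyc(i, 1)
        rx.append(Reaction({i: 1, j: 1}, {j: 1}, params.alpha / w, "heterocidal"))
    for i in range(3):
        j = _cyc(i, 2)
        rx.append(Reaction({i: 1, j: 1}, {j: 1}, params.beta / w, "heterocidal"))
    return ReactionNetwork(3, tuple(rx), params=params)


def build_three_pool_network(params: ThreePoolParams) -> ReactionNetwork:
    """Three-pool reaction net over active counts (9 reactions, states bounded by Omega).

    self-activation ``A_i + I_i -> 2A_i`` (c = 1/(tau*Omega)); inhibition of
    pool i by pool i+1 ``A_i + A_{i+1} -> I_i + A_{i+1}`` (c = gamma/(tau*Omega));
    endogenous activation ``I_i -> A_i`` (c = mu/tau).  ``I_i`` is the implicit
    inactive count ``Omega - N_i``; every reaction conserves ``N_i + I_i``.
    """
    w, tau = params.omega, params.tau
    rx: list[Reaction] = []
    for i in range(3):
        rx.append(Reaction({i: 1, 3 + i: 1}, {i: 2}, 1.0 / (tau * w), "self-activation"))
    for i in range(3):
        j = _cyc(i, 1)
        rx.append(Reaction({i: 1, j: 1}, {3 + i: 1, j: 1}, params.gamma / (tau * w), "inhibition"))
    for i in range(3):
        rx.append(Reaction({3 + i: 1}, {i: 1}, params.mu / tau, "endogenous"))
    return ReactionNetwork(3, tuple(rx), state_bounds=w, params=params)


def single_species_minimal_network(r: float, omega: float) -> ReactionNetwork:
    """One-species subsystem of the minimal model: birth rN and homocide N(N-1)/Omega.

    This is the chain obeyed by the sole survivor after the second extinction;
    its stationary law on {1, 2, ...} is the truncated Poisson of rate r*Omega.
    """
    _require(r > 0 and omega > 0, "r and omega must be positive")
    return ReactionNetwork(
        1,
        (
            Reaction({0: 1}, {0: 2}, r, "birth"),
            Reaction({0: 2}, {0: 1}, 2.0 / omega, "homocidal"),
        ),
    )


def minimal_pair_network(params: MinimalParams) -> ReactionNetwork:
    """Two-species subsystem of the minimal model on the plane N_3 = 0.

    Species (1, 2) of the cyclic system: species 1 is killed by species 2 at
    strength alpha (2 = 1+1 cyclically) and species 2 by species 1 at strength
    beta (1 = 2+2 cyclically).
    """
    w = params.omega
    return ReactionNetwork(
        2,
        (
            Reaction({0: 1}, {0: 2}, params.r, "birth"),
            Reaction({1: 1}, {1: 2}, params.r, "birth"),
            Reaction({0: 2}, {0: 1}, 2.0 / w, "homocidal"),
            Reaction({1: 2}, {1: 1}, 2.0 / w, "homocidal"),
            Reaction({0: 1, 1: 1}, {1: 1}, params.alpha / w, "heterocidal"),
            Reaction({1: 1, 0: 1}, {0: 1}, params.beta / w, "heterocidal"),
        ),
    )


def _check_state(net: ReactionNetwork, state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, dtype=np.int64)
    if state.shape != (net.n_species,):
        raise DomainError(f"state must have {net.n_species} components")
    if np.any(state < 0):
        raise DomainError("population counts must be nonnegative")
    if net.state_bounds is not None and np.any(state > net.state_bounds):
        raise DomainError(f"counts must not exceed the pool size {net.state_bounds}")
    return state


def propensities(net: ReactionNetwork, state) -> np.ndarray:
    """Combinatorial mass-action propensities of every reaction at ``state``.

    First order in A: ``c*N``; second order A+B: ``c*N_A*N_B``; second order
    2A: ``c*N*(N-1)/2``; complement reactants contribute ``Omega - N``.
    """
    x = _check_state(net, state)
    S, c, f_spec, f_kind = net.arrays()
    w = net.engine_omega()
    a = c.copy()
    for k in (0, 1):
        kinds = f_kind[:, k]
        sp = f_spec[:, k]
        vals = np.ones_like(a)
        m = kinds == _KIND_N
        vals[m] = x[sp[m]]
        m = kinds == _KIND_PAIR
        vals[m] = 0.5 * (x[sp[m]] - 1)
        m = kinds == _KIND_COMP
        vals[m] = w - x[sp[m]]
        a *= vals
    return np.maximum(a, 0.0)


def drift(params, point) -> np.ndarray:
    """Deterministic mean-field right-hand side at ``point`` (componentwise >= 0).

    Uses the macroscopic ``N**2`` form: the expected SSA increment rate equals
    this drift *plus* the combinatorial correction ``N_i/Omega`` from the
    homocidal channel for the GV/minimal models, and equals it exactly for the
    three-pool model.
    """
    x = np.asarray(point, dtype=np.float64)
    if x.shape != (3,):
        raise DomainError("point must have 3 components")
    if np.any(x < 0):
        raise DomainError("point must be componentwise nonnegative")
    xp = np.roll(x, -1)   # N_{i+1}
    xpp = np.roll(x, -2)  # N_{i+2}
    if isinstance(params, (GVParams, MinimalParams)):
        w = params.omega
        return x * (params.r - (x + params.alpha * xp + params.beta * xpp) / w)
    if isinstance(params, ThreePoolParams):
        w = params.omega
        return (x * (1.0 - x / w - params.gamma * xp / w) + params.mu * (w - x)) / params.tau
    raise TypeError(f"unsupported parameter type {type(params)!r}")


_MODEL_KEYS = {
    "gv": (GVParams, ("b", "d", "alpha", "beta", "omega")),
    "minimal": (MinimalParams, ("r", "alpha", "beta", "omega")),
    "threepool": (ThreePoolParams, ("tau", "gamma", "mu", "omega")),
}


def params_to_dict(params) -> dict:
    """Flat declarative form with a ``model`` selector key."""
    for name, (cls, keys) in _MODEL_KEYS.items():
        if isinstance(params, cls):
            out = {"model": name}
            out.update({k: getattr(params, k) for k in keys})
            return out
    raise TypeError(f"unsupported parameter type {type(params)!r}")


def params_from_dict(d: Mapping) -> GVParams | MinimalParams | ThreePoolParams:
    d = dict(d)
    model = d.pop("model", None)
    if model not in _MODEL_KEYS:
        raise ParameterError(f"model selector must be one of {sorted(_MODEL_KEYS)}, got {model!r}")
    cls, keys = _MODEL_KEYS[model]
    missing = [k for k in keys if k not in d]
    if missing:
        raise ParameterError(f"missing parameter(s) {missing} for model {model!r}")
    extra = [k for k in d if k not in keys]
    if extra:
        raise ParameterError(f"unknown parameter(s) {extra} for model {model!r}")
    return cls(**{k: d[k] for k in keys})


def build_network(params) -> ReactionNetwork:
    """Build the reaction network matching the parameter type."""
    if isinstance(params, GVParams):
        return build_gv_network(params)
    if isinstance(params, MinimalParams):
        return build_minimal_network(params)
    if isinstance(params, ThreePoolParams):
        return build_three_pool_network(params)
    raise TypeError(f"unsupported parameter type {type(params)!r}")
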