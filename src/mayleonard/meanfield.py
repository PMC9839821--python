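"""Deterministic mean-field dynamics: integration, Poincare sections, periods.

The three mean-field systems (GV, minimal, three-pool) share the same
cyclically symmetric structure.  For competition strengths with
``alpha + beta > 2`` and ``min(alpha, beta) < 1`` the GV/minimal field
exhibits heteroclinic cycling: each circuit of the three saddle points takes
longer than the last.  With ``alpha + beta = 2`` the orbit is periodic, and
the three-pool model with endogenous activation ``mu > 0`` converges to a
finite-period limit cycle.

Cycle completions are detected with three Poincare sections P_i: the plane
``N_{i+1} = N_{i+2}`` restricted to the triangle with vertices (0,0,0),
(Omega,Omega,Omega) and Omega*e_i.  The valid crossing direction is fixed
once per model by the sign of the mean-field flux through the section at a
representative interior point; the same orientation sets the cyclic order in
which the sections are visited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .models import GVParams, MinimalParams, ThreePoolParams, DomainError, drift

__all__ = [
    "OdeTrajectory",
    "CycleTimes",
    "IntegrationError",
    "integrate",
    "section_passage_times",
    "section_orientation",
    "deterministic_period",
]


class IntegrationError(RuntimeError):
    """ODE integration failed or did not converge."""


def _rhs(params):
    """Mean-field right-hand side as a plain closure (no domain checks).

    Identical to :func:`mayleonard.models.drift` on the nonnegative orthant;
    evaluating the raw polynomial off-domain keeps stiff integrators stable
    when a component undershoots zero by O(atol).
    """
    if isinstance(params, (GVParams, MinimalParams)):
        r, al, be, w = params.r, params.alpha, params.beta, params.omega

        def f(t, x):
            xp = np.roll(x, -1)
            xpp = np.roll(x, -2)
            return x * (r - (x + al * xp + be * xpp) / w)

    elif isinstance(params, ThreePoolParams):
        tau, ga, mu, w = params.tau, params.gamma, params.mu, params.omega

        def f(t, x):
            xp = np.roll(x, -1)
            return (x * (1.0 - x / w - ga * xp / w) + mu * (w - x)) / tau

    else:
        raise TypeError(f"unsupported parameter type {type(params)!r}")
    return f


@dataclass
class OdeTrajectory:
    """Numerical mean-field solution with a dense interpolant."""

    times: np.ndarray
    points: np.ndarray  # (n, 3)
    params: object
    rtol: float
    atol: float
    _sol: object = field(repr=False, default=None)

    def __call__(self, t):
        """Interpolated state at time(s) t."""
        return np.asarray(self._sol(t)).T

    def to_csv(self, path, intensive: bool = False) -> None:
        import pandas as pd

        w = self.params.omega if intensive else 1.0
        cols = ["n1", "n2", "n3"] if intensive else ["N1", "N2", "N3"]
        df = pd.DataFrame(self.points / w, columns=cols)
        df.insert(0, "t", self.times)
        df.to_csv(path, index=False)


@dataclass
class CycleTimes:
    """Section passage times and completed-circuit durations."""

    events: list  # (section index 1..3, time)
    durations: np.ndarray

    @property
    def passage_times(self) -> np.ndarray:
        return np.array([t for _, t in self.events])


def integrate(params, initial, duration, rtol: float = 1e-8, atol: float = 1e-10) -> OdeTrajectory:
    """Integrate the chosen mean-field system from ``initial`` for ``duration``.

    Uses a stiff-capable method (LSODA); heteroclinic orbits approach the
    coordinate planes exponentially fast and make the problem stiff.
    """
    x0 = np.asarray(initial, dtype=np.float64)
    if duration <= 0:
        raise ValueError("duration must be positive")
    if x0.shape != (3,) or np.any(x0 < 0):
        raise DomainError("initial point must be a nonnegative 3-vector")
    sol = solve_ivp(
        _rhs(params), (0.0, float(duration)), x0,
        method="LSODA", rtol=rtol, atol=atol, dense_output=True,
    )
    if not sol.success:
        raise IntegrationError(f"integration failed at t={sol.t[-1]:.6g}: {sol.message}")
    if np.any(sol.y < -10 * atol - 1e-14):
        warnings.warn("solution dipped below -atol; tolerances may be too loose")
    return OdeTrajectory(sol.t, sol.y.T, params, rtol, atol, _sol=sol.sol)


def section_orientation(params) -> int:
    """Sign of the mean-field flux through section P_1 at a representative point.

    Evaluated at (Omega/2)(1,1,1) + (Omega/4) e_1; by cyclic symmetry the same
    sign applies to every section.  +1 means the oriented coordinate
    ``N_{i+1} - N_{i+2}`` increases through a valid crossing and the circuit
    visits the sections in the order P_1 -> P_2 -> P_3; -1 reverses both.
    """
    w = params.omega
    p = np.full(3, w / 2.0)
    p[0] += w / 4.0
    f = drift(params, p)
    d = f[1] - f[2]
    if d == 0:
        raise ValueError("section flux vanishes; orientation is undefined "
                         "(degenerate, e.g. alpha == beta)")
    return 1 if d > 0 else -1


def _continuous_crossings(traj: OdeTrajectory, orient: int):
    """(section, time) events where the interpolated orbit crosses a section.

    Sign changes of the oriented coordinate are located on a fine grid and
    refined by root bracketing; the triangle condition
    ``N_i >= (N_{i+1} + N_{i+2}) / 2`` is applied at the crossing point.
    """
    t0, t1 = traj.times[0], traj.times[-1]
    n_grid = max(2000, int((t1 - t0) * 50))
    tg = np.linspace(t0, t1, n_grid)
    y = traj(tg)  # (n, 3)
    events = []
    for i in range(3):
        i1, i2 = (i + 1) % 3, (i + 2) % 3
        d = orient * (y[:, i1] - y[:, i2])
        sign = np.sign(d)
        idx = np.nonzero((sign[:-1] <= 0) & (sign[1:] > 0))[0]
        for j in idx:
            f = lambda t: orient * (traj(t)[i1] - traj(t)[i2])
            tc = brentq(f, tg[j], tg[j + 1], xtol=1e-12 * max(1.0, t1))
            p = traj(tc)
            if p[i] >= (p[i1] + p[i2]) / 2:
                events.append((i + 1, tc))
    events.sort(key=lambda e: e[1])
    return events


def _circuit_durations(events, orient: int) -> np.ndarray:
    """Reduce an event sequence to completed-circuit durations."""
    step = 1 if orient > 0 else 2
    durations = []
    armed = False
    s0 = legs = 0
    t_anchor = 0.0
    for sec, t in events:
        i = sec - 1
        if not armed:
            armed, s0, legs, t_anchor = True, i, 0, t
        elif i == (s0 + step * (legs + 1)) % 3:
            legs += 1
            if legs == 3:
                durations.append(t - t_anchor)
                t_anchor, legs = t, 0
    return np.array(durations)


def section_passage_times(traj: OdeTrajectory, omega: float | None = None) -> CycleTimes:
    """Times at which the orbit crosses the Poincare sections, in circuit order.

    ``omega`` is accepted for interface symmetry with the discrete detector;
    the section planes and triangle condition do not depend on it.
    """
    orient = section_orientation(traj.params)
    events = _continuous_crossings(traj, orient)
    if not events:
        warnings.warn("no section crossings found on the trajectory")
    return CycleTimes(events, _circuit_durations(events, orient))


def deterministic_period(params: ThreePoolParams, rtol: float = 1e-6,
                         max_time: float = 20000.0) -> float:
    """Limit-cycle period of the three-pool mean field (first return to P_1).

    Integrates from (Omega, 0, 0), discards transients, and returns the
    circuit duration once successive durations agree to relative ``rtol``.
    Fails for ``mu = 0``, where the cycle is heteroclinic and the period
    diverges.
    """
    if not isinstance(params, ThreePoolParams):
        raise TypeError("deterministic_period applies to the three-pool model")
    if params.mu <= 0:
        raise IntegrationError("mu = 0: heteroclinic regime, no finite period")
    w = params.omega
    x0 = np.array([float(w), 0.0, 0.0])
    duration = 200.0 * params.tau
    while duration <= max_time:
        traj = integrate(params, x0, duration, rtol=1e-10, atol=1e-12)
        durations = section_passage_times(traj).durations
        if len(durations) >= 3:
            a, b = durations[-2], durations[-1]
            if abs(a - b) <= rtol * abs(b):
                return float(b)
        duration *= 2
    raise IntegrationError(
        f"period did not converge to rtol={rtol} within t={max_time}"
    )
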