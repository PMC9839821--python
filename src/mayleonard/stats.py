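"""Stationary laws, goodness-of-fit, and cycle-length statistics.

The sole survivor of the minimal model performs stochastic logistic growth
whose stationary law is the zero-truncated Poisson distribution of rate
``r * Omega``,

    pi(N) = (r*Omega)**N / (N! * (exp(r*Omega) - 1)),   N >= 1.

Three-pool cycle lengths in the small-``Omega``, small-``mu`` regime are
dominated by three rate-limiting corner escapes, each exponential with rate
``Omega*mu/tau``; the cycle length is then Gamma(shape 3, scale
``tau/(mu*Omega)``), predicting mean ``T_a = 3*tau/(Omega*mu)`` and
coefficient of variation ``CV_a = 1/sqrt(3)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

from .models import ThreePoolParams

__all__ = [
    "TruncatedPoisson",
    "GofResult",
    "CycleStats",
    "truncated_poisson",
    "chi2_gof",
    "gamma_cycle_approx",
    "fit_gamma",
    "cycle_summary",
]


@dataclass(frozen=True)
class TruncatedPoisson:
    """Zero-truncated Poisson pmf on {1..n_max} with rate product r*Omega."""

    rate: float                 # r * Omega
    support: np.ndarray         # 1..n_max
    pmf: np.ndarray

    def mean(self) -> float:
        return float(self.support @ self.pmf)


def truncated_poisson(r: float, omega: float, n_max: int | None = None,
                      tail_tol: float = 1e-12) -> TruncatedPoisson:
    """Zero-truncated Poisson law of rate ``r * Omega`` on {1..n_max}.

    ``n_max`` must be large enough that the neglected tail mass is below
    ``tail_tol``; by default it is grown automatically until it is.
    """
    if r <= 0 or omega <= 0:
        raise ValueError("r and omega must be positive")
    lam = r * omega
    if n_max is None:
        n_max = max(10, int(np.ceil(lam + 12 * np.sqrt(lam) + 12)))
    k = np.arange(1, n_max + 1)
    # log pmf: k*log(lam) - log(k!) - log(e^lam - 1), stable via log1p/expm1
    log_norm = lam + np.log1p(-np.exp(-lam)) if lam > 1e-8 else np.log(np.expm1(lam))
    logp = k * np.log(lam) - gammaln(k + 1) - log_norm
    pmf = np.exp(logp)
    tail = 1.0 - pmf.sum()
    if tail > tail_tol:
        raise ValueError(
            f"n_max={n_max} leaves tail mass {tail:.3g} > {tail_tol:g}; increase n_max"
        )
    return TruncatedPoisson(lam, k, pmf)


@dataclass(frozen=True)
class GofResult:
    statistic: float
    dof: int
    pvalue: float
    bin_edges: tuple            # right-open index ranges merged into each bin
    observed: np.ndarray
    expected: np.ndarray


def chi2_gof(observed, expected_pmf, min_expected: float = 5.0) -> GofResult:
    """Pearson chi-square test of counts against a discrete pmf.

    ``observed[j]`` are counts for the support points of ``expected_pmf``
    (any residual tail mass of the model is folded into the last bin).
    Adjacent support points are merged left-to-right until every expected
    count reaches ``min_expected``; degrees of freedom are bins - 1.
    """
    obs = np.asarray(observed, dtype=float)
    pmf = np.asarray(expected_pmf, dtype=float)
    if len(obs) != len(pmf):
        raise ValueError("observed and expected pmf must have equal length")
    if np.any(obs < 0) or obs.sum() <= 0:
        raise ValueError("observed counts must be nonnegative with positive total")
    n = obs.sum()
    exp_counts = pmf / pmf.sum() * n
    bins = []          # (start, stop) index ranges
    o_m, e_m = [], []
    start = 0
    acc_o = acc_e = 0.0
    for j in range(len(obs)):
        acc_o += obs[j]
        acc_e += exp_counts[j]
        if acc_e >= min_expected:
            bins.append((start, j + 1))
            o_m.append(acc_o)
            e_m.append(acc_e)
            start = j + 1
            acc_o = acc_e = 0.0
    if acc_e > 0 or acc_o > 0:  # fold the remainder into the last bin
        if not bins:
            raise ValueError("fewer than 2 bins reach the minimum expected count")
        s, _ = bins[-1]
        bins[-1] = (s, len(obs))
        o_m[-1] += acc_o
        e_m[-1] += acc_e
    if len(bins) < 2:
        raise ValueError("fewer than 2 bins reach the minimum expected count")
    o_m = np.array(o_m)
    e_m = np.array(e_m)
    stat, p = sps.chisquare(o_m, e_m)
    return GofResult(float(stat), len(bins) - 1, float(p), tuple(bins), o_m, e_m)


def gamma_cycle_approx(tau: float, mu: float, omega: float) -> tuple[float, float]:
    """Rate-limiting-step approximants: T_a = 3*tau/(Omega*mu), CV_a = 1/sqrt(3)."""
    if tau <= 0 or mu <= 0 or omega <= 0:
        raise ValueError("tau, mu and omega must be positive")
    return 3.0 * tau / (omega * mu), 1.0 / np.sqrt(3.0)


def fit_gamma(samples) -> tuple[float, float]:
    """Maximum-likelihood fit of a two-parameter Gamma (location fixed at 0).

    Returns ``(shape, scale)``.  Requires at least 30 positive samples with
    nonzero variance.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 30:
        raise ValueError("need at least 30 samples for a Gamma fit")
    if np.any(x <= 0):
        raise ValueError("samples must be positive")
    if np.var(x) == 0:
        raise ValueError("degenerate (zero-variance) samples")
    shape, loc, scale = sps.gamma.fit(x, floc=0)
    return float(shape), float(scale)


@dataclass(frozen=True)
class CycleStats:
    """Summary of a cycle-length sample with the Gamma-approximation contrast."""

    samples: np.ndarray
    mean: float
    variance: float
    cv: float
    se_mean: float
    se_variance: float
    se_cv: float
    gamma_shape: float | None = None
    gamma_scale: float | None = None
    t_approx: float | None = None       # T_a
    cv_approx: float | None = None      # CV_a
    delta_cv: float | None = None       # CV_c - CV_a


def cycle_summary(samples, params: ThreePoolParams | None = None,
                  fit: bool = True) -> CycleStats:
    """Mean, variance, CV (with standard errors) of cycle lengths.

    Standard errors use moment estimators (delta method for the CV).  When
    three-pool ``params`` are given, the rate-limiting-step approximants and
    ``delta_cv = CV_c - CV_a`` are attached; a Gamma MLE is attached when
    ``fit`` is true and the sample is large enough.
    """
    x = np.asarray(samples, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples")
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    cv = float(np.sqrt(var) / mean)
    m2 = x.var()
    m4 = float(((x - x.mean()) ** 4).mean())
    se_mean = float(np.sqrt(var / n))
    se_var = float(np.sqrt(max(m4 - m2**2, 0.0) / n))
    se_cv = float(cv * np.sqrt(1.0 / (2.0 * (n - 1)) + cv**2 / n)) if var > 0 else 0.0
    shape = scale = ta = cva = dcv = None
    if params is not None:
        ta, cva = gamma_cycle_approx(params.tau, params.mu, params.omega)
        dcv = cv - cva
    if fit and n >= 30 and var > 0:
        shape, scale = fit_gamma(x)
    return CycleStats(x, mean, var, cv, se_mean, se_var, se_cv,
                      shape, scale, ta, cva, dcv)
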