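"""Richness estimators: sample coverage, bias-corrected Chao2 with
log-normal confidence intervals, the true-uniques adjustment, and
Fisher's log-series parametric machinery.

All estimators are pure functions of :class:`~treerich.grid.FrequencyCounts`
(or of a raw abundance vector for the Fisher branch): identical tallies
give bit-identical output.

Notation.  For incidence data over ``T`` sampling units, ``Q1..Q4`` count
species present in exactly 1–4 units.  The bias-corrected Chao2 lower
bound is

    Chao2 = S_obs + ((T-1)/T) * Q1*(Q1-1) / (2*(Q2+1)),

with a log-normal 95% CI built on the excess E = Chao2 − S_obs:

    lower = S_obs + E/K,   upper = S_obs + E*K,
    K = exp(z * sqrt(ln(1 + var/E^2))).

Good–Turing sample coverage (Chao–Shen bias-reduced form) is

    C_n = 1 − (f1/n) * [(n−1) f1 / ((n−1) f1 + 2 f2)],

read with (f1, f2, n) = (singletons, doubletons, individuals) on
abundance data or (uniques, duplicates, total presences) on incidence
data.

Misidentification inflates the unique count: a rare species recorded
under two names in two cells yields two false uniques where one
duplicate existed.  The true-uniques estimator predicts the unique count
from the duplicate/triplicate/quadruplicate tail, with A = (T−1)/T:

    Q1_hat = A * 2*Q2^2/(3*Q3) + A^2 * Q2 * (Q2/(2*Q3) − Q3/(4*Q4)),

and Chao2_adj substitutes Q1_hat for Q1 in the Chao2 point and CI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .grid import FrequencyCounts

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageResult",
    "Chao2Estimate",
    "AdjustedEstimate",
    "FisherFit",
    "UndefinedCoverageError",
    "AlphaUnboundedError",
    "sample_coverage",
    "chao2",
    "chao2_ci",
    "estimate_true_uniques",
    "adjusted_chao2",
    "fisher_alpha_fit",
    "fisher_alpha_ci",
    "fisher_richness",
    "logseries_gof",
]


class UndefinedCoverageError(ValueError):
    """Coverage is undefined on an empty sample (n = 0)."""


class AlphaUnboundedError(ValueError):
    """Fisher's alpha diverges when every species is a singleton (S = n)."""


# ---------------------------------------------------------------------------
# sample coverage


@dataclass(frozen=True)
class CoverageResult:
    c_n: float
    """Estimated sample coverage, in [0, 1]."""

    @property
    def deficit(self) -> float:
        """Coverage deficit 1 − C_n: the accumulation curve's terminal slope."""
        return 1.0 - self.c_n


def sample_coverage(counts: FrequencyCounts) -> CoverageResult:
    """Bias-reduced (Chao–Shen) estimate of sample completeness."""
    n, f1, f2 = counts.n, counts.q1, counts.q2
    if n < 1:
        raise UndefinedCoverageError("coverage undefined for n = 0")
    if f1 == 0:
        return CoverageResult(1.0)
    c_n = 1.0 - (f1 / n) * ((n - 1) * f1 / ((n - 1) * f1 + 2.0 * f2))
    return CoverageResult(float(min(max(c_n, 0.0), 1.0)))


# ---------------------------------------------------------------------------
# Chao2


@dataclass(frozen=True)
class Chao2Estimate:
    s_obs: int
    T: int
    q1: float
    q2: int
    point: float
    variance: float | None = None
    K: float | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None

    @property
    def excess(self) -> float:
        """E = point − S_obs, the estimated number of undetected species."""
        return self.point - self.s_obs


def _chao2_core(s_obs: int, T: int, q1: float, q2: int) -> tuple[float, float]:
    """Point estimate and variance shared by the raw and adjusted paths.

    ``q1`` may be fractional (the adjusted path passes Q1_hat); values
    below 1 contribute nothing.  Variance is the bias-corrected companion
    of the point formula (the form EstimateS and the iNEXT family ship),
    with A = (T−1)/T:

        var = A*Q1*(Q1−1)/(2*(Q2+1))
            + A^2*Q1*(2*Q1−1)^2/(4*(Q2+1)^2)
            + A^2*Q1^2*Q2*(Q1−1)^2/(4*(Q2+1)^4)
    """
    A = (T - 1) / T
    d = q2 + 1.0
    if q1 < 1.0:
        return float(s_obs), 0.0
    point = s_obs + A * q1 * (q1 - 1.0) / (2.0 * d)
    var = (
        A * q1 * (q1 - 1.0) / (2.0 * d)
        + A**2 * q1 * (2.0 * q1 - 1.0) ** 2 / (4.0 * d**2)
        + A**2 * q1**2 * q2 * (q1 - 1.0) ** 2 / (4.0 * d**4)
    )
    return float(point), float(var)


def chao2(counts: FrequencyCounts) -> Chao2Estimate:
    """Bias-corrected Chao2 lower-bound richness estimate (point only).

    Defined for incidence-mode tallies with T ≥ 1; the ``Q2 + 1``
    denominator keeps the estimate finite when duplicates are absent.
    """
    if counts.mode != "incidence":
        raise ValueError("chao2 requires incidence-mode counts")
    if counts.T is None or counts.T < 1:
        raise ValueError("chao2 requires T >= 1")
    point, var = _chao2_core(counts.s_obs, counts.T, counts.q1, counts.q2)
    return Chao2Estimate(s_obs=counts.s_obs, T=counts.T, q1=counts.q1,
                         q2=counts.q2, point=point, variance=var)


def chao2_ci(estimate: Chao2Estimate, level: float = 0.95) -> Chao2Estimate:
    """Attach the log-normal CI; degenerates to [S_obs, S_obs] when E = 0."""
    E = estimate.excess
    var = estimate.variance
    if var is None:
        _, var = _chao2_core(estimate.s_obs, estimate.T, estimate.q1, estimate.q2)
    if E <= 0.0 or var <= 0.0:
        s = float(estimate.s_obs)
        return replace(estimate, variance=var, K=1.0,
                       ci_lower=max(s, estimate.point), ci_upper=estimate.point)
    z = stats.norm.ppf(0.5 + level / 2.0)
    K = math.exp(z * math.sqrt(math.log1p(var / E**2)))
    return replace(estimate, variance=var, K=K,
                   ci_lower=estimate.s_obs + E / K,
                   ci_upper=estimate.s_obs + E * K)


# ---------------------------------------------------------------------------
# true uniques and Chao2_adj


def estimate_true_uniques(
    counts: FrequencyCounts, *, squared_first_term: bool = False
) -> tuple[float, bool]:
    """Estimate the true number of uniques/singletons from Q2–Q4.

    Returns ``(Q1_hat, fallback_used)``.  The full formula needs Q3 > 0
    and Q4 > 0; on degenerate tallies the observed Q1 is returned
    unchanged with the fallback flag set (conservative: no adjustment).
    Negative estimates clamp to 0 with a logged warning.

    ``squared_first_term`` switches to the variant reading with the
    leading factor A squared; for T ≫ 1 the two differ negligibly.
    """
    T = counts.T if counts.mode == "incidence" else counts.n
    q1, q2, q3, q4 = counts.q1, counts.q2, counts.q3, counts.q4
    if q3 == 0 or q4 == 0:
        return float(q1), True
    A = (T - 1) / T
    first = A**2 if squared_first_term else A
    q1_hat = first * 2.0 * q2**2 / (3.0 * q3) + A**2 * q2 * (
        q2 / (2.0 * q3) - q3 / (4.0 * q4)
    )
    if q1_hat < 0.0:
        logger.warning("true-uniques estimate negative (%.3f); clamped to 0", q1_hat)
        q1_hat = 0.0
    return float(q1_hat), False


@dataclass(frozen=True)
class AdjustedEstimate:
    s_obs: int
    T: int
    q1_hat: float
    q2: int
    point: float
    variance: float
    ci_lower: float
    ci_upper: float
    fallback_used: bool = False


def adjusted_chao2(
    counts: FrequencyCounts,
    q1_hat: float,
    *,
    fallback_used: bool = False,
    level: float = 0.95,
) -> AdjustedEstimate:
    """Chao2 recomputed with the estimated true unique count Q1_hat.

    Q1_hat substitutes for Q1 in both the point formula and the variance
    feeding the CI.  It is left uncapped above the observed Q1 — when
    duplicates outnumber uniques the adjustment can revise richness
    upward.  With ``q1_hat`` equal to the observed Q1 the result
    reproduces :func:`chao2` exactly.
    """
    if q1_hat < 0.0:
        raise ValueError("q1_hat must be >= 0")
    if counts.mode != "incidence":
        raise ValueError("adjusted_chao2 requires incidence-mode counts")
    point, var = _chao2_core(counts.s_obs, counts.T, q1_hat, counts.q2)
    base = Chao2Estimate(s_obs=counts.s_obs, T=counts.T, q1=q1_hat,
                         q2=counts.q2, point=point, variance=var)
    with_ci = chao2_ci(base, level=level)
    return AdjustedEstimate(
        s_obs=counts.s_obs, T=counts.T, q1_hat=float(q1_hat), q2=counts.q2,
        point=with_ci.point, variance=with_ci.variance,
        ci_lower=with_ci.ci_lower, ci_upper=with_ci.ci_upper,
        fallback_used=fallback_used,
    )


# ---------------------------------------------------------------------------
# Fisher's log-series


@dataclass(frozen=True)
class FisherFit:
    alpha: float
    n: int
    s_obs: int
    ks_d: float | None = None
    ks_p: float | None = None
    ci_lower: float | None = None
    ci_upper: float | None = None

    @property
    def x(self) -> float:
        """Log-series parameter x = n / (n + alpha)."""
        return self.n / (self.n + self.alpha)

    def predict(self, n_total: float) -> float:
        """Richness expected at an external total of ``n_total`` individuals."""
        return fisher_richness(self.alpha, n_total)


def fisher_alpha_fit(abundances, rtol: float = 1e-9) -> FisherFit:
    """Fit Fisher's alpha to a per-species abundance vector.

    Solves ``S_obs = alpha * ln(1 + n/alpha)`` by bracketed root search.
    All-singleton samples (S_obs = n) make alpha unbounded and raise
    :class:`AlphaUnboundedError`.
    """
    counts = np.asarray(list(abundances), dtype=float)
    if counts.size == 0 or (counts < 1).any():
        raise ValueError("abundances must be a nonempty vector of counts >= 1")
    n = float(counts.sum())
    s = float(counts.size)
    if s >= n:
        raise AlphaUnboundedError("all species are singletons; alpha unbounded")

    def gap(alpha: float) -> float:
        return alpha * math.log1p(n / alpha) - s

    lo, hi = 1e-12, 1.0
    while gap(hi) < 0.0:
        hi *= 2.0
        if hi > 1e18:  # pragma: no cover - unreachable for s < n
            raise RuntimeError("failed to bracket alpha")
    alpha = float(optimize.brentq(gap, lo, hi, rtol=rtol, maxiter=200))
    return FisherFit(alpha=alpha, n=int(round(n)), s_obs=int(round(s)))


def fisher_alpha_ci(
    abundances,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for alpha: resample individuals, refit.

    Each replicate redraws the n individuals with replacement
    (multinomially over species) and refits alpha; replicates that come
    out all-singleton (alpha unbounded) are discarded.
    """
    counts = np.asarray(list(abundances), dtype=int)
    n = int(counts.sum())
    probs = counts / n
    rng = np.random.default_rng(seed)
    alphas = []
    for _ in range(n_boot):
        resampled = rng.multinomial(n, probs)
        resampled = resampled[resampled > 0]
        try:
            alphas.append(fisher_alpha_fit(resampled).alpha)
        except AlphaUnboundedError:
            continue
    if not alphas:
        raise AlphaUnboundedError("every bootstrap replicate was all-singleton")
    lo, hi = np.percentile(alphas, [100 * (0.5 - level / 2), 100 * (0.5 + level / 2)])
    return float(lo), float(hi)


def fisher_richness(alpha: float, n_total: float) -> float:
    """Fisher's classical richness equation S = alpha * ln(1 + N/alpha)."""
    if alpha <= 0 or n_total <= 0:
        raise ValueError("alpha and n_total must be positive")
    return float(alpha * math.log1p(n_total / alpha))


def logseries_gof(abundances, alpha: float | None = None) -> tuple[float, float]:
    """Kolmogorov–Smirnov test of log-series fit to an abundance vector.

    D is the sup distance between the empirical abundance CDF and the
    fitted log-series CDF, compared at the distinct observed abundance
    values (both CDFs are right-continuous step functions on the integer
    support; comparing there avoids the spurious inflation a sample-based
    D suffers under heavy ties).  The p value comes from the asymptotic
    Kolmogorov distribution with the number of compared support points as
    the effective sample size — an acknowledged approximation for
    discrete data that errs conservative (true rejection rates run below
    nominal).
    """
    counts = np.asarray(list(abundances), dtype=int)
    support = np.unique(counts)
    if support.size < 3:
        raise ValueError("goodness-of-fit needs >= 3 distinct abundance values")
    if alpha is None:
        alpha = fisher_alpha_fit(counts).alpha
    x = counts.sum() / (counts.sum() + alpha)
    emp_cdf = np.searchsorted(np.sort(counts), support, side="right") / counts.size
    fit_cdf = stats.logser.cdf(support, x)
    d = float(np.max(np.abs(emp_cdf - fit_cdf)))
    p = float(stats.kstwobign.sf(d * math.sqrt(support.size)))
    return d, min(p, 1.0)
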