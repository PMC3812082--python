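"""Luria-Delbrück probability model and mutation-rate estimators.

A fluctuation assay grows many parallel cultures from small inocula and
plates each on selective medium.  Because a mutation arising early in the
growth of a culture is amplified clonally, the distribution of mutant
colony counts is heavy-tailed (the Luria-Delbrück distribution).  Two
estimators of the mutation rate are provided:

* the Ma-Sandri-Sarkar (MSS) maximum-likelihood estimator, which fits the
  expected number of mutation events per culture ``m`` to the full
  distribution of mutant counts via the MSS recursion for the
  Lea-Coulson probability mass function, and
* the Drake median estimator, which solves the implicit equation
  ``mu = f / ln(N * mu)`` per culture (``f`` the observed mutant
  frequency, ``N`` the number of cells) and summarises per-culture rates
  as a median with an exact order-statistic confidence interval.

Rates are expressed per cell per generation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import binom

__all__ = [
    "CultureCount",
    "FluctuationAssay",
    "RateEstimate",
    "mss_pmf",
    "mss_loglik",
    "mss_mle",
    "drake_rate",
    "median_rate_with_ci",
    "drake_median_rate",
]

#: Bracketing grid for the MSS likelihood: log-spaced m in [1e-3, 1e3].
MLE_GRID = np.logspace(-3.0, 3.0, 61)

#: Extra pmf entries computed beyond the largest observed count, so that
#: the likelihood never evaluates the recursion at its truncation edge.
PMF_TAIL_GUARD = 20

#: Constant of the Stewart large-sample standard error for ln(m).
_STEWART_A, _STEWART_B = 1.225, -0.315


class InvalidParameterError(ValueError):
    """Raised for out-of-domain estimator parameters."""


@dataclass(frozen=True)
class CultureCount:
    """One culture of a fluctuation assay.

    ``r`` is the observed mutant colony count, ``n_t`` the final number of
    viable cells in the culture, and the two plating fractions record which
    part of the culture went on selective and on permissive plates.
    """

    culture_id: str
    r: int
    n_t: float
    plated_fraction_selective: float = 1.0
    plated_fraction_total: float = 1.0

    def __post_init__(self) -> None:
        if self.r < 0:
            raise InvalidParameterError(f"negative mutant count for {self.culture_id}")
        if not (self.n_t > 0 and math.isfinite(self.n_t)):
            raise InvalidParameterError(f"non-positive cell count for {self.culture_id}")
        for frac in (self.plated_fraction_selective, self.plated_fraction_total):
            if not (0.0 < frac <= 1.0):
                raise InvalidParameterError(
                    f"plating fraction {frac} outside (0, 1] for {self.culture_id}"
                )

    @property
    def r_whole_culture(self) -> float:
        """Mutant count rescaled to the whole culture.

        Partial plating observes only a fraction of the mutants; the count is
        scaled to whole-culture equivalents before rate estimation.
        """
        return self.r / self.plated_fraction_selective

    @property
    def frequency(self) -> float:
        """Mutant frequency f = r / (N_t * plated fraction)."""
        return self.r / (self.n_t * self.plated_fraction_selective)


@dataclass(frozen=True)
class FluctuationAssay:
    """A collection of parallel cultures for one genotype and reporter."""

    genotype: str
    reporter: str
    cultures: tuple[CultureCount, ...]

    def __post_init__(self) -> None:
        if len(self.cultures) == 0:
            raise InvalidParameterError("assay needs at least one culture")
        ids = [c.culture_id for c in self.cultures]
        if len(set(ids)) != len(ids):
            raise InvalidParameterError(f"duplicate culture ids in {self.genotype}")
        object.__setattr__(self, "cultures", tuple(self.cultures))

    @property
    def counts(self) -> np.ndarray:
        return np.array([c.r for c in self.cultures], dtype=int)

    @property
    def counts_whole_culture(self) -> np.ndarray:
        return np.array([c.r_whole_culture for c in self.cultures])

    @property
    def cell_counts(self) -> np.ndarray:
        return np.array([c.n_t for c in self.cultures])


@dataclass(frozen=True)
class RateEstimate:
    """A mutation rate per cell per generation with a 95% CI.

    ``m`` is the fitted expected number of mutation events per culture and
    is populated only by the maximum-likelihood path.  ``is_upper_bound``
    marks detection-limit results ("<" bounds) produced when no mutants, or
    a zero median, were observed; for those the CI ordering constraint does
    not apply.  ``ci_low``/``ci_high`` are ``None`` when too few cultures
    were available for a two-sided interval.
    """

    rate: float
    ci_low: float | None
    ci_high: float | None
    method: str
    m: float | None = None
    is_upper_bound: bool = False
    n_cultures: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise InvalidParameterError("negative rate")
        if (
            not self.is_upper_bound
            and self.ci_low is not None
            and self.ci_high is not None
            and not (self.ci_low - 1e-12 <= self.rate <= self.ci_high + 1e-12)
        ):
            raise InvalidParameterError("CI does not bracket the point estimate")


def mss_pmf(m: float, r_max: int) -> np.ndarray:
    """Lea-Coulson probability mass function by the MSS recursion.

    ``p_0 = exp(-m)`` and ``p_r = (m / r) * sum_{i<r} p_i / (r - i + 1)``.
    Returns probabilities for mutant counts ``r = 0 .. r_max``.  No
    renormalisation is applied: entries are the raw recursion values, whose
    partial sum is below one by exactly the (heavy) tail mass.
    """
    if not math.isfinite(m) or m < 0:
        raise InvalidParameterError(f"m must be a finite nonnegative real, got {m}")
    if r_max < 0:
        raise InvalidParameterError("r_max must be nonnegative")
    p = np.zeros(r_max + 1)
    p[0] = math.exp(-m)
    if m == 0.0 or r_max == 0:
        return p
    # weight for term i of p_r is 1/(r-i+1); reversed slice of `inv` below
    inv = 1.0 / np.arange(2.0, r_max + 2.0)
    for r in range(1, r_max + 1):
        p[r] = (m / r) * float(np.dot(p[:r], inv[r - 1 :: -1]))
    return p


def mss_loglik(m: float, counts: np.ndarray) -> float:
    """Log-likelihood of integer mutant counts under the MSS pmf at ``m``."""
    counts = np.asarray(counts, dtype=int)
    pmf = mss_pmf(m, int(counts.max()) + PMF_TAIL_GUARD)
    probs = pmf[counts]
    if np.any(probs <= 0.0):
        return -np.inf
    return float(np.sum(np.log(probs)))


def _stewart_sigma_ln_m(m: float, n_cultures: int) -> float:
    """Large-sample standard error of ln(m-hat) for the MSS MLE."""
    return _STEWART_A * m ** _STEWART_B / math.sqrt(n_cultures)


def mss_mle(assay: FluctuationAssay) -> RateEstimate:
    """Ma-Sandri-Sarkar maximum-likelihood mutation-rate estimate.

    The expected number of mutations per culture ``m`` is fitted by scanning
    a log-spaced grid and refining the best bracket with bounded scalar
    optimisation; the rate is ``m / median(N_t)``.  The 95% CI is a normal
    interval on ``ln m`` with the Stewart standard error
    ``1.225 * m^-0.315 / sqrt(C)``, back-transformed and divided by the
    median cell count.  Counts from partially plated cultures are rescaled
    to whole-culture equivalents first.

    When every culture has zero mutants no point estimate exists; the
    estimate returned is the detection-limit upper bound ``m`` at which the
    probability of observing all zeros is 5% (``exp(-mC) = 0.05``).
    """
    if len(assay.cultures) < 2:
        raise InvalidParameterError("MSS MLE needs at least two cultures")
    counts = np.rint(assay.counts_whole_culture).astype(int)
    c = len(counts)
    median_n = float(np.median(assay.cell_counts))

    if counts.max() == 0:
        m_bound = math.log(20.0) / c  # exp(-m*C) = 0.05
        bound_rate = m_bound / median_n
        return RateEstimate(
            rate=bound_rate,
            ci_low=0.0,
            ci_high=bound_rate,
            method="mss_mle",
            m=m_bound,
            is_upper_bound=True,
            n_cultures=c,
        )

    ll = np.array([mss_loglik(m, counts) for m in MLE_GRID])
    best = int(np.argmax(ll))  # argmax returns the first (smallest-m) maximiser
    lo = MLE_GRID[max(best - 1, 0)]
    hi = MLE_GRID[min(best + 1, len(MLE_GRID) - 1)]
    res = minimize_scalar(
        lambda lm: -mss_loglik(math.exp(lm), counts),
        bounds=(math.log(lo), math.log(hi)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    m_hat = math.exp(res.x)
    sigma = _stewart_sigma_ln_m(m_hat, c)
    m_lo = m_hat * math.exp(-1.959963984540054 * sigma)
    m_hi = m_hat * math.exp(+1.959963984540054 * sigma)
    return RateEstimate(
        rate=m_hat / median_n,
        ci_low=m_lo / median_n,
        ci_high=m_hi / median_n,
        method="mss_mle",
        m=m_hat,
        n_cultures=c,
    )


def drake_rate(r: float, n: float) -> float:
    """Drake's implicit per-culture mutation-rate estimator.

    Solves ``mu = f / ln(N * mu)`` with mutant frequency ``f = r / N``,
    equivalently the root of the monotone ``g(mu) = mu * ln(N * mu) - f``
    on ``mu > 1/N``.  Returns 0 for ``r = 0`` (below detection).
    """
    if not (math.isfinite(r) and math.isfinite(n)):
        raise InvalidParameterError("non-finite input to drake_rate")
    if n <= 0:
        raise InvalidParameterError("N must be positive")
    if r < 0:
        raise InvalidParameterError("r must be nonnegative")
    if r == 0:
        return 0.0
    f = r / n

    def g(mu: float) -> float:
        return mu * math.log(n * mu) - f

    lo = 1.0 / n  # g(lo) = -f < 0
    hi = max(f, 2.0 / n)
    while g(hi) <= 0.0:
        hi *= 2.0
    return float(brentq(g, lo, hi, xtol=1e-300, rtol=1e-15, maxiter=200))


def _order_statistic_ci_ranks(n: int, alpha: float = 0.05) -> tuple[int, int] | None:
    """1-based order-statistic ranks of the exact binomial median CI.

    ``k`` is the largest integer with ``P(X <= k-1) <= alpha/2`` for
    ``X ~ Binomial(n, 1/2)``; the CI is the (k, n-k+1)-th order statistics.
    Returns ``None`` when no two-sided interval exists (n < 6 at 5%).
    """
    if n < 6:
        return None
    k = 0
    for j in range(1, n + 1):
        if binom.cdf(j - 1, n, 0.5) <= alpha / 2.0:
            k = j
        else:
            break
    if k == 0 or n - k + 1 <= k:
        return None
    return k, n - k + 1


def median_rate_with_ci(
    per_culture_rates: list[float] | np.ndarray,
    method: str = "drake_median",
    detection_limit_rate: float | None = None,
) -> RateEstimate:
    """Median of per-culture rates with an exact order-statistic 95% CI.

    The CI endpoints are the (k, n-k+1)-th order statistics with ``k`` the
    largest rank leaving at most 2.5% binomial(n, 1/2) probability in each
    tail; fewer than 6 cultures leaves the CI unavailable (``None`` bounds).

    A zero median means the mutant count of the median culture was zero; the
    assay only bounds the rate from above.  When ``detection_limit_rate``
    (the rate implied by a single mutant colony) is supplied, such assays
    are reported as that upper bound with ``is_upper_bound`` set.
    """
    rates = np.asarray(per_culture_rates, dtype=float)
    if rates.size == 0:
        raise InvalidParameterError("empty rate list")
    if np.any(rates < 0) or not np.all(np.isfinite(rates)):
        raise InvalidParameterError("rates must be finite and nonnegative")
    n = rates.size
    ordered = np.sort(rates)
    med = float(np.median(ordered))
    ranks = _order_statistic_ci_ranks(n)
    ci_low = ci_high = None
    if ranks is not None:
        ci_low = float(ordered[ranks[0] - 1])
        ci_high = float(ordered[ranks[1] - 1])
    if med == 0.0 and detection_limit_rate is not None:
        return RateEstimate(
            rate=detection_limit_rate,
            ci_low=ci_low,
            ci_high=max(ci_high, detection_limit_rate) if ci_high is not None else None,
            method=method,
            is_upper_bound=True,
            n_cultures=n,
        )
    return RateEstimate(
        rate=med, ci_low=ci_low, ci_high=ci_high, method=method, n_cultures=n
    )


def drake_median_rate(assay: FluctuationAssay, pooled: bool = False) -> RateEstimate:
    """Drake estimate of an assay rate: per-culture rates, then the median.

    Each culture yields a rate from its own whole-culture-equivalent mutant
    count and cell number; the assay rate is the median of those with the
    exact order-statistic CI.  With ``pooled=True`` the Drake formula is
    instead applied once to the median mutant frequency (an alternative
    convention some labs use).  Zero-median assays are reported as the
    detection-limit upper bound implied by one mutant colony at the median
    cell count.
    """
    limit = drake_rate(1.0, float(np.median(assay.cell_counts)))
    if pooled:
        med_f = float(np.median([c.frequency for c in assay.cultures]))
        med_n = float(np.median(assay.cell_counts))
        rate = drake_rate(med_f * med_n, med_n)
        if rate == 0.0:
            return RateEstimate(
                rate=limit,
                ci_low=None,
                ci_high=None,
                method="drake_pooled",
                is_upper_bound=True,
                n_cultures=len(assay.cultures),
            )
        return RateEstimate(
            rate=rate,
            ci_low=None,
            ci_high=None,
            method="drake_pooled",
            n_cultures=len(assay.cultures),
        )
    per_culture = [drake_rate(c.r_whole_culture, c.n_t) for c in assay.cultures]
    return median_rate_with_ci(per_culture, detection_limit_rate=limit)
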