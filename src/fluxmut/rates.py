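"""Relative mutation rates and classification of genetic interactions.

A mutator phenotype is quantified as the *relative rate*: the mutant
genotype's rate divided by the isogenic wild-type rate for the same
reporter.  Combining two mutator alleles then asks how the double mutant's
relative rate R_ab compares with the single-mutant relatives R_a, R_b:

* synergistic   — R_ab exceeds the sum R_a + R_b (the two gene products
  guard the same pool of pre-mutagenic lesions);
* multiplicative — the stronger sub-type of synergy in which R_ab equals
  the product R_a * R_b;
* additive      — R_ab equals the sum (independent lesion pools);
* epistatic     — R_ab is no larger than the stronger single (same
  pathway);
* suppressive   — R_ab falls below the weaker single.

"Equals" is judged on the log scale within a configurable tolerance
factor (default 1.5x), and every call carries the raw sum/product ratios
so the thresholds can be revisited downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .ld import InvalidParameterError, RateEstimate

__all__ = [
    "GenotypeRate",
    "InteractionCall",
    "RelativeRate",
    "round_sig",
    "printed_relative",
    "relative_rate",
    "classify_interaction",
    "rank_sum_test",
]


class InvalidComparisonError(ValueError):
    """Raised when two rate estimates are not comparable."""


@dataclass(frozen=True)
class GenotypeRate:
    """A rate estimate tied to a genotype, reporter and reference strain."""

    genotype: str
    reporter: str
    estimate: RateEstimate
    background: str = "wild type"


class RelativeRate(NamedTuple):
    rounded: float
    unrounded: float


@dataclass(frozen=True)
class InteractionCall:
    """Outcome of comparing a combined mutant against its single mutants."""

    single_relatives: tuple[float, ...]
    combined_relative: float
    sum_expectation: float
    product_expectation: float
    category: str
    tolerance_factor: float


def round_sig(x: float, sig_figs: int = 2) -> float:
    """Round to ``sig_figs`` significant figures, half away from zero."""
    if sig_figs < 1:
        raise InvalidParameterError("sig_figs must be positive")
    if x == 0 or not math.isfinite(x):
        return x
    exponent = math.floor(math.log10(abs(x))) - (sig_figs - 1)
    quantum = Decimal(1).scaleb(exponent)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def printed_relative(quotient: float) -> float:
    """Render a relative rate the way rate tables conventionally print it.

    Two significant figures, half away from zero, with values at or above
    one shown as whole numbers (so 1.74 prints as 2 and 233.3 as 230) and
    sub-unity mutators at one significant figure (0.58 prints as 0.6).
    """
    r = round_sig(quotient, 2)
    if abs(r) >= 1.0:
        return float(Decimal(repr(r)).quantize(Decimal(1), rounding=ROUND_HALF_UP))
    return round_sig(quotient, 1)


def relative_rate(
    mutant: GenotypeRate, wild_type: GenotypeRate, sig_figs: int = 2
) -> RelativeRate:
    """Mutant rate divided by the isogenic wild-type rate, same reporter.

    Returns both the value rounded to ``sig_figs`` significant figures
    (half away from zero) and the unrounded quotient.
    """
    if mutant.reporter != wild_type.reporter:
        raise InvalidComparisonError(
            f"reporter mismatch: {mutant.reporter} vs {wild_type.reporter}"
        )
    if wild_type.estimate.rate <= 0:
        raise InvalidParameterError("wild-type rate must be positive")
    q = mutant.estimate.rate / wild_type.estimate.rate
    return RelativeRate(rounded=round_sig(q, sig_figs), unrounded=q)


def classify_interaction(
    single_relatives: Sequence[float],
    combined_relative: float,
    tolerance_factor: float = 1.5,
    sum_margin: float = 1.0,
    relative_floor: float = 0.1,
) -> InteractionCall:
    """Classify the genetic interaction between mutator alleles.

    With S the sum and P the product of the single-mutant relative rates,
    a combined relative rate above ``S * sum_margin`` is synergistic and is
    refined to multiplicative when it matches P within the log-scale
    tolerance (``|ln(R_ab / P)| <= ln(tolerance_factor)``).  Otherwise it
    is additive when it matches S within the same tolerance, epistatic when
    it does not exceed the strongest single by more than the tolerance, and
    suppressive when it falls below the weakest single by more than the
    tolerance.  Anything left between those bands is reported as the
    additive-to-synergistic boundary.
    """
    rel = tuple(float(r) for r in single_relatives)
    if len(rel) < 2:
        raise InvalidParameterError("need at least two single-mutant relative rates")
    if any(r <= 0 for r in rel) or combined_relative <= 0:
        raise InvalidParameterError("relative rates must be positive")
    if any(r < relative_floor for r in rel):
        raise InvalidParameterError(
            f"single-mutant relative rate below floor {relative_floor}"
        )
    if tolerance_factor <= 1.0:
        raise InvalidParameterError("tolerance_factor must exceed 1")
    s = float(sum(rel))
    p = float(np.prod(rel))
    log_tol = math.log(tolerance_factor)
    r_ab = float(combined_relative)

    if r_ab > s * sum_margin:
        category = (
            "multiplicative" if abs(math.log(r_ab / p)) <= log_tol else "synergistic"
        )
    elif abs(math.log(r_ab / s)) <= log_tol:
        category = "additive"
    elif r_ab < min(rel) / tolerance_factor:
        category = "suppressive"
    elif r_ab <= max(rel) * tolerance_factor:
        category = "epistatic"
    else:
        category = "additive-to-synergistic"
    return InteractionCall(
        single_relatives=rel,
        combined_relative=r_ab,
        sum_expectation=s,
        product_expectation=p,
        category=category,
        tolerance_factor=tolerance_factor,
    )


def rank_sum_test(sample_a: Sequence[float], sample_b: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value for two rate samples.

    Exact by enumeration when the pooled size is at most 20 and there are
    no ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(min(res.pvalue, 1.0))
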