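"""Synthetic fluctuation assays and mutant reporter sequences.

Raw colony counts and mutant Sanger reads from reporter-gene studies are
rarely deposited, so every input the pipeline consumes can be generated
here: Luria-Delbrück-distributed mutant counts per culture (by two
independent routes — exact inverse-CDF sampling from the Lea-Coulson pmf,
and a generative growth-process simulation) and mutant reporter-ORF
sequences drawn from a configurable mutation spectrum, with machine-
readable truth tables.

Defaults mirror the culture regime of reporter-gene fluctuation assays in
budding yeast: 15 parallel cultures grown from small inocula to ~2x10^8
cells, and a spectrum patterned on a strongly mutating, GCR-prone strain
(40% whole-reporter losses, one third base substitutions, the remainder
1-bp indels, complex mutations and medium-size deletions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ld import CultureCount, FluctuationAssay, mss_pmf
from .spectrum import MutationEvent, apply_events

__all__ = [
    "SimulationConfig",
    "DEFAULT_SPECTRUM_WEIGHTS",
    "sample_ld_counts",
    "simulate_growth_process",
    "make_reporter_reference",
    "generate_mutant_sequences",
    "SyntheticIsolate",
]

#: Spectrum of a hyperacetylated-chromatin mutator strain: whole-reporter
#: (GCR) losses dominate, base substitutions are one third of isolates, and
#: 1-bp indels, complex mutations and medium deletions share the rest.
DEFAULT_SPECTRUM_WEIGHTS: dict[str, float] = {
    "base_substitution": 0.33,
    "gcr_deletion": 0.40,
    "del_1bp": 0.10,
    "ins_1bp": 0.06,
    "complex": 0.055,
    "medium_deletion": 0.055,
}


class ConfigurationError(ValueError):
    """Raised for inconsistent simulation configurations."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a simulated fluctuation assay.

    Either ``m_true`` (expected mutations per culture) or ``rate_true``
    (mutations per cell per generation, converted as ``m = rate * n_t``)
    must be given.  Defaults reproduce a typical assay: 15 cultures grown
    from a 100-cell inoculum to 2x10^8 cells.
    """

    m_true: float | None = None
    rate_true: float | None = None
    n0: float = 100.0
    n_t: float = 2.0e8
    n_cultures: int = 15
    seed: int = 0
    genotype: str = "synthetic"
    reporter: str = "CAN1"
    plated_fraction_selective: float = 1.0
    plated_fraction_total: float = 1.0
    reporter_length: int = 1771
    spectrum_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM_WEIGHTS)
    )

    def __post_init__(self) -> None:
        if self.m_true is None and self.rate_true is None:
            raise ConfigurationError("either m_true or rate_true is required")
        if self.m_true is not None and self.m_true < 0:
            raise ConfigurationError("m_true must be nonnegative")
        if self.rate_true is not None and self.rate_true < 0:
            raise ConfigurationError("rate_true must be nonnegative")
        if self.n_t < self.n0 or self.n0 <= 0:
            raise ConfigurationError("need 0 < n0 <= n_t")
        if self.n_cultures < 1:
            raise ConfigurationError("n_cultures must be positive")
        total = sum(self.spectrum_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"spectrum weights sum to {total}, not 1")

    @property
    def m(self) -> float:
        if self.m_true is not None:
            return self.m_true
        return self.rate_true * self.n_t


def _assay_from_counts(
    config: SimulationConfig,
    counts: np.ndarray,
    rng: np.random.Generator | None = None,
) -> FluctuationAssay:
    if config.plated_fraction_selective < 1.0:
        if rng is None:
            raise ConfigurationError("partial plating requires a generator")
        # dilution plating observes a binomial subsample of the mutants
        counts = rng.binomial(counts, config.plated_fraction_selective)
    cultures = tuple(
        CultureCount(
            culture_id=f"c{i + 1:03d}",
            r=int(r),
            n_t=config.n_t,
            plated_fraction_selective=config.plated_fraction_selective,
            plated_fraction_total=config.plated_fraction_total,
        )
        for i, r in enumerate(counts)
    )
    return FluctuationAssay(
        genotype=config.genotype, reporter=config.reporter, cultures=cultures
    )


def sample_ld_counts(
    config: SimulationConfig,
    tail_tolerance: float = 1e-12,
    r_cap: int = 4096,
) -> FluctuationAssay:
    """Exact mutant counts by inverse-CDF sampling of the Lea-Coulson pmf.

    The pmf is evaluated by the MSS recursion out to the first count where
    the remaining tail mass drops below ``tail_tolerance`` or to ``r_cap``,
    whichever comes first; the residual tail mass is lumped into the last
    bin.  Because the Luria-Delbrück tail decays only like ``m / r``, the
    cap is what binds in practice — at the default it holds the lumped
    mass below ``m / 4096`` while keeping the recursion quadratic cost
    manageable.  Fully reproducible from ``config.seed``.
    """
    m = config.m
    rng = np.random.default_rng(config.seed)
    if m == 0.0:
        return _assay_from_counts(config, np.zeros(config.n_cultures, dtype=int), rng)
    pmf = mss_pmf(m, r_cap)
    cdf = np.cumsum(pmf)
    cut = int(np.searchsorted(cdf, 1.0 - tail_tolerance)) + 1
    cdf = cdf[: min(cut, r_cap + 1)]
    cdf[-1] = 1.0  # lump the remaining tail into the last bin
    u = rng.random(config.n_cultures)
    counts = np.searchsorted(cdf, u, side="left")
    return _assay_from_counts(config, counts, rng)


def simulate_growth_process(config: SimulationConfig) -> FluctuationAssay:
    """Generative growth-process oracle for Luria-Delbrück counts.

    The culture grows from ``n0`` to ``n_t`` cells; every division carries
    the same chance of producing a mutant daughter, so the number of
    mutation events per culture is Binomial(divisions, mu) with
    ``mu = m / (n_t - n0)``.  A mutation striking when the population has
    ``n`` cells founds a clone that expands with the culture to
    ``floor(n_t / n)`` cells at plating.  Division times are implicit: the
    mutation's position among the ``n_t - n0`` divisions is uniform, which
    reproduces the 1/(j(j+1)) clone-size law of the Lea-Coulson model
    without touching the pmf recursion — an independent route against
    which the exact sampler can be checked.
    """
    m = config.m
    rng = np.random.default_rng(config.seed)
    divisions = int(round(config.n_t - config.n0))
    if divisions <= 0:
        raise ConfigurationError("n_t must exceed n0 by at least one division")
    mu = m / divisions
    if mu > 1.0:
        raise ConfigurationError("per-division mutation probability exceeds one")
    counts = np.zeros(config.n_cultures, dtype=np.int64)
    n_events = rng.binomial(divisions, mu, size=config.n_cultures)
    for i, k in enumerate(n_events):
        if k == 0:
            continue
        # population size at each mutation's division, uniform over divisions
        n_at = config.n0 + rng.random(k) * divisions
        counts[i] = int(np.sum(np.floor(config.n_t / n_at)))
    return _assay_from_counts(config, counts, rng)


# ---------------------------------------------------------------------------
# Mutant reporter-ORF sequences


@dataclass(frozen=True)
class SyntheticIsolate:
    """One simulated mutant isolate with its ground truth.

    GCR isolates carry no sequence (the reporter no longer amplifies) and
    are represented by their PCR-marker row instead.
    """

    isolate_id: str
    true_class: str
    events: tuple[MutationEvent, ...]
    sequence: str | None
    can1_amplified: bool
    pol2_amplified: bool


def make_reporter_reference(
    length: int = 1771,
    seed: int = 0,
    n_planted_repeats: int = 6,
    repeat_length: int = 8,
) -> tuple[str, list[tuple[int, int]]]:
    """Random reporter ORF with direct-repeat pairs planted at known loci.

    Returns the sequence and a list of (start_1based, spacing) pairs: each
    records two identical ``repeat_length``-mers whose starts are
    ``spacing`` apart, so a deletion of length ``spacing`` starting at the
    first copy removes one copy plus the spacer and leaves a repeat
    straddling its junctions — the geometry seen at medium-size deletion
    breakpoints.
    """
    if length < 100:
        raise ConfigurationError("reference must be at least 100 bp")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seq = list(rng.choice(bases, size=length))
    registry: list[tuple[int, int]] = []
    if n_planted_repeats:
        # keep planted loci inside the middle of the ORF, non-overlapping
        slots = np.linspace(length * 0.1, length * 0.8, n_planted_repeats)
        for s in slots:
            start = int(s)
            spacing = int(rng.integers(40, min(200, length // 4)))
            if start + spacing + repeat_length >= length:
                continue
            unit = rng.choice(bases, size=repeat_length)
            seq[start - 1 : start - 1 + repeat_length] = unit
            seq[start - 1 + spacing : start - 1 + spacing + repeat_length] = unit
            registry.append((start, spacing))
    return "".join(seq), registry


def _random_substitution(rng: np.random.Generator, reference: str) -> MutationEvent:
    pos = int(rng.integers(1, len(reference) + 1))
    ref_base = reference[pos - 1]
    alt = rng.choice([b for b in "ACGT" if b != ref_base])
    return MutationEvent(position=pos, kind="substitution", ref_allele=ref_base, alt_allele=str(alt))


def _homopolymer_runs(reference: str, min_run: int = 3) -> list[tuple[int, int]]:
    """(start_1based, run_length) of homopolymer runs of at least min_run."""
    runs = []
    i = 0
    while i < len(reference):
        j = i
        while j < len(reference) and reference[j] == reference[i]:
            j += 1
        if j - i >= min_run:
            runs.append((i + 1, j - i))
        i = j
    return runs


def _run_indel(
    rng: np.random.Generator, reference: str, kind: str, run_bias: float = 0.8
) -> MutationEvent:
    """A 1-bp indel, biased into homopolymer runs, leftmost-normalised."""
    runs = _homopolymer_runs(reference)
    if runs and rng.random() < run_bias:
        start, _ = runs[int(rng.integers(len(runs)))]
        pos = start  # leftmost placement within the run
        base = reference[start - 1]
    else:
        pos = int(rng.integers(2, len(reference)))
        base = reference[pos - 1]
        # walk to the leftmost equivalent placement
        while pos > 1 and reference[pos - 2] == base:
            pos -= 1
    if kind == "ins_1bp":
        return MutationEvent(position=pos, kind="insertion", ref_allele="", alt_allele=base)
    return MutationEvent(position=pos, kind="deletion", ref_allele=base, alt_allele="")


def _complex_cluster(
    rng: np.random.Generator, reference: str, window: int = 10
) -> tuple[MutationEvent, ...]:
    """Two substitutions within the complex window, at non-run positions.

    Substitution pairs cannot be re-aligned ambiguously, so the planted
    events survive the calling round trip exactly.
    """
    for _ in range(100):
        pos1 = int(rng.integers(1, len(reference) - window))
        offset = int(rng.integers(1, window + 1))
        pos2 = pos1 + offset
        ev1 = _random_substitution_at(rng, reference, pos1)
        ev2 = _random_substitution_at(rng, reference, pos2)
        return (ev1, ev2)
    raise ConfigurationError("could not place a complex cluster")


def _random_substitution_at(
    rng: np.random.Generator, reference: str, pos: int
) -> MutationEvent:
    ref_base = reference[pos - 1]
    alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
    return MutationEvent(position=pos, kind="substitution", ref_allele=ref_base, alt_allele=alt)


def _medium_deletion(
    rng: np.random.Generator,
    reference: str,
    repeat_registry: list[tuple[int, int]],
    between_repeat_fraction: float,
    length_range: tuple[int, int] = (40, 1036),
) -> MutationEvent:
    use_repeat = repeat_registry and rng.random() < between_repeat_fraction
    if use_repeat:
        start, spacing = repeat_registry[int(rng.integers(len(repeat_registry)))]
        pos, length = start, spacing
    else:
        max_len = min(length_range[1], len(reference) - 2)
        length = int(rng.integers(length_range[0], max_len + 1))
        pos = int(rng.integers(1, len(reference) - length + 1))
    allele = reference[pos - 1 : pos - 1 + length]
    ev = MutationEvent(position=pos, kind="deletion", ref_allele=allele, alt_allele="")
    # report at the leftmost equivalent placement, like the caller will
    from .spectrum import _left_normalize

    npos, nallele = _left_normalize(reference, pos, allele, "deletion")
    return MutationEvent(position=npos, kind="deletion", ref_allele=nallele, alt_allele="")


def generate_mutant_sequences(
    reference: str,
    n: int,
    spectrum_weights: dict[str, float] | None = None,
    seed: int = 0,
    complex_window: int = 10,
    between_repeat_fraction: float = 0.8,
    repeat_registry: list[tuple[int, int]] | None = None,
) -> list[SyntheticIsolate]:
    """Draw ``n`` mutant isolates from a configurable mutation spectrum.

    Each isolate carries exactly one classified mutation.  GCR isolates
    are emitted as PCR-marker rows without a sequence; every other class
    yields a mutant sequence plus its ground-truth event set, placed in
    leftmost-normalised form so the calling round trip is exact.  Medium
    deletions are carved between planted direct-repeat copies (see
    :func:`make_reporter_reference`) in ``between_repeat_fraction`` of
    cases.
    """
    if len(reference) < 100:
        raise ConfigurationError("reference must be at least 100 bp")
    weights = dict(spectrum_weights or DEFAULT_SPECTRUM_WEIGHTS)
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ConfigurationError(f"spectrum weights sum to {total}, not 1")
    rng = np.random.default_rng(seed)
    classes = sorted(weights)
    probs = np.array([weights[c] for c in classes])
    registry = repeat_registry if repeat_registry is not None else []
    isolates: list[SyntheticIsolate] = []
    for i in range(n):
        mclass = str(rng.choice(classes, p=probs))
        iso_id = f"iso{i + 1:04d}"
        if mclass == "gcr_deletion":
            isolates.append(
                SyntheticIsolate(
                    isolate_id=iso_id,
                    true_class="gcr_deletion",
                    events=(),
                    sequence=None,
                    can1_amplified=False,
                    pol2_amplified=True,
                )
            )
            continue
        for _attempt in range(100):
            if mclass == "base_substitution":
                events = (_random_substitution(rng, reference),)
            elif mclass == "ins_1bp":
                events = (_run_indel(rng, reference, "ins_1bp"),)
            elif mclass == "del_1bp":
                events = (_run_indel(rng, reference, "del_1bp"),)
            elif mclass == "complex":
                events = _complex_cluster(rng, reference, complex_window)
            elif mclass == "medium_deletion":
                events = (
                    _medium_deletion(
                        rng, reference, registry, between_repeat_fraction
                    ),
                )
            else:
                raise ConfigurationError(f"cannot generate class {mclass!r}")
            try:
                seq = apply_events(reference, events)
                break
            except Exception:
                continue
        else:
            raise ConfigurationError(f"could not place a {mclass} mutation")
        isolates.append(
            SyntheticIsolate(
                isolate_id=iso_id,
                true_class=mclass,
                events=tuple(sorted(events)),
                sequence=seq,
                can1_amplified=True,
                pol2_amplified=True,
            )
        )
    return isolates
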