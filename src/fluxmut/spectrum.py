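"""Mutation calling and spectrum classification for reporter ORFs.

Each canavanine-resistant (or His+ revertant) isolate yields either a
finished mutant ORF sequence or, when the reporter gene no longer
amplifies by PCR, evidence of a gross chromosomal rearrangement (GCR).
Sequenced isolates are compared with the reference ORF by global
alignment; the resulting events are clustered and assigned to the
spectrum classes used for reporter-gene studies:

* base substitution
* 1-bp insertion / 1-bp deletion
* complex mutation — two or more changes within a short (~10 bp) window,
  a signature of DNA polymerase zeta
* medium-size deletion — a single deletion of intermediate length, often
  bounded by direct repeats at its junctions
* GCR deletion — whole-reporter loss called from the PCR marker table
* other — anything that fits none of the above (e.g. a lone 2-bp
  insertion outside a cluster)

Coordinates are 1-based on the reporter coding strand; indels are
left-normalised within homopolymer runs and placed at the leftmost
affected base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from Bio import Align

from .ld import InvalidParameterError

__all__ = [
    "MutationEvent",
    "ClassifiedMutation",
    "SpectrumRates",
    "RepeatJunction",
    "call_mutations",
    "cluster_and_classify",
    "classify_gcr_pcr",
    "spectrum_rates",
    "his7_reversion_check",
    "find_junction_repeats",
    "apply_events",
    "MUTATION_CLASSES",
]

MUTATION_CLASSES = (
    "base_substitution",
    "ins_1bp",
    "del_1bp",
    "complex",
    "medium_deletion",
    "gcr_deletion",
    "other",
)

_DNA = set("ACGT")


class InvalidSequenceError(ValueError):
    """Raised for sequences containing non-ACGT characters."""


class SuspiciousPairError(ValueError):
    """Raised when reference and mutant differ by more than the edit cap."""


class InvalidCoordinatesError(ValueError):
    """Raised when an event lies outside its reference."""


@dataclass(frozen=True, order=True)
class MutationEvent:
    """One called difference between a mutant and the reference ORF.

    ``position`` is the 1-based coordinate of the affected base on the
    coding strand; for indels it is the leftmost affected base after
    normalisation.  The absent side of an indel is the empty string.
    """

    position: int
    kind: str  # substitution | insertion | deletion
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.kind not in ("substitution", "insertion", "deletion"):
            raise InvalidParameterError(f"unknown event kind {self.kind!r}")
        if self.position < 1:
            raise InvalidCoordinatesError("positions are 1-based")
        for allele in (self.ref_allele, self.alt_allele):
            if set(allele) - _DNA:
                raise InvalidSequenceError(f"non-ACGT allele {allele!r}")
        if self.kind == "substitution" and not (
            len(self.ref_allele) == len(self.alt_allele) == 1
        ):
            raise InvalidParameterError("substitutions carry single-base alleles")
        if self.kind == "insertion" and (self.ref_allele or not self.alt_allele):
            raise InvalidParameterError("insertion must have empty ref allele")
        if self.kind == "deletion" and (self.alt_allele or not self.ref_allele):
            raise InvalidParameterError("deletion must have empty alt allele")

    @property
    def length(self) -> int:
        return max(len(self.ref_allele), len(self.alt_allele))

    @property
    def frameshift(self) -> int:
        """Signed reading-frame change contributed by this event."""
        return len(self.alt_allele) - len(self.ref_allele)


@dataclass(frozen=True)
class ClassifiedMutation:
    """The events of one isolate with their spectrum class."""

    events: tuple[MutationEvent, ...]
    mclass: str
    net_frameshift: int


@dataclass(frozen=True)
class SpectrumRates:
    """Per-class decomposition of a genotype's total mutation rate."""

    total_rate: float
    class_counts: dict[str, int]
    class_rates: dict[str, float]
    n_isolates: int


@dataclass(frozen=True)
class RepeatJunction:
    """A direct repeat straddling the two breakpoints of a deletion."""

    deletion: MutationEvent
    repeat_seq_left: str
    repeat_seq_right: str
    repeat_length: int
    mismatches: int

    @property
    def is_perfect(self) -> bool:
        return self.mismatches == 0


def _validate_dna(seq: str, label: str) -> None:
    if not seq:
        raise InvalidSequenceError(f"{label} sequence is empty")
    extra = set(seq) - _DNA
    if extra:
        raise InvalidSequenceError(
            f"{label} sequence contains non-ACGT characters {sorted(extra)}"
        )


def _left_normalize(
    reference: str, position: int, allele: str, kind: str
) -> tuple[int, str]:
    """Shift an indel to its leftmost equivalent placement.

    Within a homopolymer run (or more generally whenever the base left of
    the indel equals the last base of the varying allele) the indel can be
    slid left without changing the mutant sequence; the convention here is
    the leftmost placement, matching standard variant normalisation.
    """
    pos, seq = position, allele
    while pos > 1 and reference[pos - 2] == seq[-1]:
        seq = reference[pos - 2] + seq[:-1]
        pos -= 1
    return pos, seq


def _make_aligner() -> Align.PairwiseAligner:
    """Global aligner with gap-affine scoring.

    Mismatch costs 1 and a gap costs 2.5 to open plus 0.01 per base to
    extend, so a kilobase-scale deletion aligns as one contiguous gap
    instead of a same-cost mosaic of mismatches and short gaps (the
    ambiguity of unit-cost edit alignment), while short substitution
    clusters still align base-per-base.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.5
    aligner.extend_gap_score = -0.01
    return aligner


_ALIGNER = _make_aligner()


def call_mutations(
    reference: str, mutant: str, max_edit_distance: int = 50
) -> list[MutationEvent]:
    """Call the differences between a mutant ORF and its reference.

    Global gap-affine alignment followed by left-normalisation of indels
    within homopolymer runs and merging of touching same-type indels.
    Substitutions are reported per base so that clustered changes can
    later be recognised as complex mutations.

    To guard against mispaired inputs, a difference count — substituted
    bases, plus inserted bases, plus one per deletion gap regardless of
    its length — above ``max_edit_distance`` raises
    :class:`SuspiciousPairError`.  Counting each deletion once keeps a
    legitimate kilobase-scale deletion callable, while counting inserted
    bases in full rejects unrelated sequences that would otherwise align
    as a delete-everything/insert-everything pair.
    """
    _validate_dna(reference, "reference")
    _validate_dna(mutant, "mutant")
    if reference == mutant:
        return []
    alignment = _ALIGNER.align(reference, mutant)[0]
    ref_blocks, mut_blocks = alignment.aligned
    events: list[MutationEvent] = []
    prev_ref_end = 0
    prev_mut_end = 0
    for (r0, r1), (q0, q1) in zip(ref_blocks, mut_blocks):
        if r0 > prev_ref_end:  # reference bases skipped: deletion
            pos, allele = _left_normalize(
                reference, prev_ref_end + 1, reference[prev_ref_end:r0], "deletion"
            )
            events.append(
                MutationEvent(position=pos, kind="deletion", ref_allele=allele, alt_allele="")
            )
        if q0 > prev_mut_end:  # mutant bases skipped: insertion
            pos, allele = _left_normalize(
                reference, r0 + 1, mutant[prev_mut_end:q0], "insertion"
            )
            events.append(
                MutationEvent(position=pos, kind="insertion", ref_allele="", alt_allele=allele)
            )
        for k in range(r1 - r0):
            if reference[r0 + k] != mutant[q0 + k]:
                events.append(
                    MutationEvent(
                        position=r0 + k + 1,
                        kind="substitution",
                        ref_allele=reference[r0 + k],
                        alt_allele=mutant[q0 + k],
                    )
                )
        prev_ref_end, prev_mut_end = r1, q1
    if len(reference) > prev_ref_end:  # trailing deletion
        pos, allele = _left_normalize(
            reference, prev_ref_end + 1, reference[prev_ref_end:], "deletion"
        )
        events.append(
            MutationEvent(position=pos, kind="deletion", ref_allele=allele, alt_allele="")
        )
    if len(mutant) > prev_mut_end:  # trailing insertion
        events.append(
            MutationEvent(
                position=len(reference) + 1,
                kind="insertion",
                ref_allele="",
                alt_allele=mutant[prev_mut_end:],
            )
        )
    events.sort(key=lambda e: (e.position, e.kind))
    events = _merge_touching_indels(events)
    distance = sum(1 if e.kind == "deletion" else e.length for e in events)
    if distance > max_edit_distance:
        raise SuspiciousPairError(
            f"distance {distance} (substituted bases + gaps) "
            f"exceeds cap {max_edit_distance}"
        )
    return events


def _merge_touching_indels(events: list[MutationEvent]) -> list[MutationEvent]:
    """Merge same-type indels that touch after normalisation."""
    merged: list[MutationEvent] = []
    for ev in events:
        if merged and ev.kind == merged[-1].kind and ev.kind in ("insertion", "deletion"):
            prev = merged[-1]
            if ev.kind == "deletion" and ev.position == prev.position + prev.length:
                merged[-1] = MutationEvent(
                    position=prev.position,
                    kind="deletion",
                    ref_allele=prev.ref_allele + ev.ref_allele,
                    alt_allele="",
                )
                continue
            if ev.kind == "insertion" and ev.position == prev.position:
                merged[-1] = MutationEvent(
                    position=prev.position,
                    kind="insertion",
                    ref_allele="",
                    alt_allele=prev.alt_allele + ev.alt_allele,
                )
                continue
        merged.append(ev)
    return merged


def cluster_and_classify(
    events: Sequence[MutationEvent],
    complex_window: int = 10,
    medium_del_range: tuple[int, int] = (11, 10_000),
) -> ClassifiedMutation:
    """Assign the spectrum class of one isolate's called events.

    Events whose positions lie within ``complex_window`` of each other are
    merged transitively into one candidate cluster.  A cluster of two or
    more events is a complex mutation; a lone substitution, 1-bp insertion
    or 1-bp deletion keeps its elementary class; a lone deletion whose
    length falls in ``medium_del_range`` is a medium-size deletion; any
    other configuration is ``other``.
    """
    if not events:
        raise InvalidParameterError("no events to classify")
    evs = list(events)
    if any(evs[i].position > evs[i + 1].position for i in range(len(evs) - 1)):
        warnings.warn("events were not sorted by position; sorting internally")
        evs.sort(key=lambda e: (e.position, e.kind))
    clusters: list[list[MutationEvent]] = [[evs[0]]]
    for ev in evs[1:]:
        if ev.position - clusters[-1][-1].position <= complex_window:
            clusters[-1].append(ev)
        else:
            clusters.append([ev])
    net = sum(e.frameshift for e in evs)
    if len(clusters) == 1:
        cluster = clusters[0]
        if len(cluster) >= 2:
            mclass = "complex"
        else:
            ev = cluster[0]
            if ev.kind == "substitution":
                mclass = "base_substitution"
            elif ev.kind == "insertion" and ev.length == 1:
                mclass = "ins_1bp"
            elif ev.kind == "deletion" and ev.length == 1:
                mclass = "del_1bp"
            elif (
                ev.kind == "deletion"
                and medium_del_range[0] <= ev.length <= medium_del_range[1]
            ):
                mclass = "medium_deletion"
            else:
                mclass = "other"
    else:
        mclass = "other"
    return ClassifiedMutation(events=tuple(evs), mclass=mclass, net_frameshift=net)


def classify_gcr_pcr(can1_amplified: bool, pol2_amplified: bool) -> str:
    """Screen an isolate's PCR markers for whole-reporter loss.

    An isolate whose genomic DNA fails to template the reporter (CAN1)
    amplicon while producing the unlinked control (POL2) amplicon has lost
    the reporter to a gross chromosomal rearrangement.  Failure of the
    control amplicon invalidates the DNA preparation.
    """
    if not pol2_amplified:
        return "invalid_dna"
    if not can1_amplified:
        return "gcr_deletion"
    return "sequence_required"


def spectrum_rates(
    total_rate: float,
    classified: Sequence[ClassifiedMutation],
    gcr_calls: Sequence[str] = (),
) -> SpectrumRates:
    """Decompose a genotype's total rate into per-class rates.

    Each class rate is its isolate fraction times the total rate, so the
    class rates sum back to the total.  PCR-called GCR isolates enter both
    the denominator and the ``gcr_deletion`` class; invalid-DNA isolates
    are excluded entirely.
    """
    n_gcr = sum(1 for call in gcr_calls if call == "gcr_deletion")
    n = len(classified) + n_gcr
    if n == 0:
        raise InvalidParameterError("no isolates to decompose over")
    if total_rate < 0:
        raise InvalidParameterError("total rate must be nonnegative")
    counts = {c: 0 for c in MUTATION_CLASSES}
    for cm in classified:
        counts[cm.mclass] += 1
    counts["gcr_deletion"] += n_gcr
    rates = {c: (k / n) * total_rate for c, k in counts.items()}
    return SpectrumRates(
        total_rate=total_rate, class_counts=counts, class_rates=rates, n_isolates=n
    )


def his7_reversion_check(
    events: Sequence[MutationEvent], window_start: int, window_length: int = 51
) -> bool:
    """Decide whether a set of events reverts the his7-2 frameshift.

    The his7-2 allele reverts to HIS7 through a net +1 frameshift within a
    51-bp region containing an A7 run.  True when the events inside the
    window sum to a net +1 frame change and events outside the window are
    frame-neutral.
    """
    if window_start < 1 or window_length < 1:
        raise InvalidCoordinatesError("window must lie within the reference")
    window_end = window_start + window_length - 1
    inside = sum(
        e.frameshift for e in events if window_start <= e.position <= window_end
    )
    outside = sum(
        e.frameshift for e in events if not (window_start <= e.position <= window_end)
    )
    return inside == 1 and outside == 0


def find_junction_repeats(
    reference: str,
    deletion: MutationEvent,
    min_len: int = 4,
    max_mismatches: int = 1,
) -> RepeatJunction | None:
    """Search a deletion's junctions for a flanking direct repeat.

    Medium-size deletions frequently arise between perfect or nearly
    perfect direct repeats, one copy at each breakpoint, with one copy plus
    the intervening spacer removed.  For a deletion of length L starting at
    0-based ``d``, candidate copies are the windows ``[i, i+k)`` and
    ``[i+L, i+L+k)`` with ``i`` in ``[d-k, d]``, so that one copy overlaps
    or abuts the 5' junction and the other the 3' junction.  The hit of
    maximal length with at most ``max_mismatches`` Hamming mismatches is
    returned (ties: fewer mismatches, then 5'-most); repeats shorter than
    ``min_len`` are discarded.
    """
    if deletion.kind != "deletion":
        raise InvalidParameterError("junction search requires a deletion event")
    d = deletion.position - 1
    length = deletion.length
    if d < 0 or d + length > len(reference):
        raise InvalidCoordinatesError("deletion outside reference bounds")
    if reference[d : d + length] != deletion.ref_allele:
        raise InvalidCoordinatesError("deletion allele does not match reference")
    best: tuple[int, int, int] | None = None  # (k, mismatches, i)
    k_max = min(length, len(reference))
    for k in range(k_max, min_len - 1, -1):
        if best is not None:
            break
        for i in range(d - k, d + 1):
            if i < 0 or i + length + k > len(reference):
                continue
            left = reference[i : i + k]
            right = reference[i + length : i + length + k]
            mm = sum(1 for a, b in zip(left, right) if a != b)
            if mm <= max_mismatches:
                if best is None or (mm, i) < (best[1], best[2]):
                    best = (k, mm, i)
    if best is None:
        return None
    k, mm, i = best
    return RepeatJunction(
        deletion=deletion,
        repeat_seq_left=reference[i : i + k],
        repeat_seq_right=reference[i + length : i + length + k],
        repeat_length=k,
        mismatches=mm,
    )


def apply_events(reference: str, events: Sequence[MutationEvent]) -> str:
    """Apply events to a reference; the inverse of :func:`call_mutations`."""
    seq = list(reference)
    for ev in sorted(events, key=lambda e: e.position, reverse=True):
        idx = ev.position - 1
        if ev.kind == "substitution":
            if seq[idx] != ev.ref_allele:
                raise InvalidCoordinatesError("substitution ref allele mismatch")
            seq[idx] = ev.alt_allele
        elif ev.kind == "deletion":
            if "".join(seq[idx : idx + ev.length]) != ev.ref_allele:
                raise InvalidCoordinatesError("deletion ref allele mismatch")
            del seq[idx : idx + ev.length]
        else:  # insertion before the recorded position
            seq[idx:idx] = list(ev.alt_allele)
    return "".join(seq)
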