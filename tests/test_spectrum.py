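"""Unit tests for mutation calling, classification and junction repeats."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fluxmut.spectrum import (
    InvalidParameterError,
    InvalidSequenceError,
    MutationEvent,
    SuspiciousPairError,
    apply_events,
    call_mutations,
    classify_gcr_pcr,
    cluster_and_classify,
    find_junction_repeats,
    his7_reversion_check,
    spectrum_rates,
)


def sub(pos, ref, alt):
    return MutationEvent(position=pos, kind="substitution", ref_allele=ref, alt_allele=alt)


def ins(pos, alt):
    return MutationEvent(position=pos, kind="insertion", ref_allele="", alt_allele=alt)


def dele(pos, ref):
    return MutationEvent(position=pos, kind="deletion", ref_allele=ref, alt_allele="")


REF = "GATTACAGCTAGCTAGGACTAAAAAAATTCGATCGGATTTTCATCGATCGGCATGCATGC"
#      123456789012345678901234567890123456789012345678901234567890
#               1111111111222222222233333333334444444444555555555560
# A7 run at positions 21-27; T4 run at 38-41


class TestCallMutations:
    def test_identical_sequences_yield_no_events(self):
        assert call_mutations(REF, REF) == []

    def test_single_substitution(self):
        mut = REF[:9] + "A" + REF[10:]
        assert call_mutations(REF, mut) == [sub(10, "T", "A")]

    def test_run_insertion_is_left_normalised(self):
        # extending the A7 at 21-27 into A8: the call sits at the run start
        mut = REF[:20] + "A" + REF[20:]
        events = call_mutations(REF, mut)
        assert events == [ins(21, "A")]

    def test_run_deletion_is_left_normalised(self):
        mut = REF[:24] + REF[25:]  # remove one A from the run interior
        assert call_mutations(REF, mut) == [dele(21, "A")]

    def test_multibase_deletion_called_as_one_event(self):
        mut = REF[:30] + REF[45:]
        events = call_mutations(REF, mut)
        assert len(events) == 1
        assert events[0].kind == "deletion"
        assert events[0].length == 15

    def test_round_trip_of_planted_events(self):
        events = [sub(5, REF[4], "G" if REF[4] != "G" else "C"), dele(33, REF[32])]
        mutant = apply_events(REF, events)
        called = call_mutations(REF, mutant)
        assert apply_events(REF, called) == mutant

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(InvalidSequenceError):
            call_mutations(REF, REF[:-1] + "N")

    def test_mispaired_sequences_rejected(self):
        rng = np.random.default_rng(0)
        other = "".join(rng.choice(list("ACGT"), size=len(REF)))
        with pytest.raises(SuspiciousPairError):
            call_mutations(REF, other, max_edit_distance=10)


class TestClusterAndClassify:
    def test_two_substitutions_within_window_are_complex(self):
        cm = cluster_and_classify([sub(100, "A", "G"), sub(105, "C", "T")])
        assert cm.mclass == "complex"
        assert cm.net_frameshift == 0

    def test_insertion_plus_adjacent_substitution_is_complex_plus_one(self):
        cm = cluster_and_classify([ins(200, "A"), sub(201, "C", "T")])
        assert cm.mclass == "complex"
        assert cm.net_frameshift == 1

    def test_lone_events_keep_elementary_classes(self):
        assert cluster_and_classify([sub(10, "A", "G")]).mclass == "base_substitution"
        assert cluster_and_classify([ins(10, "G")]).mclass == "ins_1bp"
        assert cluster_and_classify([dele(10, "G")]).mclass == "del_1bp"

    def test_medium_deletion_by_length(self):
        cm = cluster_and_classify([dele(100, "A" * 500)])
        assert cm.mclass == "medium_deletion"
        assert cm.net_frameshift == -500

    def test_two_bp_insertion_alone_is_other(self):
        assert cluster_and_classify([ins(10, "GT")]).mclass == "other"

    def test_distant_events_are_other(self):
        cm = cluster_and_classify([sub(10, "A", "G"), sub(500, "C", "T")])
        assert cm.mclass == "other"

    def test_unsorted_events_warn_and_sort(self):
        with pytest.warns(UserWarning):
            cm = cluster_and_classify([sub(105, "C", "T"), sub(100, "A", "G")])
        assert cm.mclass == "complex"

    def test_classification_is_a_fixed_point(self):
        cm = cluster_and_classify([sub(100, "A", "G"), sub(105, "C", "T")])
        again = cluster_and_classify(cm.events)
        assert again == cm


class TestGcrPcr:
    @pytest.mark.parametrize(
        "can1,pol2,expected",
        [
            (False, True, "gcr_deletion"),
            (True, True, "sequence_required"),
            (True, False, "invalid_dna"),
            (False, False, "invalid_dna"),
        ],
    )
    def test_decision_table(self, can1, pol2, expected):
        assert classify_gcr_pcr(can1, pol2) == expected


class TestSpectrumRates:
    def test_gcr_fraction_times_total(self):
        # 40% whole-reporter losses of a 480e-8 total rate -> 190e-8 class rate
        classified = [
            cluster_and_classify([sub(10, "A", "G")]) for _ in range(60)
        ]
        gcr_calls = ["gcr_deletion"] * 40
        sr = spectrum_rates(480e-8, classified, gcr_calls)
        assert sr.class_rates["gcr_deletion"] == pytest.approx(192e-8)
        assert sr.n_isolates == 100

    def test_conservation(self):
        classified = [
            cluster_and_classify([sub(10, "A", "G")]),
            cluster_and_classify([ins(21, "A")]),
            cluster_and_classify([dele(100, "A" * 100)]),
        ]
        sr = spectrum_rates(3.3e-7, classified, ["gcr_deletion", "invalid_dna"])
        assert sum(sr.class_rates.values()) == pytest.approx(3.3e-7, rel=1e-12)
        assert sr.n_isolates == 4  # invalid DNA is excluded

    def test_single_class_takes_the_whole_rate(self):
        classified = [cluster_and_classify([sub(10, "A", "G")])] * 5
        sr = spectrum_rates(1e-7, classified)
        assert sr.class_rates["base_substitution"] == pytest.approx(1e-7)

    def test_uniform_four_classes(self):
        classified = (
            [cluster_and_classify([sub(10, "A", "G")])] * 25
            + [cluster_and_classify([ins(21, "A")])] * 25
            + [cluster_and_classify([dele(10, "G")])] * 25
            + [cluster_and_classify([dele(100, "A" * 60)])] * 25
        )
        sr = spectrum_rates(4e-7, classified)
        for c in ("base_substitution", "ins_1bp", "del_1bp", "medium_deletion"):
            assert sr.class_rates[c] == pytest.approx(1e-7)

    def test_empty_isolates_rejected(self):
        with pytest.raises(InvalidParameterError):
            spectrum_rates(1e-7, [], [])


class TestHis7Reversion:
    def test_single_run_insertion_reverts(self):
        assert his7_reversion_check([ins(105, "A")], window_start=100)

    def test_no_events_do_not_revert(self):
        assert not his7_reversion_check([], window_start=100)

    def test_complex_net_plus_one_reverts(self):
        events = [ins(105, "A"), sub(106, "C", "T")]
        assert his7_reversion_check(events, window_start=100)

    def test_frameshift_outside_window_blocks(self):
        events = [ins(105, "A"), dele(300, "G")]
        assert not his7_reversion_check(events, window_start=100)

    def test_net_plus_two_does_not_revert(self):
        assert not his7_reversion_check([ins(105, "AG")], window_start=100)

    @given(st.permutations([ins(105, "A"), sub(110, "C", "T"), sub(130, "G", "A")]))
    def test_order_invariance(self, events):
        assert his7_reversion_check(list(events), window_start=100)


def brute_force_junction(reference, deletion, min_len, max_mismatches):
    """Exhaustive scan over all repeat lengths and placements."""
    d = deletion.position - 1
    length = deletion.length
    best = None
    for k in range(min_len, min(length, len(reference)) + 1):
        for i in range(len(reference)):
            if not (i <= d <= i + k):
                continue
            if i < 0 or i + length + k > len(reference):
                continue
            left = reference[i : i + k]
            right = reference[i + length : i + length + k]
            mm = sum(1 for a, b in zip(left, right) if a != b)
            if mm <= max_mismatches:
                cand = (-k, mm, i)
                if best is None or cand < best:
                    best = cand
    if best is None:
        return None
    return (-best[0], best[1], best[2])


class TestJunctionRepeats:
    def make_deletion(self, reference, pos, length):
        return dele(pos, reference[pos - 1 : pos - 1 + length])

    def test_engineered_perfect_repeat(self):
        rng = np.random.default_rng(1)
        seq = list(rng.choice(list("ACGT"), size=200))
        unit = list("ACGTACGT")
        seq[49:57] = unit
        seq[99:107] = unit  # spacing 50
        reference = "".join(seq)
        hit = find_junction_repeats(
            reference, self.make_deletion(reference, 50, 50), max_mismatches=0
        )
        assert hit is not None
        assert hit.repeat_length >= 8
        assert hit.is_perfect

    def test_nearly_perfect_repeat_reports_mismatch(self):
        rng = np.random.default_rng(2)
        seq = list(rng.choice(list("ACGT"), size=200))
        seq[49:57] = list("ACGTACGT")
        seq[99:107] = list("ACCTACGT")  # one internal mismatch
        reference = "".join(seq)
        hit = find_junction_repeats(reference, self.make_deletion(reference, 50, 50))
        oracle = brute_force_junction(reference, self.make_deletion(reference, 50, 50), 4, 1)
        assert hit is not None
        assert (hit.repeat_length, hit.mismatches) == (oracle[0], oracle[1])

    def test_random_sequence_usually_has_no_long_repeat(self):
        rng = np.random.default_rng(3)
        none_count = 0
        for _ in range(20):
            reference = "".join(rng.choice(list("ACGT"), size=200))
            deletion = self.make_deletion(reference, 80, 40)
            if find_junction_repeats(reference, deletion, min_len=10) is None:
                none_count += 1
        assert none_count >= 18

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            reference = "".join(rng.choice(list("ACGT"), size=150))
            pos = int(rng.integers(20, 80))
            length = int(rng.integers(10, 50))
            deletion = self.make_deletion(reference, pos, length)
            hit = find_junction_repeats(reference, deletion, min_len=3)
            oracle = brute_force_junction(reference, deletion, 3, 1)
            if oracle is None:
                assert hit is None
            else:
                assert hit is not None
                assert (hit.repeat_length, hit.mismatches) == (oracle[0], oracle[1])

    def test_out_of_bounds_deletion_rejected(self):
        from fluxmut.spectrum import InvalidCoordinatesError

        with pytest.raises(InvalidCoordinatesError):
            find_junction_repeats("ACGTACGT", dele(7, "GTAA"))

    def test_non_deletion_rejected(self):
        with pytest.raises(InvalidParameterError):
            find_junction_repeats("ACGTACGT", sub(2, "C", "T"))
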