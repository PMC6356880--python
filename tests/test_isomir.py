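"""Seed-anchored classification, templated checks and variant filtering."""

import pandas as pd
import pytest
from importlib import resources

from mirforge.esv_model import ESVProfile, FilterParams
from mirforge.formats_io import GenomicLocus
from mirforge.isomir import (
    CANONICAL,
    ISOMIR_3P_LEN,
    ISOMIR_3P_SUB,
    ISOMIR_5P,
    MISMATCH_INTERNAL,
    IsomiRCall,
    MatureRecord,
    MiRNAome,
    PrecursorRecord,
    call_isomirs,
    call_polymorphisms,
    check_templated,
    classify_read,
    polymorphism_from_pair,
    summarize_classes,
)
from mirforge.preprocess import CollapsedRead

PROFILE = ESVProfile(r5=0.02, r_int=0.0004, r3=0.21)

# hand-built two-gene miRNAome: 5p arm is a prefix, 3p arm a suffix
ARM_A = "UGAGGUAGUAGGUUGUAUAGUU"
ARM_B = "ACCCGUAGAUCCGAACUUGUGG"
LOOP = "CGAAUAGCAAUGACG"  # starts with C: U-addition on 5p is non-templated


def _revcomp(s):
    return s.translate(str.maketrans("ACGU", "UGCA"))[::-1]


def build_mirnaome():
    precursors, matures = [], []
    for name, arm in (("mirA", ARM_A), ("mirB", ARM_B)):
        pre_seq = arm + LOOP + _revcomp(arm)
        precursors.append(
            PrecursorRecord(
                id=name,
                sequence=pre_seq,
                locus=GenomicLocus("chr1", 100, 100 + len(pre_seq), "+"),
                flank5="A" * 29 + "C",
                flank3="G" + "A" * 29,
                mature5p=f"{name}-5p",
                mature3p=f"{name}-3p",
            )
        )
        matures.append(MatureRecord(f"{name}-5p", arm, "5p", name))
        matures.append(MatureRecord(f"{name}-3p", _revcomp(arm), "3p", name))
    return MiRNAome(precursors, matures)


@pytest.fixture(scope="module")
def mirnaome():
    return build_mirnaome()


class TestClassifyRead:
    def test_identical_read_is_canonical(self, mirnaome):
        call = classify_read(ARM_A, mirnaome.ordered_matures())
        assert call.category == CANONICAL
        assert call.parent == "mirA-5p"
        assert not call.edits and not call.extension

    def test_trailing_u_is_3p_length_variant(self, mirnaome):
        call = classify_read(ARM_A + "U", mirnaome.ordered_matures())
        assert call.category == ISOMIR_3P_LEN
        assert call.extension == "U"

    def test_internal_substitution(self, mirnaome):
        read = ARM_A[:9] + ("A" if ARM_A[9] != "A" else "C") + ARM_A[10:]
        call = classify_read(read, mirnaome.ordered_matures())
        assert call.category == MISMATCH_INTERNAL
        assert call.edits == [(10, ARM_A[9], read[9])]

    def test_terminal_substitution_is_3p_sub(self, mirnaome):
        read = ARM_A[:-1] + ("A" if ARM_A[-1] != "A" else "C")
        call = classify_read(read, mirnaome.ordered_matures())
        assert call.category == ISOMIR_3P_SUB

    def test_five_prime_extension(self, mirnaome):
        call = classify_read("G" + ARM_A, mirnaome.ordered_matures())
        assert call.category == ISOMIR_5P
        assert call.shift5 == 1

    def test_first_base_substitution_is_5p(self, mirnaome):
        read = ("A" if ARM_A[0] != "A" else "C") + ARM_A[1:]
        call = classify_read(read, mirnaome.ordered_matures())
        assert call.category == ISOMIR_5P

    def test_no_seed_anchor_returns_none(self, mirnaome):
        assert classify_read("A" * 22, mirnaome.ordered_matures()) is None

    def test_seed_mutated_read_does_not_anchor_to_parent(self, mirnaome):
        read = ARM_A[:4] + ("A" if ARM_A[4] != "A" else "C") + ARM_A[5:]
        call = classify_read(read, mirnaome.ordered_matures())
        assert call is None or call.parent != "mirA-5p"

    def test_truncated_read_flagged_shorter(self, mirnaome):
        call = classify_read(ARM_A[:-3], mirnaome.ordered_matures())
        assert call.trim3 == 3 and call.shorter_than_canonical


class TestTemplated:
    def test_templated_extension_matches_downstream(self, mirnaome):
        # downstream of the 5p arm is the loop, which starts with C
        call = classify_read(ARM_A + "C", mirnaome.ordered_matures())
        pre = mirnaome.precursor_of(call.parent)
        assert check_templated(call, pre, mirnaome.matures) is True

    def test_u_addition_non_templated(self, mirnaome):
        call = classify_read(ARM_A + "U", mirnaome.ordered_matures())
        pre = mirnaome.precursor_of(call.parent)
        assert check_templated(call, pre, mirnaome.matures) is False

    def test_substitution_never_templated(self, mirnaome):
        read = ARM_A[:-1] + ("A" if ARM_A[-1] != "A" else "C")
        call = classify_read(read, mirnaome.ordered_matures())
        pre = mirnaome.precursor_of(call.parent)
        assert check_templated(call, pre, mirnaome.matures) is False

    def test_templated_5p_shift_detected(self, mirnaome):
        # upstream genomic base (flank5 end) is C by construction
        call = classify_read("C" + ARM_A, mirnaome.ordered_matures())
        pre = mirnaome.precursor_of(call.parent)
        assert check_templated(call, pre, mirnaome.matures) is True

    def test_missing_flanks_raise(self, mirnaome):
        call = classify_read(ARM_A + "U", mirnaome.ordered_matures())
        bare = PrecursorRecord(id="x", sequence=ARM_A + LOOP + _revcomp(ARM_A))
        with pytest.raises(ValueError):
            check_templated(call, bare, mirnaome.matures)


class TestCallIsomirs:
    def make_collapsed(self):
        return [
            CollapsedRead(ARM_A, 1000),                 # canonical
            CollapsedRead(ARM_A + "U", 500),            # non-templated, above threshold
            CollapsedRead(ARM_A + "C", 800),            # templated -> excluded
            CollapsedRead(ARM_A[:-3], 400),             # degradation-like -> excluded
            CollapsedRead(ARM_B, 1000),
            CollapsedRead(ARM_B + "U", 100),            # below 3'-class threshold (420)
        ]

    def test_filtering_and_exclusions(self, mirnaome):
        calls = call_isomirs(self.make_collapsed(), mirnaome, PROFILE)
        by_seq = {c.read.sequence: c for c in calls}
        assert by_seq[ARM_A].category == CANONICAL
        u_call = by_seq[ARM_A + "U"]
        assert u_call.category == ISOMIR_3P_LEN and u_call.passed_filter
        assert u_call.threshold_used == 420  # ceil(2 * 0.21 * 1000)
        assert ARM_A + "C" not in by_seq          # templated length variant
        assert ARM_A[:-3] not in by_seq           # shorter than canonical
        weak = by_seq[ARM_B + "U"]
        assert not weak.passed_filter

    def test_every_reported_variant_is_non_templated(self, mirnaome):
        calls = call_isomirs(self.make_collapsed(), mirnaome, PROFILE)
        for c in calls:
            if c.category != CANONICAL:
                assert c.templated is False


class TestPolymorphisms:
    def _variant(self, fraction_reads, canonical_reads):
        read = ARM_A[:9] + ("A" if ARM_A[9] != "A" else "C") + ARM_A[10:]
        return [
            CollapsedRead(ARM_A, canonical_reads),
            CollapsedRead(read, fraction_reads),
        ]

    def test_fraction_above_threshold_called(self, mirnaome):
        calls = call_polymorphisms(self._variant(450, 600), mirnaome, PROFILE)
        assert len(calls) == 1
        assert calls[0].fraction == pytest.approx(450 / 1050)
        assert calls[0].position == 10 and not calls[0].in_seed

    def test_fraction_exactly_forty_percent_not_called(self, mirnaome):
        assert call_polymorphisms(self._variant(400, 600), mirnaome, PROFILE) == []

    def test_below_count_threshold_not_called(self, mirnaome):
        assert (
            call_polymorphisms(
                self._variant(9, 2), mirnaome, PROFILE, FilterParams()
            )
            == []
        )


class TestPolymorphicReferenceSet:
    """The bundled allelic-variant pairs behave as printed."""

    @pytest.fixture(scope="class")
    def pairs(self):
        path = resources.files("mirforge.data").joinpath("polymorphic_mirnas.tsv")
        with resources.as_file(path) as p:
            return pd.read_csv(p, sep="\t")

    def test_all_pairs_single_substitution(self, pairs):
        assert len(pairs) == 5
        for _, row in pairs.iterrows():
            call = polymorphism_from_pair(row["reference"], row["variant"], row["id"])
            assert call.position >= 1

    def test_exactly_one_seed_polymorphism(self, pairs):
        calls = [
            polymorphism_from_pair(r["reference"], r["variant"], r["id"])
            for _, r in pairs.iterrows()
        ]
        in_seed = [c for c in calls if c.in_seed]
        assert len(in_seed) == 1
        assert in_seed[0].parent == "ssa-miR-100a-2-3p"
        assert in_seed[0].position == 8
        assert (in_seed[0].ref, in_seed[0].alt) == ("U", "C")

    def test_hamming_distance_two_rejected(self):
        with pytest.raises(ValueError):
            polymorphism_from_pair("ACGUACGU", "AGGUACGA")


class TestSummary:
    def _calls(self, n_3p_sub, n_3p_len, n_5p):
        calls = []
        for cat, n in (
            (ISOMIR_3P_SUB, n_3p_sub),
            (ISOMIR_3P_LEN, n_3p_len),
            (ISOMIR_5P, n_5p),
        ):
            for i in range(n):
                calls.append(
                    IsomiRCall(
                        read=CollapsedRead("ACGUACGUACGUACGUAC", 50),
                        parent=f"m{cat}{i}",
                        category=cat,
                        passed_filter=True,
                    )
                )
        return calls

    def test_three_prime_percentage(self):
        summary = summarize_classes(self._calls(32, 8, 1))
        assert summary["n_variants"] == 41
        assert summary["percent_3p_end"] == 98

    def test_empty_calls_no_division_by_zero(self):
        summary = summarize_classes([])
        assert summary["n_variants"] == 0
        assert "percent_3p_end" not in summary

    def test_variant_more_abundant_than_canonical_flagged(self):
        canonical = IsomiRCall(
            read=CollapsedRead(ARM_A, 100), parent="p", category=CANONICAL,
            passed_filter=True,
        )
        variant = IsomiRCall(
            read=CollapsedRead(ARM_A + "U", 300), parent="p",
            category=ISOMIR_3P_LEN, extension="U", passed_filter=True,
        )
        summary = summarize_classes([canonical, variant])
        assert summary["more_abundant_than_canonical"] == [variant]
        assert summary["canonical_to_variant_ratio"]["p"] == pytest.approx(1 / 3)
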