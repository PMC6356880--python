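"""Hairpin folding, candidate validation rules, repeats and clusters."""

import random

import pytest

from mirforge.annotation import (
    CandidatePrecursor,
    ReadEvidence,
    annotate_clusters,
    flag_repeats,
    fold_hairpin,
    load_novel_mirnas,
    score_filter,
    table1_consistency,
    validate_criteria,
)
from mirforge.formats_io import GenomicLocus
from mirforge.isomir import PrecursorRecord

from .oracles import PAIRABLE, brute_max_pairs


def _revcomp(s):
    return s.translate(str.maketrans("ACGU", "UGCA"))[::-1]


def make_candidate(score=5.0, n_reads=15, n_samples=3, arm=None):
    arm = arm or "GCCGAGGCUGCAGCGAGGCACC"
    loop = "CAACAACAACAAC"
    pre_seq = arm + loop + _revcomp(arm)
    pre = PrecursorRecord(id="cand", sequence=pre_seq)
    s3 = len(arm) + len(loop)
    per_sample = [n_reads // n_samples + (1 if i < n_reads % n_samples else 0)
                  for i in range(n_samples)]
    evidence = []
    for i, n in enumerate(per_sample):
        if n == 0:
            continue
        evidence.append(ReadEvidence(arm, n, f"s{i + 1}", 0, 0))
    evidence.append(ReadEvidence(_revcomp(arm), 5, "s1", s3, 0))
    return CandidatePrecursor(
        precursor=pre,
        mature5p_seq=arm,
        mature3p_seq=_revcomp(arm),
        score=score,
        evidence=evidence,
    )


class TestScoreFilter:
    def test_boundary_inclusive(self):
        kept = score_filter([make_candidate(score=2.0)])
        assert len(kept) == 1

    def test_below_cutoff_removed(self):
        assert score_filter([make_candidate(score=1.99)]) == []

    def test_empty_input(self):
        assert score_filter([]) == []


class TestFoldHairpin:
    def test_simple_stem(self):
        fold = fold_hairpin("GGGAAACCC")
        assert fold.max_pairs == 3
        assert fold.pairing == {0: 8, 8: 0, 1: 7, 7: 1, 2: 6, 6: 2}

    def test_unpairable_sequence(self):
        assert fold_hairpin("AAAAAA").max_pairs == 0

    def test_min_loop_respected(self):
        fold = fold_hairpin("GCCCC" + "AAA" + "GGGGC", min_loop=3)
        for i, j in fold.pairing.items():
            if i < j:
                assert j - i > 3

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = random.Random(seed)
        n = rng.randint(8, 14)
        seq = "".join(rng.choice("ACGU") for _ in range(n))
        fold = fold_hairpin(seq)
        assert fold.max_pairs == brute_max_pairs(seq)
        # structure validity: symmetric, pairable, nested, min loop
        seen = []
        for i, j in fold.pairing.items():
            if i < j:
                assert (seq[i], seq[j]) in PAIRABLE
                assert j - i > 3
                seen.append((i, j))
        for (a, b) in seen:
            for (c, d) in seen:
                if a < c:
                    assert c > b or d < b  # no crossing

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fold_hairpin("ACG")


class TestValidateCriteria:
    def test_designed_candidate_passes_all(self):
        report = validate_criteria(make_candidate())
        assert report.passed == {
            "min_samples": True,
            "min_reads": True,
            "overhang": True,
            "five_prime_homogeneity": True,
            "mature_pairing": True,
        }
        assert report.overall

    def test_nine_reads_fail_support_rule(self):
        report = validate_criteria(make_candidate(n_reads=4))  # 4 + 5 star = 9
        assert not report.passed["min_reads"]
        assert not report.overall

    def test_single_sample_fails_replication(self):
        report = validate_criteria(make_candidate(n_samples=1))
        assert not report.passed["min_samples"]

    def test_unpairable_arms_fail_structure_rules(self):
        arm5 = "ACCCAACCCAAACCCAACCCAA"
        arm3 = "AAACCCAAACCCAAACCCAAAC"
        pre = PrecursorRecord(id="flat", sequence=arm5 + "AACAACAACAACA" + arm3)
        cand = CandidatePrecursor(
            precursor=pre,
            mature5p_seq=arm5,
            mature3p_seq=arm3,
            score=5.0,
            evidence=[
                ReadEvidence(arm5, 20, "s1", 0, 0),
                ReadEvidence(arm5, 20, "s2", 0, 0),
            ],
        )
        report = validate_criteria(cand)
        assert not report.passed["mature_pairing"]
        assert not report.passed["overhang"]
        assert not report.overall

    def test_heterogeneous_five_prime_starts_fail(self):
        cand = make_candidate()
        arm = cand.mature5p_seq
        # half of the 5p reads start one base in: modal fraction ~0.5
        cand.evidence.append(ReadEvidence(arm[1:], 15, "s1", 1, 0))
        report = validate_criteria(cand)
        assert not report.passed["five_prime_homogeneity"]

    def test_adding_modal_perfect_reads_is_monotone(self):
        cand = make_candidate()
        assert validate_criteria(cand).overall
        cand.evidence.append(ReadEvidence(cand.mature5p_seq, 100, "s4", 0, 0))
        assert validate_criteria(cand).overall

    def test_no_evidence_raises_naming_rules(self):
        cand = make_candidate()
        cand.evidence = []
        with pytest.raises(ValueError, match="min_samples"):
            validate_criteria(cand)


class TestNovelReferenceSet:
    def test_all_seventeen_rows_consistent(self):
        rows = load_novel_mirnas()
        assert len(rows) == 17
        assert table1_consistency(rows) == 17

    def test_corrupted_mature_detected(self):
        rows = load_novel_mirnas().copy()
        m = rows.loc[0, "mature_5p"]
        rows.loc[0, "mature_5p"] = ("A" if m[0] != "A" else "C") + m[1:]
        assert table1_consistency(rows) == 16


class TestFlagRepeats:
    def _genome_with_copies(self, n_copies, seed=0):
        rng = random.Random(seed)
        planted = "GCGGAUCCGAGCUCGGUACCAAGCUUGGCA"
        spacer = lambda: "".join(rng.choice("AC") for _ in range(50))
        return {"chr1": spacer() + spacer().join([planted] * n_copies) + spacer()}, planted

    def test_sixteen_loci_flagged(self):
        genome, planted = self._genome_with_copies(16)
        count, flagged = flag_repeats(planted, genome)
        assert count == 16 and flagged

    def test_fifteen_loci_not_flagged(self):
        genome, planted = self._genome_with_copies(15)
        count, flagged = flag_repeats(planted, genome)
        assert count == 15 and not flagged

    def test_single_copy(self):
        genome, planted = self._genome_with_copies(1)
        assert flag_repeats(planted, genome) == (1, False)

    def test_reverse_strand_counted(self):
        genome, planted = self._genome_with_copies(1)
        genome["chr2"] = "AC" * 30 + _revcomp(planted) + "CA" * 30
        assert flag_repeats(planted, genome)[0] == 2


class TestClusters:
    def _locus(self, lid, start, end, strand="+", contig="c1"):
        return (lid, GenomicLocus(contig, start, end, strand), {})

    def test_gap_below_threshold_clusters(self):
        loci = [self._locus("a", 0, 100), self._locus("b", 8500, 8600)]
        clusters, assignment = annotate_clusters(loci)
        assert clusters == {"cluster_a": ["a", "b"]}
        assert assignment == {"a": "cluster_a", "b": "cluster_a"}

    def test_gap_boundary_inclusive(self):
        loci = [self._locus("a", 0, 100), self._locus("b", 10_100, 10_200)]
        clusters, _ = annotate_clusters(loci)
        assert clusters == {"cluster_a": ["a", "b"]}

    def test_gap_one_past_boundary_excluded(self):
        loci = [self._locus("a", 0, 100), self._locus("b", 10_101, 10_200)]
        clusters, assignment = annotate_clusters(loci)
        assert clusters == {}
        assert assignment == {"a": None, "b": None}

    def test_opposite_strands_never_cluster(self):
        loci = [self._locus("a", 0, 100, "+"), self._locus("b", 200, 300, "-")]
        assert annotate_clusters(loci)[0] == {}

    def test_chaining_is_transitive(self):
        loci = [
            self._locus("a", 0, 100),
            self._locus("b", 9000, 9100),
            self._locus("c", 18_000, 18_100),
        ]
        clusters, _ = annotate_clusters(loci)
        assert clusters == {"cluster_a": ["a", "b", "c"]}

    def test_input_order_invariance(self):
        loci = [
            self._locus("a", 0, 100),
            self._locus("b", 5000, 5100),
            self._locus("x", 0, 50, contig="c2"),
        ]
        forward = annotate_clusters(loci)
        backward = annotate_clusters(loci[::-1])
        assert forward == backward

    def test_synthetic_mirnaome_clusters_recovered(self, synthetic_mirnaome):
        clusters, _ = annotate_clusters(synthetic_mirnaome.loci)
        found = {tuple(sorted(m)) for m in clusters.values()}
        expected = {tuple(sorted(c)) for c in synthetic_mirnaome.expected_clusters}
        assert found == expected
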