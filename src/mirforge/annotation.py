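"""Novel-miRNA candidate validation and gene-cluster annotation.

Candidate precursors (ingested with their discovery log-odds scores) are
score-filtered, checked for repeat-likeness by exact genome locus counting,
and validated against five miRBase-style evidence rules: replication across
samples, minimum perfect-read support, a plausible hairpin duplex with short
3' overhangs, homogeneous 5' processing, and a minimum pairing fraction of
the mature arms.  Hairpin structure is computed by maximum-cardinality
nested base pairing (Nussinov-style dynamic programming over AU/GC/GU pairs
with a minimum loop), a deliberately simple automatable proxy for manual
secondary-structure inspection.  Gene clusters are same-contig, same-strand
runs of loci whose inter-gene gaps do not exceed 10 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .formats_io import GenomicLocus, normalize_rna, revcomp
from .isomir import PrecursorRecord

PAIRABLE = {
    ("A", "U"), ("U", "A"),
    ("C", "G"), ("G", "C"),
    ("G", "U"), ("U", "G"),
}


@dataclass(frozen=True)
class ReadEvidence:
    """One mapped read supporting a candidate precursor."""

    sequence: str
    count: int
    sample_id: str
    offset: int  # 0-based start on the precursor
    mismatches: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.offset < 0:
            raise ValueError("offset must be within the precursor")


@dataclass
class CandidatePrecursor:
    """A discovery-pipeline candidate with score and read evidence."""

    precursor: PrecursorRecord
    mature5p_seq: str
    mature3p_seq: str
    score: float
    evidence: list[ReadEvidence] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mature5p_seq = normalize_rna(self.mature5p_seq)
        self.mature3p_seq = normalize_rna(self.mature3p_seq)
        for ev in self.evidence:
            if ev.offset >= len(self.precursor.sequence):
                raise ValueError(f"evidence offset {ev.offset} outside precursor")


@dataclass
class HairpinStructure:
    """A nested base-pairing of a sequence (0-based position -> partner)."""

    pairing: dict[int, int]
    max_pairs: int

    def __post_init__(self) -> None:
        for i, j in self.pairing.items():
            if self.pairing.get(j) != i:
                raise ValueError("pairing must be symmetric")

    def partner(self, i: int) -> int | None:
        return self.pairing.get(i)

    def paired_fraction(self, start: int, end: int) -> float:
        """Fraction of positions in [start, end) that are paired."""
        if end <= start:
            raise ValueError("empty region")
        return sum(1 for i in range(start, end) if i in self.pairing) / (end - start)


@dataclass
class CriteriaReport:
    """Per-rule outcomes of the novel-miRNA evidence check."""

    passed: dict[str, bool]
    evidence: dict[str, str]

    @property
    def overall(self) -> bool:
        return all(self.passed.values())


def score_filter(
    candidates: list[CandidatePrecursor], min_score: float = 2.0
) -> list[CandidatePrecursor]:
    """Keep candidates whose discovery score is >= ``min_score`` (inclusive)."""
    return [c for c in candidates if c.score >= min_score]


def fold_hairpin(sequence: str, min_loop: int = 3) -> HairpinStructure:
    """Maximum-cardinality nested base pairing with a minimum hairpin loop.

    Allowed pairs are AU, GC and GU; paired positions must be separated by at
    least ``min_loop`` unpaired-capable bases.  Traceback is deterministic:
    pairing (i, j) is preferred over bifurcation, then the smallest split
    point.
    """
    seq = normalize_rna(sequence)
    n = len(seq)
    if n < min_loop + 2:
        raise ValueError("sequence shorter than min_loop + 2")

    def can_pair(i: int, j: int) -> bool:
        return j - i > min_loop and (seq[i], seq[j]) in PAIRABLE

    table = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = max(table[i + 1][j], table[i][j - 1])
            if can_pair(i, j):
                inner = table[i + 1][j - 1] if i + 1 <= j - 1 else 0
                best = max(best, inner + 1)
            for k in range(i + 1, j):
                best = max(best, table[i][k] + table[k + 1][j])
            table[i][j] = best

    pairing: dict[int, int] = {}
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or table[i][j] == 0:
            continue
        if can_pair(i, j) and table[i][j] == (table[i + 1][j - 1] if i + 1 <= j - 1 else 0) + 1:
            pairing[i] = j
            pairing[j] = i
            stack.append((i + 1, j - 1))
            continue
        if table[i][j] == table[i + 1][j]:
            stack.append((i + 1, j))
            continue
        if table[i][j] == table[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i + 1, j):
            if table[i][k] + table[k + 1][j] == table[i][j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
    return HairpinStructure(pairing=pairing, max_pairs=len(pairing) // 2)


def _arm_bounds(precursor_seq: str, m5: str, m3: str) -> tuple[int, int, int, int]:
    s5 = precursor_seq.find(m5)
    s3 = precursor_seq.rfind(m3)
    if s5 == -1 or s3 == -1:
        raise ValueError("mature arms must be exact substrings of the precursor")
    return s5, s5 + len(m5), s3, s3 + len(m3)


def _duplex_overhangs(
    fold: HairpinStructure, s5: int, e5: int, s3: int, e3: int
) -> tuple[int, int] | None:
    """3' overhang lengths (5p arm, 3p arm) of the folded mature duplex.

    Returns ``None`` when no base of one arm pairs into the other arm.  An
    arm's 3' overhang counts how far its 3' end extends past the base paired
    with the partner arm's 5'-most paired base.
    """
    f5 = next(
        (i for i in range(s5, e5) if s3 <= fold.pairing.get(i, -1) < e3), None
    )
    f3 = next(
        (i for i in range(s3, e3) if s5 <= fold.pairing.get(i, -1) < e5), None
    )
    if f5 is None or f3 is None:
        return None
    overhang_3p = (e3 - 1 - fold.pairing[f5]) + (f5 - s5)
    overhang_5p = (e5 - 1 - fold.pairing[f3]) + (f3 - s3)
    return overhang_5p, overhang_3p


def validate_criteria(
    candidate: CandidatePrecursor,
    min_samples: int = 2,
    min_reads: int = 10,
    max_overhang: int = 4,
    homogeneity: float = 0.9,
    min_pairing: float = 0.60,
    min_loop: int = 3,
) -> CriteriaReport:
    """Evaluate the five evidence rules for a novel-miRNA candidate.

    Rules: detection in >= ``min_samples`` independent samples; >=
    ``min_reads`` perfect reads mapped over the mature arms; both arms of the
    folded duplex carrying a 0-``max_overhang`` nt 3' overhang; a modal 5'
    start fraction >= ``homogeneity`` on the dominant arm; and strictly more
    than ``min_pairing`` of each mature's bases paired in the hairpin.
    """
    if not candidate.evidence:
        raise ValueError(
            "no read evidence: rules min_samples, min_reads and "
            "five_prime_homogeneity are unevaluable"
        )
    seq = candidate.precursor.sequence
    s5, e5, s3, e3 = _arm_bounds(seq, candidate.mature5p_seq, candidate.mature3p_seq)
    passed: dict[str, bool] = {}
    notes: dict[str, str] = {}

    samples = {ev.sample_id for ev in candidate.evidence}
    passed["min_samples"] = len(samples) >= min_samples
    notes["min_samples"] = f"{len(samples)} samples"

    def overlaps_arm(ev: ReadEvidence) -> bool:
        r0, r1 = ev.offset, ev.offset + len(ev.sequence)
        return (r0 < e5 and r1 > s5) or (r0 < e3 and r1 > s3)

    perfect = sum(
        ev.count for ev in candidate.evidence if ev.mismatches == 0 and overlaps_arm(ev)
    )
    passed["min_reads"] = perfect >= min_reads
    notes["min_reads"] = f"{perfect} perfect mature/star reads"

    fold = fold_hairpin(seq, min_loop=min_loop)
    overhangs = _duplex_overhangs(fold, s5, e5, s3, e3)
    if overhangs is None:
        passed["overhang"] = False
        notes["overhang"] = "arms do not pair with each other"
    else:
        o5, o3 = overhangs
        passed["overhang"] = 0 <= o5 <= max_overhang and 0 <= o3 <= max_overhang
        notes["overhang"] = f"3' overhangs 5p={o5}, 3p={o3}"

    # dominant arm = the arm with more count-weighted evidence
    arm_counts = {"5p": 0, "3p": 0}
    starts: dict[str, dict[int, int]] = {"5p": {}, "3p": {}}
    for ev in candidate.evidence:
        mid5 = abs(ev.offset - s5)
        mid3 = abs(ev.offset - s3)
        arm = "5p" if mid5 <= mid3 else "3p"
        arm_counts[arm] += ev.count
        starts[arm][ev.offset] = starts[arm].get(ev.offset, 0) + ev.count
    dominant = "5p" if arm_counts["5p"] >= arm_counts["3p"] else "3p"
    total = arm_counts[dominant]
    modal = max(starts[dominant].values()) if starts[dominant] else 0
    frac = modal / total if total else 0.0
    passed["five_prime_homogeneity"] = frac >= homogeneity
    notes["five_prime_homogeneity"] = (
        f"modal 5' start fraction {frac:.2f} on {dominant} arm"
    )

    frac5 = fold.paired_fraction(s5, e5)
    frac3 = fold.paired_fraction(s3, e3)
    passed["mature_pairing"] = frac5 > min_pairing and frac3 > min_pairing
    notes["mature_pairing"] = f"paired fractions 5p={frac5:.2f}, 3p={frac3:.2f}"

    return CriteriaReport(passed=passed, evidence=notes)


def load_novel_mirnas() -> pd.DataFrame:
    """Bundled novel Atlantic salmon miRNA set (precursor + both matures)."""
    path = resources.files("mirforge.data").joinpath("novel_mirnas.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def table1_consistency(rows: pd.DataFrame) -> int:
    """Count rows whose both printed matures occur exactly in the precursor."""
    n_pass = 0
    for _, row in rows.iterrows():
        pre = normalize_rna(row["precursor"])
        if (
            normalize_rna(row["mature_5p"]) in pre
            and normalize_rna(row["mature_3p"]) in pre
        ):
            n_pass += 1
    return n_pass


def flag_repeats(
    precursor_seq: str, genome: dict[str, str], max_loci: int = 15
) -> tuple[int, bool]:
    """Count exact genome occurrences (both strands); flag repeat-like candidates.

    A candidate matching strictly more than ``max_loci`` loci is flagged as
    an interspersed repeat.
    """
    query = normalize_rna(precursor_seq)
    queries = {query, revcomp(query)}
    n = 0
    for contig_seq in genome.values():
        contig = normalize_rna(contig_seq)
        for q in queries:
            start = contig.find(q)
            while start != -1:
                n += 1
                start = contig.find(q, start + 1)
    return n, n > max_loci


def annotate_clusters(
    loci: list[tuple[str, GenomicLocus, dict]], max_gap: int = 10_000
) -> tuple[dict[str, list[str]], dict[str, str | None]]:
    """Single-linkage clustering of same-contig, same-strand miRNA loci.

    Loci sorted by start are chained while the gap from the rightmost end
    seen so far to the next start is <= ``max_gap``.  Returns
    ``(clusters, assignment)``: clusters maps a deterministic cluster id
    (named after the leftmost member) to its member ids; singletons get
    ``None`` in the assignment.
    """
    groups: dict[tuple[str, str], list[tuple[str, GenomicLocus]]] = {}
    for lid, locus, _ in loci:
        groups.setdefault((locus.contig, locus.strand), []).append((lid, locus))
    clusters: dict[str, list[str]] = {}
    assignment: dict[str, str | None] = {lid: None for lid, _, _ in loci}
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda m: (m[1].start, m[0]))
        chain: list[str] = []
        chain_end = None
        for lid, locus in members + [(None, None)]:
            if locus is not None and chain_end is not None and locus.start - chain_end <= max_gap:
                chain.append(lid)
                chain_end = max(chain_end, locus.end)
                continue
            if len(chain) > 1:
                cid = f"cluster_{chain[0]}"
                clusters[cid] = chain
                for member in chain:
                    assignment[member] = cid
            if locus is None:
                break
            chain = [lid]
            chain_end = locus.end
    return clusters, assignment
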