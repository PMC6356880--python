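"""Seed-anchored isomiR classification and allelic-variant calling.

Reads are assigned to canonical mature miRNAs by locating an exact occurrence
of a canonical's seed (bases 2-8) in the read, which fixes the alignment
register.  At that register a read is either identical to the canonical, a 5'
variant (shifted start or first-base substitution), a 3' variant (terminal
substitutions or a length change), or an internal-mismatch variant.  Variants
whose length change is templated in the genome (precursor plus flanking
context) are excluded: they cannot be told apart from precursor degradation
fragments.  Reads shorter than their canonical are likewise excluded as
degradation-indistinguishable.  The surviving non-templated variants are
filtered against the ESV count threshold of their position class; internal
single-substitution variants at high allele fraction are additionally
reported as candidate polymorphisms (allelic variants).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .esv_model import (
    CLASS_3P,
    CLASS_5P,
    CLASS_INTERNAL,
    ESVProfile,
    FilterParams,
    esv_threshold,
)
from .formats_io import GenomicLocus, normalize_rna
from .preprocess import CollapsedRead

CANONICAL = "canonical"
ISOMIR_5P = "isomir_5p"
ISOMIR_3P_SUB = "isomir_3p_sub"
ISOMIR_3P_LEN = "isomir_3p_len"
MISMATCH_INTERNAL = "mismatch_internal"

VARIANT_CATEGORIES = (ISOMIR_5P, ISOMIR_3P_SUB, ISOMIR_3P_LEN)

#: ESV position class used to threshold each variant category
CATEGORY_CLASS = {
    ISOMIR_5P: CLASS_5P,
    ISOMIR_3P_SUB: CLASS_3P,
    ISOMIR_3P_LEN: CLASS_3P,
    MISMATCH_INTERNAL: CLASS_INTERNAL,
}

SEED_START = 1  # 0-based; seed = mature bases 2-8 (1-based)
SEED_END = 8


@dataclass(frozen=True)
class MatureRecord:
    """A canonical mature miRNA excised from one arm of a precursor hairpin."""

    id: str
    sequence: str
    arm: str  # {"5p", "3p"}
    precursor_id: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"arm must be 5p or 3p, got {self.arm!r}")

    @property
    def seed(self) -> str:
        return self.sequence[SEED_START:SEED_END]


@dataclass(frozen=True)
class PrecursorRecord:
    """A miRNA hairpin precursor with genomic locus and flanking context."""

    id: str
    sequence: str
    locus: GenomicLocus | None = None
    flank5: str = ""
    flank3: str = ""
    mature5p: str | None = None  # mature record ids
    mature3p: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        object.__setattr__(self, "flank5", normalize_rna(self.flank5))
        object.__setattr__(self, "flank3", normalize_rna(self.flank3))


class MiRNAome:
    """Precursors plus their mature miRNAs, indexed by id."""

    def __init__(
        self,
        precursors: Iterable[PrecursorRecord],
        matures: Iterable[MatureRecord],
    ) -> None:
        self.precursors: dict[str, PrecursorRecord] = {
            p.id: p for p in precursors
        }
        self.matures: dict[str, MatureRecord] = {m.id: m for m in matures}
        for m in self.matures.values():
            pre = self.precursors.get(m.precursor_id)
            if pre is not None and m.sequence not in pre.sequence:
                raise ValueError(
                    f"mature {m.id} is not a substring of precursor {pre.id}"
                )

    def ordered_matures(self) -> list[MatureRecord]:
        return sorted(self.matures.values(), key=lambda m: m.id)

    def precursor_of(self, mature_id: str) -> PrecursorRecord:
        return self.precursors[self.matures[mature_id].precursor_id]


@dataclass
class IsomiRCall:
    """A collapsed read assigned to a canonical mature miRNA."""

    read: CollapsedRead
    parent: str
    category: str
    edits: list[tuple[int, str, str]] = field(default_factory=list)  # 1-based
    extension: str = ""  # non-empty only for 3' length variants
    shift5: int = 0  # >0: extra 5' bases on the read; <0: 5'-truncated
    trim3: int = 0  # canonical 3' bases missing from the read
    templated: bool | None = None
    passed_filter: bool = False
    threshold_used: int = 0

    @property
    def n_edits(self) -> int:
        return (
            len(self.edits) + len(self.extension) + self.trim3 + abs(self.shift5)
        )

    @property
    def shorter_than_canonical(self) -> bool:
        return self.shift5 < 0 or self.trim3 > 0


@dataclass
class PolymorphismCall:
    """A single-substitution allelic variant of a canonical mature miRNA."""

    parent: str
    position: int  # 1-based on the mature
    ref: str
    alt: str
    fraction: float | None = None  # variant / (variant + canonical) reads
    in_seed: bool = False

    def __post_init__(self) -> None:
        if self.fraction is not None and not (0 < self.fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")


def _align_at(
    read: str, canonical: str, offset: int, window: int
) -> IsomiRCall | None:
    """Categorize a read against a canonical at a fixed register.

    ``offset`` is the read index where canonical base 1 (0-based 0) sits; it
    is negative when the read starts inside the canonical.
    """
    lc, lr = len(canonical), len(read)
    shift5 = offset
    # overlap in canonical coordinates
    start = max(0, -offset)
    end = min(lc, lr - offset)
    if end <= start:
        return None
    subs = [
        (i + 1, canonical[i], read[offset + i])
        for i in range(start, end)
        if canonical[i] != read[offset + i]
    ]
    extension = read[offset + lc :] if offset + lc < lr else ""
    trim3 = lc - end
    first_base_sub = any(pos == 1 for pos, _, _ in subs)
    internal_subs = [
        s for s in subs if 1 < s[0] <= lc - window
    ]
    if shift5 != 0 or first_base_sub:
        category = ISOMIR_5P
    elif internal_subs:
        category = MISMATCH_INTERNAL
    elif extension or trim3:
        category = ISOMIR_3P_LEN
    elif subs:
        category = ISOMIR_3P_SUB
    else:
        category = CANONICAL
    call = IsomiRCall(
        read=CollapsedRead(read, 1),
        parent="",
        category=category,
        edits=subs,
        extension=extension,
        shift5=shift5,
        trim3=trim3,
    )
    return call


def classify_read(
    read: CollapsedRead | str,
    canonicals: Iterable[MatureRecord],
    window: int = 2,
) -> IsomiRCall | None:
    """Seed-anchored classification of a read against canonical miRNAs.

    The read must contain an exact copy of some canonical's seed (bases 2-8);
    the seed occurrence fixes the alignment register.  When several canonicals
    anchor, the call with the fewest edits wins, ties broken by canonical id
    order.  Returns ``None`` when no seed anchors.
    """
    if isinstance(read, str):
        read = CollapsedRead(normalize_rna(read), 1)
    seq = read.sequence
    best: IsomiRCall | None = None
    for mature in sorted(canonicals, key=lambda m: m.id):
        seed = mature.seed
        p = seq.find(seed)
        while p != -1:
            call = _align_at(seq, mature.sequence, p - SEED_START, window)
            if call is not None:
                call.parent = mature.id
                call.read = read
                if best is None or call.n_edits < best.n_edits:
                    best = call
            p = seq.find(seed, p + 1)
    return best


def check_templated(
    call: IsomiRCall,
    precursor: PrecursorRecord,
    matures: Mapping[str, MatureRecord],
) -> bool:
    """Whether every edited/extended base of a call matches the genome.

    The genomic context is the precursor sequence extended by its recorded
    flanks.  A 3' extension is compared against the bases immediately
    downstream of the mature; a 5' extension against the bases immediately
    upstream.  Substitutions are never templated, so any substitution edit
    makes the call non-templated.
    """
    mature = matures[call.parent]
    if not precursor.flank5 or not precursor.flank3:
        raise ValueError(f"precursor {precursor.id} has no flanking context")
    if call.edits:
        return False
    genome = precursor.flank5 + precursor.sequence + precursor.flank3
    m0 = genome.find(mature.sequence)
    if m0 == -1:
        raise ValueError(
            f"mature {mature.id} not found in precursor {precursor.id}"
        )
    m_end = m0 + len(mature.sequence)
    if call.extension:
        down = genome[m_end : m_end + len(call.extension)]
        if down != call.extension:
            return False
    if call.shift5 > 0:
        up_read = call.read.sequence[: call.shift5]
        up_genome = genome[m0 - call.shift5 : m0]
        if up_genome != up_read:
            return False
    return True


def canonical_counts(
    collapsed: Iterable[CollapsedRead], mirnaome: MiRNAome
) -> dict[str, int]:
    """Read count exactly matching each canonical mature sequence."""
    by_seq = {c.sequence: c.count for c in collapsed}
    return {
        m.id: by_seq.get(m.sequence, 0) for m in mirnaome.matures.values()
    }


def call_isomirs(
    collapsed: list[CollapsedRead],
    mirnaome: MiRNAome,
    esv_profile: ESVProfile,
    filter_params: FilterParams = FilterParams(),
) -> list[IsomiRCall]:
    """Classify collapsed reads and filter variants against ESV thresholds.

    Reads shorter than their canonical are dropped (indistinguishable from
    degradation), as are templated length/5' variants (indistinguishable from
    precursor fragments).  Each surviving variant is held to the count
    threshold of its ESV position class, computed against its parent
    canonical's read count; ``passed_filter`` records the outcome.
    """
    matures = mirnaome.ordered_matures()
    window = esv_profile.window
    can_counts = canonical_counts(collapsed, mirnaome)
    calls: list[IsomiRCall] = []
    for cread in collapsed:
        call = classify_read(cread, matures, window=window)
        if call is None:
            continue
        if call.category == CANONICAL:
            call.templated = True
            call.passed_filter = True
            calls.append(call)
            continue
        if call.shorter_than_canonical:
            continue
        precursor = mirnaome.precursor_of(call.parent)
        call.templated = check_templated(call, precursor, mirnaome.matures)
        if call.templated and call.category in (ISOMIR_3P_LEN, ISOMIR_5P):
            continue
        threshold = esv_threshold(
            esv_profile,
            can_counts[call.parent],
            CATEGORY_CLASS[call.category],
            filter_params,
        )
        call.threshold_used = threshold
        call.passed_filter = cread.count >= threshold
        calls.append(call)
    return calls


def polymorphism_from_pair(
    reference: str, variant: str, parent: str = ""
) -> PolymorphismCall:
    """Build a polymorphism call from a reference/variant sequence pair.

    The pair must be equal-length with exactly one substitution (Hamming
    distance 1); the substitution position determines the seed flag.
    """
    ref = normalize_rna(reference)
    var = normalize_rna(variant)
    if len(ref) != len(var):
        raise ValueError("reference and variant must have equal length")
    diffs = [i for i in range(len(ref)) if ref[i] != var[i]]
    if len(diffs) != 1:
        raise ValueError(
            f"expected exactly one substitution, found {len(diffs)}"
        )
    pos = diffs[0] + 1  # 1-based
    return PolymorphismCall(
        parent=parent,
        position=pos,
        ref=ref[diffs[0]],
        alt=var[diffs[0]],
        in_seed=SEED_START + 1 <= pos <= SEED_END,
    )


def call_polymorphisms(
    collapsed: list[CollapsedRead],
    mirnaome: MiRNAome,
    esv_profile: ESVProfile,
    filter_params: FilterParams = FilterParams(),
    min_fraction: float = 0.40,
) -> list[PolymorphismCall]:
    """Report internal single-substitution variants at high allele fraction.

    A variant qualifies as allelic when it passes the internal-class ESV
    threshold and its read fraction among variant + canonical reads is
    strictly greater than ``min_fraction``.
    """
    can_counts = canonical_counts(collapsed, mirnaome)
    calls = call_isomirs(collapsed, mirnaome, esv_profile, filter_params)
    out: list[PolymorphismCall] = []
    for call in calls:
        if call.category != MISMATCH_INTERNAL or len(call.edits) != 1:
            continue
        if not call.passed_filter:
            continue
        variant_count = call.read.count
        total = variant_count + can_counts[call.parent]
        fraction = variant_count / total
        if fraction <= min_fraction:
            continue
        pos, ref, alt = call.edits[0]
        out.append(
            PolymorphismCall(
                parent=call.parent,
                position=pos,
                ref=ref,
                alt=alt,
                fraction=fraction,
                in_seed=SEED_START + 1 <= pos <= SEED_END,
            )
        )
    out.sort(key=lambda c: (c.parent, c.position))
    return out


def summarize_classes(calls: list[IsomiRCall]) -> dict:
    """Category counts, 3'-end variant percentage and canonical:variant ratios.

    Only variants that passed the ESV filter are summarized.  The 3'-end
    percentage is (3' substitution + 3' length variants) / all passed isomiR
    variants, rounded to the nearest integer percent.  Variants more abundant
    than their parent canonical are flagged.
    """
    passed = [
        c
        for c in calls
        if c.category in VARIANT_CATEGORIES and c.passed_filter
    ]
    counts = {cat: 0 for cat in VARIANT_CATEGORIES}
    for c in passed:
        counts[c.category] += 1
    total = sum(counts.values())
    summary: dict = {"counts": counts, "n_variants": total}
    if total:
        pct = 100 * (counts[ISOMIR_3P_SUB] + counts[ISOMIR_3P_LEN]) / total
        summary["percent_3p_end"] = round(pct)
    can_by_parent = {
        c.parent: c.read.count for c in calls if c.category == CANONICAL
    }
    ratios: dict[str, float] = {}
    flagged: list[IsomiRCall] = []
    for c in passed:
        can = can_by_parent.get(c.parent, 0)
        ratios[c.parent] = can / c.read.count if c.read.count else float("nan")
        if c.read.count > can:
            flagged.append(c)
    summary["canonical_to_variant_ratio"] = ratios
    summary["more_abundant_than_canonical"] = flagged
    return summary
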