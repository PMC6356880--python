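"""Adapter trimming, size filtering and read collapsing.

Small-RNA inserts (mature miRNAs, 18-25 nt) are shorter than the sequencing
cycle count, so reads run through the 3' adapter; the trimmer removes the
leftmost adapter occurrence (full internal match, or an exact adapter-prefix
match of at least ``min_overlap`` bases at the read 3' end).  Surviving reads
are size-filtered to the expected mature-miRNA range and collapsed into unique
sequences annotated with their read counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .formats_io import normalize_rna

MIN_LEN_DEFAULT = 18
MAX_LEN_DEFAULT = 25


@dataclass
class CollapsedRead:
    """A unique read sequence with its total count and contributing samples."""

    sequence: str
    count: int
    samples: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")


def trim_adapter(read: str, adapter: str, min_overlap: int = 5) -> str | None:
    """Remove the leftmost adapter occurrence from a read.

    A cut qualifies when the adapter occurs in full, or when a prefix of the
    adapter of length >= ``min_overlap`` is a suffix of the read.  Returns the
    insert 5' of the cut, or ``None`` when nothing remains (adapter at read
    start or no insert).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    read = normalize_rna(read)
    adapter = normalize_rna(adapter)
    best_cut: int | None = None
    full = read.find(adapter)
    if full != -1:
        best_cut = full
    # exact adapter-prefix overlap at the read 3' end
    max_ov = min(len(adapter), len(read))
    for ov in range(max_ov, min_overlap - 1, -1):
        cut = len(read) - ov
        if read.endswith(adapter[:ov]):
            if best_cut is None or cut < best_cut:
                best_cut = cut
            break
    if best_cut is None:
        return read
    return read[:best_cut] or None


def size_filter(
    reads: list[str],
    min_len: int = MIN_LEN_DEFAULT,
    max_len: int = MAX_LEN_DEFAULT,
) -> list[str]:
    """Retain only reads with min_len <= length <= max_len (bounds inclusive)."""
    return [r for r in reads if min_len <= len(r) <= max_len]


def collapse(
    reads: list[str], sample_ids: list[str] | None = None
) -> list[CollapsedRead]:
    """Collapse reads into unique sequences with counts.

    Output is sorted by descending count, ties broken lexicographically by
    sequence; the sum of counts equals the number of input reads.
    """
    if sample_ids is not None and len(sample_ids) != len(reads):
        raise ValueError("sample_ids must parallel reads")
    counts: dict[str, int] = {}
    samples: dict[str, set] = {}
    for i, read in enumerate(reads):
        seq = normalize_rna(read)
        counts[seq] = counts.get(seq, 0) + 1
        if sample_ids is not None:
            samples.setdefault(seq, set()).add(sample_ids[i])
    out = [
        CollapsedRead(seq, n, frozenset(samples.get(seq, ())))
        for seq, n in counts.items()
    ]
    out.sort(key=lambda c: (-c.count, c.sequence))
    return out


def preprocess_reads(
    reads: list[str],
    adapter: str,
    min_len: int = MIN_LEN_DEFAULT,
    max_len: int = MAX_LEN_DEFAULT,
    min_overlap: int = 5,
    sample_ids: list[str] | None = None,
) -> list[CollapsedRead]:
    """Trim, size-filter and collapse a read list in one pass."""
    trimmed: list[str] = []
    kept_samples: list[str] = []
    for i, read in enumerate(reads):
        t = trim_adapter(read, adapter, min_overlap=min_overlap)
        if t is None:
            continue
        if min_len <= len(t) <= max_len:
            trimmed.append(t)
            if sample_ids is not None:
                kept_samples.append(sample_ids[i])
    return collapse(trimmed, kept_samples if sample_ids is not None else None)
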