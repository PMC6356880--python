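"""Position-class sequencing-pipeline error (ESV) estimation.

Erroneous sequence variants (ESVs) are read variants created by the
extraction/cDNA/sequencing pipeline rather than by biology.  Aligning
collapsed reads to two highly abundant control RNAs (an rRNA and a short
mRNA), which are not expected to be RNA-edited, reveals the rate and the
within-read position of these artifacts.  Errors are strongly biased towards
the read termini, so rates are estimated per position class: the first
``window`` bases (5'-terminal), the last ``window`` bases (3'-terminal), and
everything between (internal).  Each class rate is the count-weighted ratio of
reads whose mismatches fall in that class to reads aligning perfectly — the
same quantity later used to threshold candidate isomiRs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .formats_io import SequenceRecord, normalize_rna
from .preprocess import CollapsedRead

CLASS_5P = "5'-terminal"
CLASS_INTERNAL = "internal"
CLASS_3P = "3'-terminal"
VARIANT_CLASSES = (CLASS_5P, CLASS_INTERNAL, CLASS_3P)

_BASE_CODE = {c: i for i, c in enumerate("ACGUN")}


@dataclass(frozen=True)
class ESVProfile:
    """Per-position-class ratios of ESV reads to perfectly aligned reads."""

    r5: float
    r_int: float
    r3: float
    n_aligned: int = 0
    window: int = 2

    def __post_init__(self) -> None:
        if min(self.r5, self.r_int, self.r3) < 0:
            raise ValueError("ratios must be >= 0")
        if self.n_aligned < 0:
            raise ValueError("n_aligned must be >= 0")
        if self.window < 1:
            raise ValueError("window must be >= 1")

    def rate_for_class(self, variant_class: str) -> float:
        if variant_class == CLASS_5P:
            return self.r5
        if variant_class == CLASS_INTERNAL:
            return self.r_int
        if variant_class == CLASS_3P:
            return self.r3
        raise ValueError(f"unknown variant class {variant_class!r}")


@dataclass(frozen=True)
class FilterParams:
    """Realization of the count-threshold rule separating isomiRs from ESVs.

    The threshold for a variant class is ``max(min_count,
    ceil(safety_factor * class_rate * canonical_count))``: the expected number
    of artifact reads under the canonical's depth, inflated by a safety factor
    against rate-estimate noise, floored at an absolute minimum count.
    """

    safety_factor: float = 2.0
    min_count: int = 10

    def __post_init__(self) -> None:
        if self.safety_factor <= 0:
            raise ValueError("safety_factor must be > 0")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


class EstimationError(RuntimeError):
    """Raised when no reads align to the control references."""


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


@lru_cache(maxsize=64)
def _reference_windows(reference: str, length: int) -> np.ndarray:
    """All ``length``-wide windows of a reference as a (n_offsets, length) array."""
    arr = _encode(reference)
    return np.lib.stride_tricks.sliding_window_view(arr, length)


def align_ungapped(
    read: str, reference: str, max_mismatches: int = 3
) -> tuple[int, tuple[int, ...]] | None:
    """Best ungapped alignment of a read within a longer reference.

    Scans every offset, returning ``(offset, mismatch positions)`` for the
    offset with the fewest mismatches (ties broken by the smallest offset), or
    ``None`` when the minimum exceeds ``max_mismatches``.
    """
    read = normalize_rna(read)
    reference = normalize_rna(reference)
    if len(read) > len(reference):
        raise ValueError("read longer than reference")
    windows = _reference_windows(reference, len(read))
    query = _encode(read)
    mismatches = (windows != query).sum(axis=1)
    offset = int(np.argmin(mismatches))
    n_mm = int(mismatches[offset])
    if n_mm > max_mismatches:
        return None
    positions = tuple(int(i) for i in np.nonzero(windows[offset] != query)[0])
    return offset, positions


def mismatch_classes(
    positions: tuple[int, ...], read_length: int, window: int = 2
) -> set[str]:
    """Position classes touched by a set of mismatch positions."""
    classes: set[str] = set()
    for pos in positions:
        if pos < window:
            classes.add(CLASS_5P)
        elif pos >= read_length - window:
            classes.add(CLASS_3P)
        else:
            classes.add(CLASS_INTERNAL)
    return classes


def estimate_esv_profile(
    collapsed: list[CollapsedRead],
    controls: list[SequenceRecord],
    window: int = 2,
    max_mismatches: int = 3,
) -> ESVProfile:
    """Estimate position-class ESV ratios from control-RNA alignments.

    Every collapsed read is aligned (ungapped) against each control reference
    in input order; the hit with the fewest mismatches wins, earlier
    references winning ties.  Perfect alignments feed the denominator; a read
    with mismatches adds its count to the numerator of every class its
    mismatches touch.  Reads exceeding ``max_mismatches`` everywhere are
    ignored: they are not control-derived (or carry indels, which ungapped
    alignment does not model).
    """
    if not controls:
        raise ValueError("at least one control reference required")
    perfect = 0
    class_counts = {CLASS_5P: 0, CLASS_INTERNAL: 0, CLASS_3P: 0}
    n_aligned = 0
    for cread in collapsed:
        best: tuple[int, tuple[int, ...]] | None = None
        for ref in controls:
            if len(cread.sequence) > len(ref.sequence):
                continue
            hit = align_ungapped(cread.sequence, ref.sequence, max_mismatches)
            if hit is not None and (best is None or len(hit[1]) < len(best[1])):
                best = hit
        if best is None:
            continue
        n_aligned += cread.count
        _, positions = best
        if not positions:
            perfect += cread.count
        else:
            for cls in mismatch_classes(positions, len(cread.sequence), window):
                class_counts[cls] += cread.count
    if n_aligned == 0:
        raise EstimationError("no reads aligned to the control references")
    if perfect == 0:
        raise EstimationError("no perfectly aligned reads; ratios undefined")
    return ESVProfile(
        r5=class_counts[CLASS_5P] / perfect,
        r_int=class_counts[CLASS_INTERNAL] / perfect,
        r3=class_counts[CLASS_3P] / perfect,
        n_aligned=n_aligned,
        window=window,
    )


def phred_error_prob(q: float) -> float:
    """Per-base error probability implied by a Phred quality score."""
    if q < 0:
        raise ValueError("Phred score must be >= 0")
    return 10 ** (-q / 10)


def esv_threshold(
    profile: ESVProfile,
    canonical_count: int,
    variant_class: str,
    params: FilterParams = FilterParams(),
) -> int:
    """Minimum count for a variant of the given class to be called an isomiR.

    ``max(min_count, ceil(safety_factor * r_class * canonical_count))`` —
    variants below this are indistinguishable from pipeline artifacts at the
    parent canonical's sequencing depth.
    """
    if canonical_count < 0:
        raise ValueError("canonical_count must be >= 0")
    rate = profile.rate_for_class(variant_class)
    expected = params.safety_factor * rate * canonical_count
    return max(params.min_count, math.ceil(expected))
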