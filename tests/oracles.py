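"""Independent brute-force oracles, kept free of the implementation paths."""

from __future__ import annotations

from functools import lru_cache

WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
PAIRABLE = WC | {("G", "U"), ("U", "G")}
COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C", "N": "N"}


def brute_align(read: str, reference: str, max_mismatches: int):
    """All-offset scan for the fewest-mismatch ungapped placement."""
    best = None
    for offset in range(len(reference) - len(read) + 1):
        mm = tuple(
            i for i in range(len(read)) if read[i] != reference[offset + i]
        )
        if best is None or len(mm) < len(best[1]):
            best = (offset, mm)
    if best is None or len(best[1]) > max_mismatches:
        return None
    return best


def brute_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Maximum nested pairing cardinality by recursive case enumeration.

    Either position i is unpaired, or it pairs with some admissible k and the
    problem splits into the inside and outside fragments.
    """

    @lru_cache(maxsize=None)
    def solve(i: int, j: int) -> int:
        if j - i < min_loop + 1:
            return 0
        best = solve(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in PAIRABLE:
                best = max(best, 1 + solve(i + 1, k - 1) + solve(k + 1, j))
        return best

    return solve(0, len(seq) - 1)


def brute_seed_sites(mature: str, utr: str) -> list[int]:
    """Check every UTR 7-mer against seed bases 2-8 by direct base pairing."""
    seed = mature[1:8]
    sites = []
    for p in range(len(utr) - 6):
        window = utr[p : p + 7]
        # window 5'->3' pairs seed 3'->5' with Watson-Crick pairs only
        if all((window[k], seed[6 - k]) in WC for k in range(7)):
            sites.append(p)
    return sites


def brute_trim_cut(read: str, adapter: str, min_overlap: int) -> int | None:
    """Leftmost qualifying adapter cut by scanning every cut point."""
    candidates = []
    for cut in range(len(read) + 1):
        tail = read[cut:]
        if len(tail) >= len(adapter) and tail.startswith(adapter):
            candidates.append(cut)
        elif (
            len(tail) < len(adapter)
            and len(tail) >= min_overlap
            and tail == adapter[: len(tail)]
        ):
            candidates.append(cut)
    return min(candidates) if candidates else None
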