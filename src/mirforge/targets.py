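"""Seed-complementary target-site prediction and target-set comparison.

A target site is an exact Watson-Crick reverse complement of the miRNA seed
(mature bases 2-8; no G:U tolerated in the seed) on a transcript 3'UTR.
Optionally each site is scored with a simplified nearest-neighbor duplex
model: the seed duplex is extended base by base in both directions while
Watson-Crick or G:U pairing holds (internal loops and bulges terminate the
extension), and stacking free energies are summed over the paired run from a
bundled stacking table.  Sites at or below an energy threshold (default
-18 kcal/mol) count as high-stability target sites.  Set comparisons between
canonical and variant miRNAs are at transcript level: a transcript counts
once however many sites it carries.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Mapping

from .formats_io import SequenceRecord, normalize_rna, revcomp
from .isomir import SEED_END, SEED_START

PAIRABLE = {
    ("A", "U"), ("U", "A"),
    ("C", "G"), ("G", "C"),
    ("G", "U"), ("U", "G"),
}

ENERGY_THRESHOLD_DEFAULT = -18.0


@dataclass(frozen=True)
class TargetSite:
    """A seed-complementary site on a transcript 3'UTR."""

    mature_id: str
    transcript_id: str
    start: int  # 0-based on the UTR
    energy: float | None = None  # kcal/mol, more negative = more stable


@dataclass(frozen=True)
class TargetSetComparison:
    """Transcript-level overlap of canonical vs variant target repertoires."""

    canonical_only: int
    shared: int
    variant_only: int

    @property
    def percent_added(self) -> float:
        """Variant-only transcripts as a percentage of the canonical total."""
        canonical_total = self.canonical_only + self.shared
        if canonical_total == 0:
            return 0.0
        return 100.0 * self.variant_only / canonical_total


@lru_cache(maxsize=1)
def load_stack_table() -> dict[tuple[str, str], float]:
    """Bundled nearest-neighbor stacking free energies (kcal/mol at 37 C)."""
    path = resources.files("mirforge.data").joinpath("rna_stacks.tsv")
    table: dict[tuple[str, str], float] = {}
    with resources.as_file(path) as p, open(p) as fh:
        header_seen = False
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                header_seen = True
                continue
            top, bottom, dg = line.split("\t")
            table[(top, bottom)] = float(dg)
    return table


def seed_motif(mature: str) -> str:
    """The UTR site motif: Watson-Crick reverse complement of seed bases 2-8."""
    mature = normalize_rna(mature)
    if len(mature) < SEED_END:
        raise ValueError("mature must be at least 8 nt")
    return revcomp(mature[SEED_START:SEED_END])


def seed_sites(mature: str, utr: str) -> list[int]:
    """All UTR start positions carrying the seed-complement motif.

    Overlapping occurrences are all reported; matching is exact, so G:U
    wobbles in the seed are excluded by construction.
    """
    motif = seed_motif(mature)
    utr = normalize_rna(utr)
    sites = []
    p = utr.find(motif)
    while p != -1:
        sites.append(p)
        p = utr.find(motif, p + 1)
    return sites


def duplex_energy(mature: str, utr: str, site_start: int) -> float:
    """Stacking free energy of the duplex anchored at a seed site.

    Mature base m (0-based) pairs UTR position ``site_start + 7 - m``; the
    seed (m = 1..7) is paired by construction, and the duplex is extended in
    both directions while Watson-Crick or G:U pairing holds and the UTR has
    sequence.  The returned value is the sum of nearest-neighbor stacking
    energies over the contiguous paired run.
    """
    mature = normalize_rna(mature)
    utr = normalize_rna(utr)

    def utr_pos(m: int) -> int:
        return site_start + (SEED_END - 1) - m

    def pairs(m: int) -> bool:
        u = utr_pos(m)
        return (
            0 <= m < len(mature)
            and 0 <= u < len(utr)
            and (mature[m], utr[u]) in PAIRABLE
        )

    lo = SEED_START
    while pairs(lo - 1):
        lo -= 1
    hi = SEED_END - 1
    while pairs(hi + 1):
        hi += 1

    table = load_stack_table()
    energy = 0.0
    for m in range(lo, hi):
        top = mature[m] + mature[m + 1]
        bottom = utr[utr_pos(m)] + utr[utr_pos(m + 1)]
        energy += table[(top, bottom)]
    return energy


def predict_targets(
    matures: Mapping[str, str] | list[SequenceRecord],
    utrs: list[SequenceRecord],
    energy_threshold: float = ENERGY_THRESHOLD_DEFAULT,
    use_energy: bool = True,
) -> dict[str, set[str]]:
    """Map each mature miRNA to the transcripts it can target.

    A transcript qualifies when its 3'UTR carries at least one seed site
    and, when ``use_energy`` is set, at least one of those sites reaches the
    duplex-stability threshold.
    """
    if isinstance(matures, list):
        matures = {r.id: r.sequence for r in matures}
    out: dict[str, set[str]] = {mid: set() for mid in matures}
    for mid, mseq in matures.items():
        for utr in utrs:
            for start in seed_sites(mseq, utr.sequence):
                if not use_energy:
                    out[mid].add(utr.id)
                    break
                if duplex_energy(mseq, utr.sequence, start) <= energy_threshold:
                    out[mid].add(utr.id)
                    break
    return out


def target_sites(
    matures: Mapping[str, str], utrs: list[SequenceRecord]
) -> list[TargetSite]:
    """All seed sites with their duplex energies (unfiltered)."""
    sites = []
    for mid, mseq in matures.items():
        for utr in utrs:
            for start in seed_sites(mseq, utr.sequence):
                sites.append(
                    TargetSite(
                        mature_id=mid,
                        transcript_id=utr.id,
                        start=start,
                        energy=duplex_energy(mseq, utr.sequence, start),
                    )
                )
    return sites


def compare_target_sets(
    canonical: Mapping[str, set[str]],
    variant: Mapping[str, set[str]],
    universe: set[str] | None = None,
) -> TargetSetComparison:
    """Transcript-level Venn comparison of two target mappings.

    Both mappings must come from the same UTR universe; when ``universe`` is
    supplied, any target outside it raises.
    """
    canonical_set: set[str] = set().union(*canonical.values()) if canonical else set()
    variant_set: set[str] = set().union(*variant.values()) if variant else set()
    if universe is not None:
        stray = (canonical_set | variant_set) - universe
        if stray:
            raise ValueError(f"targets outside the shared UTR universe: {sorted(stray)[:5]}")
    shared = canonical_set & variant_set
    return TargetSetComparison(
        canonical_only=len(canonical_set - variant_set),
        shared=len(shared),
        variant_only=len(variant_set - canonical_set),
    )
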