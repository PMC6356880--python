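"""Synthetic small-RNA-seq inputs with ground-truth provenance.

Emulates the read structure the analysis assumes: canonical mature miRNAs
(18-25 nt) excised from designed hairpin precursors, planned non-templated
isomiRs and allelic variants, degradation and precursor fragments,
control-RNA-derived reads, 3'-adapter read-through on a fixed-cycle
single-end platform, and pipeline substitution errors with terminally biased
position-class rates.  Every read's provenance is recorded in a truth
manifest so downstream recovery can be scored.

Error injection is ratio-parameterized: each read receives at most one
substitution, with the error class drawn with probability proportional to the
configured class ratio, so that the ratio of class-c error reads to perfect
reads equals the configured value in expectation — the exact quantity the
ESV estimator measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .expression import QPCRTable
from .formats_io import GenomicLocus, SequenceRecord, normalize_rna
from .isomir import (
    ISOMIR_3P_LEN,
    ISOMIR_3P_SUB,
    ISOMIR_5P,
    MatureRecord,
    MiRNAome,
    PrecursorRecord,
)

BASES = "ACGU"

LABEL_CANONICAL = "canonical"
LABEL_POLYMORPHISM = "polymorphism"
LABEL_ESV = "esv"
LABEL_DEGRADATION = "degradation"
LABEL_PRECURSOR_FRAGMENT = "precursor_fragment"
LABEL_CONTROL = "control"
ISOMIR_LABELS = (ISOMIR_5P, ISOMIR_3P_SUB, ISOMIR_3P_LEN)

CONTROL_LENGTHS = (1750, 540)  # rRNA-like and short-mRNA-like references

# TruSeq small-RNA 3' adapter (RNA alphabet internally)
DEFAULT_ADAPTER = "UGGAAUUCUCGGGUGCCAAGG"


@dataclass(frozen=True)
class PlannedVariant:
    """A planned isomiR: a non-templated edit of a gene's 5p mature."""

    gene: int
    kind: str  # {"3p_addition", "3p_substitution", "5p_extension"}
    rel_abundance: float  # relative to the parent canonical

    def __post_init__(self) -> None:
        if self.kind not in ("3p_addition", "3p_substitution", "5p_extension"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.rel_abundance <= 0:
            raise ValueError("rel_abundance must be > 0")


@dataclass(frozen=True)
class PlannedPolymorphism:
    """A planned allelic variant at an internal, non-seed mature position."""

    gene: int
    position: int = 12  # 1-based on the 5p mature; outside seed and termini
    allele_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.allele_fraction < 1):
            raise ValueError("allele_fraction must be in (0, 1)")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic library.

    Defaults reflect the structure of the emulated experiment: terminally
    biased class error ratios (5' 0.02, internal 0.0004, 3' 0.21, terminal
    window 2), planned isomiR abundances well clear of their ESV thresholds,
    allelic variants at 50% read fraction, a 36-cycle single-end read with 3'
    adapter read-through, and 20% control-RNA-derived reads.
    """

    seed: int = 0
    n_genes: int = 20
    n_samples_per_group: int = 3
    esv_rates: tuple[float, float, float] = (0.02, 0.0004, 0.21)  # r5, r_int, r3
    window: int = 2
    isomir_spec: list[PlannedVariant] | None = None
    polymorphism_spec: list[PlannedPolymorphism] | None = None
    tissue_profiles: dict[str, dict[str, float]] | None = None
    fragment_rates: tuple[float, float] = (0.05, 0.05)  # degradation, precursor
    control_fraction: float = 0.20
    adapter: str = DEFAULT_ADAPTER
    library_size: int = 100_000
    read_length: int = 36
    quality_char: str = "I"
    qpcr_noise_sd: float = 0.15
    qpcr_baseline: float = 30.0
    cluster_pairs: int = 2  # leading gene pairs placed <10 kb apart

    def __post_init__(self) -> None:
        if self.library_size <= 0:
            raise ValueError("library_size must be > 0")
        if not all(0 <= r <= 1 for r in self.esv_rates):
            raise ValueError("esv_rates must be probabilities in [0, 1]")
        if not all(0 <= r <= 1 for r in self.fragment_rates):
            raise ValueError("fragment_rates must be in [0, 1]")
        if not 0 <= self.control_fraction <= 1:
            raise ValueError("control_fraction must be in [0, 1]")
        self.adapter = normalize_rna(self.adapter)
        if self.isomir_spec is None:
            self.isomir_spec = default_isomir_spec(self.n_genes)
        if self.polymorphism_spec is None:
            self.polymorphism_spec = default_polymorphism_spec(self.n_genes)
        if self.tissue_profiles is None:
            self.tissue_profiles = default_tissue_profiles()


def default_isomir_spec(n_genes: int) -> list[PlannedVariant]:
    """Planned variants: 3' U-additions, 3' substitutions, one 5' extension.

    3'-class variants sit at 2.5x their canonical so they exceed the
    3'-terminal ESV threshold (2 * 0.21 * canonical) about six-fold; the
    5' variant at 0.5x exceeds its far lower 5'-class threshold similarly.
    """
    spec: list[PlannedVariant] = []
    for g in range(min(5, n_genes)):
        spec.append(PlannedVariant(g, "3p_addition", 2.5))
    for g in range(5, min(8, n_genes)):
        spec.append(PlannedVariant(g, "3p_substitution", 2.5))
    if n_genes > 8:
        spec.append(PlannedVariant(8, "5p_extension", 0.5))
    return spec


def default_polymorphism_spec(n_genes: int) -> list[PlannedPolymorphism]:
    return [
        PlannedPolymorphism(g) for g in range(10, min(12, n_genes))
    ]


def default_tissue_profiles() -> dict[str, dict[str, float]]:
    """Three tissues, one ubiquitous miRNA, one 2048-fold liver-enriched."""
    return {
        "brain": {"mir-ubiq": 100.0, "mir-liver": 1.0, "mir-brain": 512.0},
        "liver": {"mir-ubiq": 110.0, "mir-liver": 2048.0, "mir-brain": 1.0},
        "muscle": {"mir-ubiq": 95.0, "mir-liver": 1.0, "mir-brain": 1.0},
    }


@dataclass
class SyntheticMirnaome:
    """A generated miRNAome with loci, contig sequences and cluster truth."""

    mirnaome: MiRNAome
    loci: list[tuple[str, GenomicLocus, dict]]
    genome: dict[str, str]
    expected_clusters: list[tuple[str, ...]]


@dataclass
class TruthManifest:
    """Per-sequence provenance of a simulated library.

    ``records`` has one row per (insert sequence, label, parent); counts sum
    to the library size.
    """

    records: pd.DataFrame
    library_size: int

    def label_counts(self) -> dict[str, int]:
        return self.records.groupby("label")["count"].sum().to_dict()

    def sequences_with_label(self, *labels: str) -> set[str]:
        mask = self.records["label"].isin(labels)
        return set(self.records.loc[mask, "sequence"])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGU", "UGCA"))[::-1]


def generate_mirnaome(config: SimulationConfig) -> SyntheticMirnaome:
    """Design hairpin precursors with exact-substring mature arms.

    Each precursor is 5p-arm + loop + 3p-arm, the 3p arm the reverse
    complement of the 5p arm so the duplex folds; arm lengths 21-24 nt, loop
    13-22 nt (total 55-70 nt).  The loop's first base is fixed to C so a 3'
    U-addition on the 5p arm is non-templated by construction.  Precursors
    are embedded in synthetic plus-strand contigs with 30-nt flanks recorded;
    the leading ``cluster_pairs`` gene pairs share a contig less than 10 kb
    apart to form known clusters.
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng([config.seed, 0])
    precursors: list[PrecursorRecord] = []
    matures: list[MatureRecord] = []
    loci: list[tuple[str, GenomicLocus, dict]] = []
    genome: dict[str, str] = {}
    expected_clusters: list[tuple[str, ...]] = []

    seen_seeds: set[str] = set()
    hairpins: list[tuple[str, str, str, str]] = []  # (gene_id, arm5, loop, arm3)
    for g in range(config.n_genes):
        while True:
            arm_len = int(rng.integers(21, 25))
            arm5 = _random_seq(rng, arm_len)
            arm3 = _revcomp(arm5)
            seeds = (arm5[1:8], arm3[1:8])
            if seeds[0] != seeds[1] and not (set(seeds) & seen_seeds):
                seen_seeds.update(seeds)
                break
        loop_len = int(rng.integers(13, 23))
        loop = "C" + _random_seq(rng, loop_len - 1)
        hairpins.append((f"syn-mir-{g + 1}", arm5, loop, arm3))

    # contig placement: leading pairs clustered, remainder one gene per contig
    placements: list[list[int]] = []
    g = 0
    for _ in range(config.cluster_pairs):
        if g + 1 < config.n_genes:
            placements.append([g, g + 1])
            g += 2
    while g < config.n_genes:
        placements.append([g])
        g += 1

    for ci, gene_indices in enumerate(placements):
        contig = f"contig{ci + 1}"
        parts: list[str] = []
        cursor = 0
        gap = 8000  # same-strand gap below the 10-kb clustering rule
        ids_here: list[str] = []
        for k, gi in enumerate(gene_indices):
            gene_id, arm5, loop, arm3 = hairpins[gi]
            pre_seq = arm5 + loop + arm3
            lead = 60 if k == 0 else gap
            parts.append(_random_seq(rng, lead))
            cursor += lead
            start = cursor
            parts.append(pre_seq)
            cursor += len(pre_seq)
            contig_locus = GenomicLocus(contig, start, cursor, "+")
            ids_here.append(gene_id)
            loci.append((gene_id, contig_locus, {"Name": gene_id}))
            precursors.append(
                PrecursorRecord(
                    id=gene_id,
                    sequence=pre_seq,
                    locus=contig_locus,
                    flank5="",  # filled after contig assembly
                    flank3="",
                    mature5p=f"{gene_id}-5p",
                    mature3p=f"{gene_id}-3p",
                )
            )
            matures.append(
                MatureRecord(f"{gene_id}-5p", arm5, "5p", gene_id)
            )
            matures.append(
                MatureRecord(f"{gene_id}-3p", arm3, "3p", gene_id)
            )
        parts.append(_random_seq(rng, 60))
        genome[contig] = "".join(parts)
        if len(ids_here) > 1:
            expected_clusters.append(tuple(ids_here))

    # record 30-nt flanks from the assembled contigs
    for i, pre in enumerate(precursors):
        contig_seq = genome[pre.locus.contig]
        s, e = pre.locus.start, pre.locus.end
        precursors[i] = PrecursorRecord(
            id=pre.id,
            sequence=pre.sequence,
            locus=pre.locus,
            flank5=contig_seq[s - 30 : s],
            flank3=contig_seq[e : e + 30],
            mature5p=pre.mature5p,
            mature3p=pre.mature3p,
        )

    return SyntheticMirnaome(
        mirnaome=MiRNAome(precursors, matures),
        loci=loci,
        genome=genome,
        expected_clusters=expected_clusters,
    )


def generate_control_references(seed: int) -> list[SequenceRecord]:
    """Two abundant-control-RNA stand-ins (1750 nt and 540 nt).

    Random composition, resampled until the GC fraction lies in [0.35, 0.65].
    """
    rng = np.random.default_rng([seed, 1])
    records = []
    for name, length in zip(("control-rRNA-18S", "control-mRNA-L37"), CONTROL_LENGTHS):
        while True:
            seq = _random_seq(rng, length)
            gc = (seq.count("G") + seq.count("C")) / length
            if 0.35 <= gc <= 0.65:
                break
        records.append(SequenceRecord(id=name, sequence=seq))
    return records


def _variant_sequence(
    kind: str, mature_seq: str, downstream: str, upstream: str
) -> tuple[str, str]:
    """Build a planned variant sequence and its edit description.

    The edited base is chosen to differ from the templated genomic base so
    the variant is non-templated by construction.
    """
    if kind == "3p_addition":
        base = "U" if downstream[:1] != "U" else "A"
        return mature_seq + base, f"+{base}@3p"
    if kind == "3p_substitution":
        pos = len(mature_seq) - 1  # last base, inside the terminal window
        ref = mature_seq[pos]
        alt = BASES[(BASES.index(ref) + 1) % 4]
        return mature_seq[:pos] + alt + mature_seq[pos + 1 :], f"{ref}>{alt}@{pos + 1}"
    if kind == "5p_extension":
        base = "G" if upstream[-1:] != "G" else "C"
        return base + mature_seq, f"+{base}@5p"
    raise ValueError(f"unknown variant kind {kind!r}")


def _polymorphic_sequence(mature_seq: str, position: int) -> tuple[str, str]:
    idx = position - 1
    ref = mature_seq[idx]
    alt = BASES[(BASES.index(ref) + 2) % 4]
    return mature_seq[:idx] + alt + mature_seq[idx + 1 :], f"{ref}>{alt}@{position}"


def _apply_error(
    rng: np.random.Generator, seq: str, error_class: int, window: int
) -> str:
    """Substitute one base within the 5' window (0), interior (1) or 3' window (2)."""
    n = len(seq)
    if error_class == 0:
        pos = int(rng.integers(0, window))
    elif error_class == 2:
        pos = int(rng.integers(n - window, n))
    else:
        pos = int(rng.integers(window, n - window))
    alt = BASES[(BASES.index(seq[pos]) + 1 + int(rng.integers(0, 3))) % 4]
    return seq[:pos] + alt + seq[pos + 1 :]


def simulate_library(
    config: SimulationConfig,
    synthetic: SyntheticMirnaome,
    controls: list[SequenceRecord],
    fastq_path: str | None = None,
) -> tuple[list[tuple[str, str, str]], TruthManifest]:
    """Simulate a single-end small-RNA library with a truth manifest.

    Inserts are drawn from canonical matures, planned variants, fragment
    classes and uniform control-RNA windows (18-25 nt); each insert then
    receives at most one substitution, the error class drawn with probability
    proportional to the configured class ratio.  The 3' adapter is appended
    and the read truncated to the cycle count.  Returns ``(reads, manifest)``
    where reads are (id, sequence, quality) triples (written as DNA-alphabet
    FASTQ when ``fastq_path`` is given).
    """
    rng = np.random.default_rng([config.seed, 2])
    mirnaome = synthetic.mirnaome
    r5, r_int, r3 = config.esv_rates
    z = 1.0 + r5 + r_int + r3
    error_probs = np.array([1.0 / z, r5 / z, r_int / z, r3 / z])

    # --- template pool -----------------------------------------------------
    templates: list[tuple[str, str, str, str, float]] = []  # seq,label,parent,edit,w
    gene_ids = [p for p in mirnaome.precursors]
    arm_weight = {}
    for gid in gene_ids:
        for arm in ("5p", "3p"):
            arm_weight[f"{gid}-{arm}"] = float(rng.lognormal(0.0, 0.3))

    poly_frac = {
        gene_ids[p.gene]: p for p in config.polymorphism_spec if p.gene < len(gene_ids)
    }
    for gid in gene_ids:
        pre = mirnaome.precursors[gid]
        for arm in ("5p", "3p"):
            mid = f"{gid}-{arm}"
            mature = mirnaome.matures[mid]
            w = arm_weight[mid]
            if arm == "5p" and gid in poly_frac:
                p = poly_frac[gid]
                var_seq, edit = _polymorphic_sequence(mature.sequence, p.position)
                templates.append(
                    (var_seq, LABEL_POLYMORPHISM, mid, edit, w * p.allele_fraction)
                )
                w = w * (1 - p.allele_fraction)
            templates.append((mature.sequence, LABEL_CANONICAL, mid, "", w))

    kind_to_label = {
        "3p_addition": ISOMIR_3P_LEN,
        "3p_substitution": ISOMIR_3P_SUB,
        "5p_extension": ISOMIR_5P,
    }
    for pv in config.isomir_spec:
        if pv.gene >= len(gene_ids):
            continue
        gid = gene_ids[pv.gene]
        mid = f"{gid}-5p"
        pre = mirnaome.precursors[gid]
        mature = mirnaome.matures[mid]
        m0 = pre.sequence.find(mature.sequence)
        downstream = pre.sequence[m0 + len(mature.sequence) :] + pre.flank3
        upstream = pre.flank5 + pre.sequence[:m0]
        var_seq, edit = _variant_sequence(
            pv.kind, mature.sequence, downstream, upstream
        )
        templates.append(
            (var_seq, kind_to_label[pv.kind], mid, edit, pv.rel_abundance * arm_weight[mid])
        )

    mirna_weight = sum(t[4] for t in templates)
    deg_rate, prefrag_rate = config.fragment_rates
    mirna_fraction = 1.0 - config.control_fraction - deg_rate - prefrag_rate
    if mirna_fraction < 0:
        raise ValueError("control and fragment fractions exceed the library")
    scaled = [
        (s, lab, par, ed, w * mirna_fraction / mirna_weight)
        for s, lab, par, ed, w in templates
    ]

    # fragment templates: 5'-intact degradation and templated precursor runs
    n = len(gene_ids)
    for gid in gene_ids:
        pre = mirnaome.precursors[gid]
        mid = f"{gid}-5p"
        mature = mirnaome.matures[mid]
        deg = mature.sequence[:-3]
        if len(deg) >= 18:
            scaled.append((deg, LABEL_DEGRADATION, mid, "-3@3p", deg_rate / n))
        m0 = pre.sequence.find(mature.sequence)
        m_end = m0 + len(mature.sequence)
        frag = mature.sequence + pre.sequence[m_end : m_end + 2]
        scaled.append((frag, LABEL_PRECURSOR_FRAGMENT, mid, "+2templated", prefrag_rate / n))

    probs = np.array([t[4] for t in scaled] + [config.control_fraction])
    probs = probs / probs.sum()
    counts = rng.multinomial(config.library_size, probs)
    n_control = int(counts[-1])

    # --- expand templates with per-read error injection --------------------
    manifest_rows: dict[tuple[str, str, str, str], int] = {}
    inserts: list[tuple[str, int]] = []  # (sequence, count) in emission order

    def emit(seq: str, label: str, parent: str, edit: str, count: int) -> None:
        if count <= 0:
            return
        key = (seq, label, parent, edit)
        manifest_rows[key] = manifest_rows.get(key, 0) + count
        inserts.append((seq, count))

    for (seq, label, parent, edit, _), n_t in zip(scaled, counts[:-1]):
        if n_t == 0:
            continue
        k = rng.multinomial(int(n_t), error_probs)
        emit(seq, label, parent, edit, int(k[0]))
        for cls in (0, 1, 2):
            for _ in range(int(k[cls + 1])):
                err_seq = _apply_error(rng, seq, cls, config.window)
                emit(err_seq, LABEL_ESV, parent, f"esv_class{cls}", 1)

    # control-derived reads: uniform windows of the two references
    if n_control:
        ref_weights = np.array([len(c.sequence) for c in controls], dtype=float)
        ref_weights /= ref_weights.sum()
        ref_idx = rng.choice(len(controls), size=n_control, p=ref_weights)
        lengths = rng.integers(18, 26, size=n_control)
        cats = rng.choice(4, size=n_control, p=error_probs)
        for ri, ln, cat in zip(ref_idx, lengths, cats):
            ref = controls[int(ri)].sequence
            start = int(rng.integers(0, len(ref) - int(ln) + 1))
            seq = ref[start : start + int(ln)]
            if cat == 0:
                emit(seq, LABEL_CONTROL, controls[int(ri)].id, "", 1)
            else:
                err_seq = _apply_error(rng, seq, int(cat) - 1, config.window)
                emit(err_seq, LABEL_ESV, controls[int(ri)].id, f"esv_class{int(cat) - 1}", 1)

    # --- assemble reads -----------------------------------------------------
    reads: list[tuple[str, str, str]] = []
    qual = config.quality_char * config.read_length
    rid = 0
    for seq, count in inserts:
        full = (seq + config.adapter)[: config.read_length]
        if len(full) < config.read_length:
            full = full + "A" * (config.read_length - len(full))
        for _ in range(count):
            rid += 1
            reads.append((f"r{rid:07d}", full, qual))

    records = pd.DataFrame(
        [
            {"sequence": k[0], "label": k[1], "parent": k[2], "edit": k[3], "count": v}
            for k, v in manifest_rows.items()
        ]
    )
    manifest = TruthManifest(records=records, library_size=config.library_size)

    if fastq_path is not None:
        from .formats_io import write_fastq

        dna_reads = [(i, s.replace("U", "T"), q) for i, s, q in reads]
        write_fastq(dna_reads, fastq_path)
    return reads, manifest


def simulate_qpcr(config: SimulationConfig) -> QPCRTable:
    """Simulate a Cq table from the configured tissue abundance profiles.

    Cq = baseline - log2(abundance) + Gaussian noise; the two reference
    miRNAs are constant across tissues up to the same noise, so the
    delta-delta-Ct of a planted fold enrichment is exactly its -log2 when the
    noise is zero.
    """
    if not config.tissue_profiles:
        raise ValueError("tissue_profiles required for qPCR simulation")
    rng = np.random.default_rng([config.seed, 3])
    references = ("miR-25-3p-like", "miR-107-3p-like")
    mirnas = sorted(
        {m for prof in config.tissue_profiles.values() for m in prof}
    )
    columns: list[str] = []
    tissue_of: dict[str, str] = {}
    data: dict[str, list[float]] = {}
    for tissue in config.tissue_profiles:
        for rep in range(1, config.n_samples_per_group + 1):
            sample = f"{tissue}_{rep}"
            columns.append(sample)
            tissue_of[sample] = tissue
            col: list[float] = []
            for mirna in mirnas:
                abundance = config.tissue_profiles[tissue].get(mirna, np.nan)
                if not abundance or math.isnan(abundance):
                    raise ValueError(
                        f"abundance for {mirna} missing in tissue {tissue}"
                    )
                cq = config.qpcr_baseline - math.log2(abundance)
                col.append(cq + rng.normal(0.0, config.qpcr_noise_sd))
            for _ in references:
                cq = config.qpcr_baseline - math.log2(100.0)
                col.append(cq + rng.normal(0.0, config.qpcr_noise_sd))
            data[sample] = col
    index = mirnas + list(references)
    cq = pd.DataFrame(data, index=index, columns=columns)
    return QPCRTable(cq=cq, reference_ids=references, tissue_of=tissue_of)
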