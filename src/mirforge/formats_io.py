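"""Readers and writers for the sequence and annotation formats the pipeline touches.

All sequences are held internally in an RNA alphabet (``U``, uppercase); DNA
input is accepted and normalized on parse.  Genomic intervals are 0-based,
half-open internally and converted to 1-based inclusive GFF3 coordinates only
on output.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO

logger = logging.getLogger("mirforge")

RNA_ALPHABET = set("ACGUN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_rna(sequence: str) -> str:
    """Uppercase and convert T to U (internal canonical alphabet is RNA)."""
    return sequence.upper().replace("T", "U")


def revcomp(sequence: str) -> str:
    """Reverse complement of an RNA string (N maps to N)."""
    table = str.maketrans("ACGUN", "UGCAN")
    return normalize_rna(sequence).translate(table)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence (RNA-normalized)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicLocus:
    """A stranded genomic interval, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("start must be non-negative")
        if self.end <= self.start:
            raise ValueError("end must be > start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def parse_fasta(path: str | Path) -> list[SequenceRecord]:
    """Parse a FASTA file into RNA-normalized records.

    Raises :class:`FormatError` for empty sequences or invalid characters,
    naming the offending record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_rna(str(rec.seq))
        if not seq:
            raise FormatError(f"record {rec.id!r}: empty sequence in {path}")
        records.append(
            SequenceRecord(id=rec.id, sequence=seq, description=rec.description)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                header = rec.description
            fh.write(f">{header}\n{rec.sequence}\n")


def parse_fastq(path: str | Path) -> list[tuple[SequenceRecord, str]]:
    """Parse Phred+33 FASTQ into (record, quality-string) pairs.

    Truncated records or read/quality length mismatches raise
    :class:`FormatError`.
    """
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            quals = rec.letter_annotations["phred_quality"]
            qstring = "".join(chr(q + 33) for q in quals)
            seq = normalize_rna(str(rec.seq))
            if len(seq) != len(qstring):  # pragma: no cover - SeqIO enforces
                raise FormatError(f"record {rec.id!r}: read/quality length mismatch")
            out.append((SequenceRecord(id=rec.id, sequence=seq), qstring))
    except ValueError as exc:
        raise FormatError(f"malformed FASTQ in {path}: {exc}") from exc
    return out


def write_fastq(
    reads: Iterable[tuple[str, str, str]], path: str | Path
) -> None:
    """Write (id, sequence, quality) triples as 4-line FASTQ records."""
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            if len(seq) != len(qual):
                raise FormatError(f"record {rid!r}: read/quality length mismatch")
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# -- GFF3 ------------------------------------------------------------------

def write_gff3(
    loci: Sequence[tuple[str, GenomicLocus, dict]],
    path: str | Path,
    source: str = "mirforge",
    feature_type: str = "miRNA_gene",
) -> None:
    """Write (id, locus, attributes) triples as GFF3.

    Internal 0-based half-open coordinates are converted to the 1-based
    inclusive convention of GFF3 (start+1, end unchanged).
    """
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for lid, locus, attributes in loci:
            attrs = {"ID": lid, **attributes}
            attr_str = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                "\t".join(
                    [
                        locus.contig,
                        source,
                        feature_type,
                        str(locus.start + 1),
                        str(locus.end),
                        ".",
                        locus.strand,
                        ".",
                        attr_str,
                    ]
                )
                + "\n"
            )


def parse_gff3(path: str | Path) -> list[tuple[str, GenomicLocus, dict]]:
    """Read GFF3 back into (id, locus, attributes) with internal coordinates."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path} line {lineno}: expected 9 columns")
            contig, _, _, start, end, _, strand, _, attr_str = fields
            attributes = {}
            for item in attr_str.split(";"):
                if "=" in item:
                    k, v = item.split("=", 1)
                    attributes[k] = v
            lid = attributes.pop("ID", f"feature{lineno}")
            locus = GenomicLocus(contig, int(start) - 1, int(end), strand)
            out.append((lid, locus, attributes))
    return out


# -- config / logging ------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a flat YAML key-value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def setup_logging(verbosity: int = 0) -> None:
    level = logging.WARNING - 10 * min(verbosity, 2)
    logging.basicConfig(
        stream=sys.stderr,
        level=level,
        format="%(levelname)s %(name)s: %(message)s",
    )
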