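"""Format readers/writers shared by the CLI: FASTA/FASTQ/BED/SAM/TSV/YAML.

All coordinates are 0-based half-open internally; 1-based formats (SAM) are
converted at the boundary.  gzip input is autodetected by suffix.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional

import yaml
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .annotation import AlignmentRecord, RnaAnnotation
from .bridge import BridgeSpec, RawRead
from .contacts import Contact, IntervalSet


def open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def read_fastq(path) -> Iterator[RawRead]:
    with open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield RawRead(read_id=title.split()[0], sequence=seq, qualities=qual)


def write_fastq(path, reads: Iterable[RawRead]) -> None:
    with open_text(path, "wt") as handle:
        for read in reads:
            qual = read.qualities or "I" * len(read.sequence)
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


def read_fasta(path) -> dict[str, str]:
    with open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(path, sequences: Mapping[str, str], width: int = 80) -> None:
    with open_text(path, "wt") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED / intervals
# ---------------------------------------------------------------------------

def read_bed(path) -> list[tuple]:
    """BED rows as (chrom, start, end, *extra); 0-based half-open as written."""
    rows = []
    with open_text(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >= 3 fields")
            try:
                rows.append((fields[0], int(fields[1]), int(fields[2]), *fields[3:]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad BED coordinates") from exc
    return rows


def read_interval_set(path, name: Optional[str] = None) -> IntervalSet:
    return IntervalSet(
        name or Path(path).stem, [(r[0], r[1], r[2]) for r in read_bed(path)]
    )


def write_bed(path, rows: Iterable[tuple]) -> None:
    with open_text(path, "wt") as handle:
        for row in rows:
            handle.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# SAM (external aligner interface)
# ---------------------------------------------------------------------------

def read_sam(path, side: str, category: str = "genome") -> list[AlignmentRecord]:
    """Mapped SAM records as AlignmentRecords.

    Uniqueness uses AS/XS score tags when present (unique iff AS > XS), else
    a single reported hit counts as unique.  Requires pysam.
    """
    import pysam

    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as handle:
        for aln in handle:
            if aln.is_unmapped:
                continue
            score = float(aln.get_tag("AS")) if aln.has_tag("AS") else float(aln.query_length or 0)
            if aln.has_tag("XS"):
                unique = score > float(aln.get_tag("XS"))
            else:
                unique = True
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    side=side,
                    reference=aln.reference_name,
                    category=category,
                    start=aln.reference_start,
                    end=aln.reference_end,
                    strand="-" if aln.is_reverse else "+",
                    score=score,
                    unique=unique,
                )
            )
    return records


# ---------------------------------------------------------------------------
# annotations / contacts tables
# ---------------------------------------------------------------------------

def write_annotations(path, annotations: Iterable[RnaAnnotation]) -> None:
    with open_text(path, "wt") as handle:
        handle.write("read_id\tstatus\tgene_id\tcategory\tsense\n")
        for ann in annotations:
            sense = "" if ann.sense is None else int(ann.sense)
            handle.write(
                f"{ann.read_id}\t{ann.status}\t{ann.gene_id or ''}\t"
                f"{ann.category or ''}\t{sense}\n"
            )


def write_contacts(path, contacts: Iterable[Contact]) -> None:
    """BED-like contacts TSV sorted upstream by (chrom, start)."""
    with open_text(path, "wt") as handle:
        handle.write("chrom\tstart\tend\tread_id\tgene_id\tcategory\tsense\tdna_strand\n")
        for c in contacts:
            handle.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.read_id}\t{c.gene_id}\t"
                f"{c.rna_category}\t{int(c.sense)}\t{c.dna_strand}\n"
            )


def read_contacts(path) -> list[Contact]:
    contacts = []
    with open_text(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in handle:
            f = line.rstrip("\n").split("\t")
            contacts.append(
                Contact(
                    read_id=f[idx["read_id"]],
                    gene_id=f[idx["gene_id"]],
                    rna_category=f[idx["category"]],
                    sense=bool(int(f[idx["sense"]])),
                    chrom=f[idx["chrom"]],
                    start=int(f[idx["start"]]),
                    end=int(f[idx["end"]]),
                    dna_strand=f[idx.get("dna_strand", idx["sense"])] if "dna_strand" in idx else "+",
                )
            )
    return contacts


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_bridge_config(path) -> BridgeSpec:
    """BridgeSpec from a YAML mapping (sequence, rna_end, max_mismatches, min_flank)."""
    with open_text(path) as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, dict) or "sequence" not in raw:
        raise ValueError(f"{path}: bridge config must be a mapping with a 'sequence' key")
    return BridgeSpec(
        sequence=raw["sequence"],
        rna_end=raw.get("rna_end", "left"),
        max_mismatches=int(raw.get("max_mismatches", 1)),
        min_flank=int(raw.get("min_flank", 15)),
    )


def write_json(path, payload: dict) -> None:
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, default=float)
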