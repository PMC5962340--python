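"""Rejoining annotated RNA sides with DNA placements into RNA-DNA contacts.

Reads that survive splitting contribute at most one contact: the RNA-side
annotation and the DNA-side genomic placement sharing a read ID are merged,
then contact-level filters remove rRNA genes (including a user-supplied
re-annotation list) and contacts whose DNA interval touches a blacklist.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .annotation import ASSIGNED, AlignmentRecord, RnaAnnotation


@dataclass(frozen=True)
class Contact:
    """One RNA-to-DNA ligation event (DNA interval 0-based half-open)."""

    read_id: str
    gene_id: str
    rna_category: str
    sense: bool
    chrom: str
    start: int
    end: int
    dna_strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"contact {self.read_id}: empty DNA interval")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class IntervalSet:
    """Named set of merged, sorted, non-overlapping 0-based half-open intervals."""

    def __init__(self, name: str, intervals: Iterable[tuple[str, int, int]] = ()):
        self.name = name
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if end <= start:
                raise ValueError(f"{name}: empty interval {chrom}:{start}-{end}")
            per_chrom.setdefault(chrom, []).append((start, end))
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            merged: list[list[int]] = []
            for start, end in ivs:
                if merged and start <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], end)
                else:
                    merged.append([start, end])
            self._starts[chrom] = [m[0] for m in merged]
            self._ends[chrom] = [m[1] for m in merged]

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def intervals(self, chrom: Optional[str] = None) -> list[tuple[str, int, int]]:
        chroms = [chrom] if chrom is not None else self.chroms
        out = []
        for c in chroms:
            out.extend(
                (c, s, e) for s, e in zip(self._starts.get(c, ()), self._ends.get(c, ()))
            )
        return out

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff [start, end) overlaps any interval by >= 1 bp."""
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect.bisect_left(starts, end)  # first interval starting at/after end
        return i > 0 and self._ends[chrom][i - 1] > start

    def overlap_bp(self, chrom: str, start: int, end: int) -> int:
        """Total bases of [start, end) covered by the set."""
        starts = self._starts.get(chrom)
        if not starts:
            return 0
        ends = self._ends[chrom]
        total = 0
        i = bisect.bisect_right(starts, start) - 1
        if i < 0:
            i = 0
        for s, e in zip(starts[i:], ends[i:]):
            if s >= end:
                break
            total += max(0, min(e, end) - max(s, start))
        return total

    def total_bp(self) -> int:
        return sum(
            e - s for c in self._starts for s, e in zip(self._starts[c], self._ends[c])
        )


def join_contacts(
    rna_annotations: Iterable[RnaAnnotation],
    dna_placements: Iterable[AlignmentRecord],
) -> tuple[list[Contact], dict]:
    """Join RNA annotations and DNA placements by read ID into contacts.

    A contact is emitted for each read with an assigned RNA annotation and a
    unique DNA placement.  The accounting dictionary reports losses at every
    stage and satisfies input = contacts + sum(losses) on the union of read
    IDs seen.
    """
    rna_by_id: dict[str, RnaAnnotation] = {}
    for ann in rna_annotations:
        if ann.read_id in rna_by_id:
            raise ValueError(f"duplicate read_id in RNA annotations: {ann.read_id}")
        rna_by_id[ann.read_id] = ann
    dna_by_id: dict[str, AlignmentRecord] = {}
    for rec in dna_placements:
        if rec.read_id in dna_by_id:
            raise ValueError(f"duplicate read_id in DNA placements: {rec.read_id}")
        dna_by_id[rec.read_id] = rec

    contacts: list[Contact] = []
    accounting = {
        "rna_only": 0,
        "dna_only": 0,
        "rna_not_assigned": 0,
        "contacts": 0,
    }
    for read_id in rna_by_id.keys() | dna_by_id.keys():
        ann = rna_by_id.get(read_id)
        rec = dna_by_id.get(read_id)
        if ann is None:
            accounting["dna_only"] += 1
            continue
        if rec is None:
            accounting["rna_only"] += 1
            continue
        if ann.status != ASSIGNED:
            accounting["rna_not_assigned"] += 1
            continue
        contacts.append(
            Contact(
                read_id=read_id,
                gene_id=ann.gene_id,
                rna_category=ann.category,
                sense=bool(ann.sense),
                chrom=rec.reference,
                start=rec.start,
                end=rec.end,
                dna_strand=rec.strand,
            )
        )
    contacts.sort(key=lambda c: (c.chrom, c.start, c.read_id))
    accounting["contacts"] = len(contacts)
    accounting["input"] = len(rna_by_id.keys() | dna_by_id.keys())
    return contacts, accounting


def filter_contacts(
    contacts: Sequence[Contact],
    rrna_genes: Iterable[str] = (),
    blacklists: Sequence[IntervalSet] = (),
) -> tuple[list[Contact], dict]:
    """Remove rRNA-gene contacts and contacts overlapping any blacklist (>=1 bp)."""
    rrna = set(rrna_genes)
    kept: list[Contact] = []
    accounting = {"input": len(contacts), "rrna_removed": 0, "blacklist_removed": 0}
    for contact in contacts:
        if contact.gene_id in rrna or contact.rna_category == "rRNA":
            accounting["rrna_removed"] += 1
            continue
        if any(bl.overlaps(contact.chrom, contact.start, contact.end) for bl in blacklists):
            accounting["blacklist_removed"] += 1
            continue
        kept.append(contact)
    accounting["kept"] = len(kept)
    return kept, accounting


def strand_composition(contacts: Sequence[Contact]) -> dict[str, dict[str, float]]:
    """Per-category (and overall) sense/antisense fractions.

    Returns {category: {'n': int, 'sense': fraction, 'antisense': fraction}},
    including a 'total' entry; empty input yields an empty report.
    """
    if not contacts:
        return {}
    counts: dict[str, list[int]] = {}
    for contact in contacts:
        for key in (contact.rna_category, "total"):
            sense_anti = counts.setdefault(key, [0, 0])
            sense_anti[0 if contact.sense else 1] += 1
    report = {}
    for key, (n_sense, n_anti) in counts.items():
        n = n_sense + n_anti
        report[key] = {"n": n, "sense": n_sense / n, "antisense": n_anti / n}
    return report


def contacts_to_frame(contacts: Sequence[Contact]):
    """Contacts as a BED-like pandas DataFrame sorted by (chrom, start)."""
    import pandas as pd

    frame = pd.DataFrame(
        {
            "chrom": [c.chrom for c in contacts],
            "start": [c.start for c in contacts],
            "end": [c.end for c in contacts],
            "read_id": [c.read_id for c in contacts],
            "gene_id": [c.gene_id for c in contacts],
            "category": [c.rna_category for c in contacts],
            "sense": [int(c.sense) for c in contacts],
            "dna_strand": [c.dna_strand for c in contacts],
        }
    )
    return frame.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def contacts_from_frame(frame) -> list[Contact]:
    return [
        Contact(
            read_id=row.read_id,
            gene_id=row.gene_id,
            rna_category=row.category,
            sense=bool(row.sense),
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            dna_strand=row.dna_strand,
        )
        for row in frame.itertuples(index=False)
    ]
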