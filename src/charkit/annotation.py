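"""RNA-side annotation by ranked transcript categories; DNA-side placement.

RNA-side sequences are aligned per category reference set (mirroring
per-transcriptome alignment).  Sense alignments are considered first; only a
read with no valid sense alignment falls back to antisense.  Equal-score
alignments across categories resolve by a fixed priority rank, and reads
whose winning category is on the removal list are discarded.  DNA-side
sequences keep only a unique best-scoring genomic placement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .bridge import revcomp

#: ranked category order, highest priority first
DEFAULT_PRIORITY_ORDER = (
    "tRNA",
    "miscRNA",
    "ncRNA",
    "transcript",
    "three_prime_UTR",
    "five_prime_UTR",
    "exon",
    "intron",
    "miRNA",
    "gene",
    "gene_extended2000",
)
DEFAULT_REMOVED = frozenset({"tRNA", "miscRNA"})

ASSIGNED = "assigned"
REMOVED_CATEGORY = "removed_category"
UNALIGNED = "unaligned"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class PriorityOrder:
    """Category rank (highest priority first) and categories removed outright."""

    order: tuple[str, ...] = DEFAULT_PRIORITY_ORDER
    removed: frozenset[str] = DEFAULT_REMOVED

    def rank(self, category: str) -> int:
        try:
            return self.order.index(category)
        except ValueError:
            return len(self.order)

    def reversed(self) -> "PriorityOrder":
        return PriorityOrder(order=tuple(reversed(self.order)), removed=self.removed)


DEFAULT_PRIORITY = PriorityOrder()


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment of a read side to a reference sequence.

    ``strand`` is '+' when the query matches the reference forward strand
    (sense, for transcript references stored in transcript orientation).
    ``unique`` is true when the best-scoring location is strictly better than
    any alternative for this query within its reference set.
    """

    read_id: str
    side: str  # 'rna' | 'dna'
    reference: str
    category: str  # one of the ranked groups, or 'genome'
    start: int
    end: int
    strand: str
    score: float
    unique: bool

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start},{self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass
class RnaAnnotation:
    read_id: str
    status: str
    gene_id: Optional[str] = None
    category: Optional[str] = None
    sense: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.status == ASSIGNED and (self.gene_id is None or self.category is None):
            raise ValueError("assigned annotation requires gene_id and category")


class ToyAligner:
    """Exact-substring aligner over a reference set, both strands.

    Test/desk-scale stand-in for an external aligner: every exact occurrence
    of the query (or its reverse complement) is reported with score equal to
    the match length; ``unique`` is true iff exactly one maximal-score
    location exists.  A k-mer index on reference sequences makes per-query
    lookup O(candidates); queries shorter than k fall back to a linear scan.
    """

    def __init__(self, references: Mapping[str, str], k: int = 12):
        if not references:
            raise ValueError("references must be non-empty")
        self.k = k
        self.references = {name: seq.upper() for name, seq in references.items()}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.references.items():
            for pos in range(len(seq) - k + 1):
                self._index.setdefault(seq[pos : pos + k], []).append((name, pos))

    def _occurrences(self, query: str) -> list[tuple[str, int]]:
        out = []
        if len(query) >= self.k:
            for name, pos in self._index.get(query[: self.k], ()):
                if self.references[name].startswith(query, pos):
                    out.append((name, pos))
        else:
            for name, seq in self.references.items():
                pos = seq.find(query)
                while pos != -1:
                    out.append((name, pos))
                    pos = seq.find(query, pos + 1)
        return out

    def align(
        self, read_id: str, query: str, side: str = "rna", category: str = "genome"
    ) -> list[AlignmentRecord]:
        query = query.upper()
        if not query:
            return []
        placements: list[tuple[str, int, str]] = []
        for strand, q in (("+", query), ("-", revcomp(query))):
            placements.extend((name, pos, strand) for name, pos in self._occurrences(q))
        unique = len(placements) == 1  # all hits share score == len(query)
        return [
            AlignmentRecord(
                read_id=read_id,
                side=side,
                reference=name,
                category=category,
                start=pos,
                end=pos + len(query),
                strand=strand,
                score=float(len(query)),
                unique=unique,
            )
            for name, pos, strand in placements
        ]


def toy_align(
    queries: Mapping[str, str],
    references: Mapping[str, str],
    side: str = "rna",
    category: str = "genome",
    k: int = 12,
) -> list[AlignmentRecord]:
    """Align each query exactly against the reference set (both strands)."""
    aligner = ToyAligner(references, k=k)
    records: list[AlignmentRecord] = []
    for read_id, seq in queries.items():
        records.extend(aligner.align(read_id, seq, side=side, category=category))
    return records


def assign_rna(
    records: Sequence[AlignmentRecord], priority: PriorityOrder = DEFAULT_PRIORITY
) -> RnaAnnotation:
    """Resolve all RNA-side alignments of one read to a single annotation.

    Sense records are considered first; antisense only when no sense record
    exists.  Among equal-score records the highest-priority category wins;
    a winning removed category yields removed_category; unresolved
    equal-score ties between distinct genes within the winning category yield
    ambiguous.  The result is order-independent in the input records.
    """
    if not records:
        raise ValueError("assign_rna requires the read_id; use annotate_read for empty sets")
    read_ids = {r.read_id for r in records}
    if len(read_ids) > 1:
        raise ValueError(f"records span multiple read_ids: {sorted(read_ids)}")
    read_id = records[0].read_id
    if any(r.side != "rna" for r in records):
        raise ValueError("assign_rna expects side='rna' records")
    for sense in (True, False):
        strand = "+" if sense else "-"
        pool = [r for r in records if r.strand == strand]
        if not pool:
            continue
        best = max(r.score for r in pool)
        winners = [r for r in pool if r.score == best]
        top_rank = min(priority.rank(r.category) for r in winners)
        in_category = [r for r in winners if priority.rank(r.category) == top_rank]
        category = in_category[0].category
        if category in priority.removed:
            return RnaAnnotation(read_id=read_id, status=REMOVED_CATEGORY, category=category)
        genes = sorted({r.reference for r in in_category})
        if len(genes) > 1:
            return RnaAnnotation(read_id=read_id, status=AMBIGUOUS, category=category)
        return RnaAnnotation(
            read_id=read_id,
            status=ASSIGNED,
            gene_id=genes[0],
            category=category,
            sense=sense,
        )
    return RnaAnnotation(read_id=read_id, status=UNALIGNED)


def annotate_read(
    read_id: str,
    records: Sequence[AlignmentRecord],
    priority: PriorityOrder = DEFAULT_PRIORITY,
) -> RnaAnnotation:
    """assign_rna with explicit read_id so empty record sets map to unaligned."""
    if not records:
        return RnaAnnotation(read_id=read_id, status=UNALIGNED)
    return assign_rna(records, priority)


def assign_dna(records: Sequence[AlignmentRecord]) -> Optional[AlignmentRecord]:
    """Keep the unique best-scoring genomic placement, else None (multi-mapping)."""
    if not records:
        return None
    if any(r.side != "dna" for r in records):
        raise ValueError("assign_dna expects side='dna' records")
    best = max(r.score for r in records)
    winners = [r for r in records if r.score == best]
    if len(winners) != 1:
        return None
    return winners[0]
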