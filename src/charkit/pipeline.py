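"""End-to-end orchestration: dedup -> split -> align -> annotate -> contacts.

The in-memory entry point is :func:`run_pipeline`; the CLI wraps it with
file I/O.  Alignment uses the bundled exact-match aligner; SAM input from an
external aligner can be substituted by feeding AlignmentRecords directly to
the annotation step.  Accounting is conservative at every stage: input reads
equal surviving contacts plus the sum of recorded losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import bridge as br
from .annotation import (
    DEFAULT_PRIORITY,
    AlignmentRecord,
    PriorityOrder,
    RnaAnnotation,
    ToyAligner,
    annotate_read,
    assign_dna,
)
from .bridge import BridgeSpec, RawRead
from .contacts import Contact, IntervalSet, filter_contacts, join_contacts


@dataclass
class PipelineResult:
    contacts: list[Contact]
    annotations: dict[str, RnaAnnotation]
    dna_placements: dict[str, AlignmentRecord]
    drop_log: list[tuple[str, str]]  # (read_id, drop_reason)
    accounting: dict = field(default_factory=dict)

    def manifest(self) -> dict:
        return dict(self.accounting)


def run_pipeline(
    reads: Sequence[RawRead],
    bridge_spec: BridgeSpec,
    category_references: Mapping[str, Mapping[str, str]],
    genome: Mapping[str, str],
    priority: PriorityOrder = DEFAULT_PRIORITY,
    rrna_genes: Sequence[str] = (),
    blacklists: Sequence[IntervalSet] = (),
    dedup: bool = True,
) -> PipelineResult:
    """Run reads through dedup, splitting, alignment, annotation and joining.

    ``category_references`` maps category name -> {transcript id -> sense
    sequence}; ``genome`` maps chromosome -> sequence.  Returns contacts plus
    full loss accounting (input = contacts + sum of losses).
    """
    n_input = len(reads)
    if dedup:
        reads, dedup_stats = br.dedup_reads(reads)
    else:
        dedup_stats = br.DedupStats(n_input=n_input, n_retained=n_input)

    drop_log: list[tuple[str, str]] = []
    split_ok: list[br.SplitRead] = []
    drop_counts = {r: 0 for r in (br.NO_BRIDGE, br.MULTI_BRIDGE, br.SHORT_FLANK, br.ONE_SIDED)}
    for read in reads:
        split = br.split_read(read, br.find_bridge(read, bridge_spec), bridge_spec)
        if split.kept:
            split_ok.append(split)
        else:
            drop_counts[split.drop_reason] += 1
            drop_log.append((read.read_id, split.drop_reason))

    rna_aligners = {
        category: ToyAligner(refs) for category, refs in category_references.items() if refs
    }
    genome_aligner = ToyAligner(genome)

    annotations: dict[str, RnaAnnotation] = {}
    placements: dict[str, AlignmentRecord] = {}
    ann_counts = {"assigned": 0, "removed_category": 0, "unaligned": 0, "ambiguous": 0}
    dna_lost = {"dna_unaligned": 0, "dna_multimapped": 0}
    for split in split_ok:
        rna_records: list[AlignmentRecord] = []
        for category, aligner in rna_aligners.items():
            rna_records.extend(
                aligner.align(split.read_id, split.rna_seq, side="rna", category=category)
            )
        annotation = annotate_read(split.read_id, rna_records, priority)
        annotations[split.read_id] = annotation
        ann_counts[annotation.status] += 1

        dna_records = genome_aligner.align(split.read_id, split.dna_seq, side="dna")
        placement = assign_dna(dna_records)
        if placement is None:
            key = "dna_unaligned" if not dna_records else "dna_multimapped"
            dna_lost[key] += 1
        else:
            placements[split.read_id] = placement

    contacts, join_accounting = join_contacts(annotations.values(), placements.values())
    contacts, filter_accounting = filter_contacts(contacts, rrna_genes, blacklists)

    accounting = {
        "input_reads": n_input,
        "dedup": dedup_stats.as_dict(),
        "split_drops": drop_counts,
        "split_kept": len(split_ok),
        "rna_annotation": ann_counts,
        "dna_placement": dna_lost,
        "join": join_accounting,
        "filter": filter_accounting,
        "contacts": len(contacts),
    }
    return PipelineResult(
        contacts=contacts,
        annotations=annotations,
        dna_placements=placements,
        drop_log=drop_log,
        accounting=accounting,
    )


def accounting_balanced(accounting: dict) -> bool:
    """Check the conservation identity: input reads fully accounted for."""
    acc = accounting
    losses = (
        acc["dedup"]["duplicates"]
        + sum(acc["split_drops"].values())
        + acc["rna_annotation"]["removed_category"]
        + acc["rna_annotation"]["unaligned"]
        + acc["rna_annotation"]["ambiguous"]
        + sum(acc["dna_placement"].values())
        + acc["filter"]["rrna_removed"]
        + acc["filter"]["blacklist_removed"]
    )
    # reads losing both sides are counted once in each side's ledger; the
    # join step reports the overlap so the identity stays exact
    double_counted = (
        acc["rna_annotation"]["removed_category"]
        + acc["rna_annotation"]["unaligned"]
        + acc["rna_annotation"]["ambiguous"]
        + sum(acc["dna_placement"].values())
    ) - (
        acc["join"]["rna_not_assigned"] + acc["join"]["rna_only"] + acc["join"]["dna_only"]
    )
    return acc["input_reads"] == acc["contacts"] + losses - double_counted
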