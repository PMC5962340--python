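"""Read deduplication, bridge localization, and RNA/DNA splitting.

A chimeric read carries an RNA-derived fragment and a genomic DNA fragment
joined by a fixed bridge adapter.  The adapter sequence is written 5'->3' on
its top strand with the RNA-ligation (5'App) end first by convention, so the
flank adjacent to that end of a located bridge is the RNA side and the
opposite flank is the DNA side.  When the bridge is found in
reverse-complement orientation the flank roles swap and both flanks are
reverse-complemented back into the canonical strand convention, which makes
the recovered (rna_seq, dna_seq) pair invariant under reverse-complementing
the whole read.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

FORWARD = "forward"
REVCOMP = "reverse_complement"

#: drop reasons for reads that do not yield a usable RNA/DNA pair
NO_BRIDGE = "no_bridge"
MULTI_BRIDGE = "multi_bridge"
SHORT_FLANK = "short_flank"
ONE_SIDED = "one_sided"


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BridgeSpec:
    """Bridge adapter sequence and matching/splitting parameters.

    ``sequence`` is the adapter top strand 5'->3' with the RNA-ligation
    (5'App) end written first; ``rna_end`` records which end of ``sequence``
    is the 5'App end ('left' under the above convention).
    """

    sequence: str
    rna_end: str = "left"
    max_mismatches: int = 1
    min_flank: int = 15

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 10:
            raise ValueError("bridge sequence must be at least 10 nt")
        if set(seq) - set("ACGT"):
            raise ValueError("bridge sequence alphabet must be A/C/G/T")
        if self.rna_end not in ("left", "right"):
            raise ValueError("rna_end must be 'left' or 'right'")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.max_mismatches >= len(seq) / 4:
            raise ValueError("max_mismatches must be < bridge length / 4")
        if self.min_flank < 1:
            raise ValueError("min_flank must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RawRead:
    """A single sequencing read (qualities optional)."""

    read_id: str
    sequence: str
    qualities: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class BridgeHit:
    """One located bridge occurrence within a read (0-based half-open)."""

    start: int
    end: int
    orientation: str
    mismatches: int


@dataclass
class SplitRead:
    """Result of splitting one read around a single bridge occurrence."""

    read_id: str
    rna_seq: str = ""
    dna_seq: str = ""
    bridge_orientation: Optional[str] = None
    drop_reason: Optional[str] = None

    @property
    def kept(self) -> bool:
        return self.drop_reason is None


@dataclass
class DedupStats:
    n_input: int = 0
    n_retained: int = 0
    n_duplicates: int = 0

    def as_dict(self) -> dict:
        return {
            "input": self.n_input,
            "retained": self.n_retained,
            "duplicates": self.n_duplicates,
        }


def dedup_reads(reads: Iterable[RawRead]) -> tuple[list[RawRead], DedupStats]:
    """Remove exact full-length sequence duplicates, keeping first occurrences.

    Deduplication runs on the raw read sequence before any splitting; PCR
    duplicates of a chimera are byte-identical over the whole read.
    """
    seen: set[str] = set()
    kept: list[RawRead] = []
    stats = DedupStats()
    for read in reads:
        stats.n_input += 1
        if read.sequence in seen:
            stats.n_duplicates += 1
            continue
        seen.add(read.sequence)
        kept.append(read)
    stats.n_retained = len(kept)
    return kept, stats


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _mismatch_counts(read_arr: np.ndarray, pat_arr: np.ndarray) -> np.ndarray:
    """Hamming mismatch count of the pattern at every offset of the read."""
    if read_arr.size < pat_arr.size:
        return np.empty(0, dtype=np.intp)
    windows = np.lib.stride_tricks.sliding_window_view(read_arr, pat_arr.size)
    return (windows != pat_arr).sum(axis=1)


def find_bridge(read: RawRead, spec: BridgeSpec) -> list[BridgeHit]:
    """Locate all full-length bridge occurrences (both orientations) in a read.

    Matching is substitution-only (no indels); an N in the read never counts
    as a match.  Occurrences truncated by the read ends are not reported.
    Overlapping candidate hits of one occurrence are collapsed to the best
    (fewest mismatches, then leftmost, forward preferred on exact ties) and
    hits are returned sorted by start.
    """
    blen = len(spec)
    read_arr = _encode(read.sequence)
    if read_arr.size < blen:
        return []
    candidates: list[tuple[int, int, int]] = []  # (start, mismatches, orient_rank)
    for orient_rank, pat in enumerate((spec.sequence, revcomp(spec.sequence))):
        counts = _mismatch_counts(read_arr, _encode(pat))
        for start in np.flatnonzero(counts <= spec.max_mismatches):
            candidates.append((int(start), int(counts[start]), orient_rank))
    if not candidates:
        return []
    candidates.sort()
    # cluster mutually-overlapping candidates; keep the best per cluster
    hits: list[BridgeHit] = []
    cluster: list[tuple[int, int, int]] = []
    cluster_end = -1
    for cand in candidates:
        if cluster and cand[0] >= cluster_end:
            hits.append(_best_hit(cluster, blen))
            cluster = []
        cluster.append(cand)
        cluster_end = max(cluster_end, cand[0] + blen)
    if cluster:
        hits.append(_best_hit(cluster, blen))
    return hits


def _best_hit(cluster: list[tuple[int, int, int]], blen: int) -> BridgeHit:
    start, mismatches, orient_rank = min(cluster, key=lambda c: (c[1], c[0], c[2]))
    orientation = FORWARD if orient_rank == 0 else REVCOMP
    return BridgeHit(start=start, end=start + blen, orientation=orientation, mismatches=mismatches)


def split_read(read: RawRead, hits: list[BridgeHit], spec: BridgeSpec) -> SplitRead:
    """Split a read into RNA-side and DNA-side sequences around a single bridge.

    Zero hits -> no_bridge; two or more -> multi_bridge.  For a single hit the
    flank adjacent to the bridge's 5'App end is the RNA side; in
    reverse-complement orientation the flank roles swap and both flanks are
    reverse-complemented so the reported pair follows one strand convention.
    """
    if not hits:
        return SplitRead(read_id=read.read_id, drop_reason=NO_BRIDGE)
    if len(hits) >= 2:
        return SplitRead(read_id=read.read_id, drop_reason=MULTI_BRIDGE)
    hit = hits[0]
    if hit.start < 0 or hit.end > len(read.sequence) or hit.end - hit.start != len(spec):
        raise ValueError(
            f"read {read.read_id}: bridge hit [{hit.start},{hit.end}) outside read "
            f"of length {len(read.sequence)}"
        )
    left = read.sequence[: hit.start].upper()
    right = read.sequence[hit.end :].upper()
    rna_on_left = spec.rna_end == "left"
    if hit.orientation == REVCOMP:
        rna_on_left = not rna_on_left
        if rna_on_left:
            rna, dna = revcomp(left), revcomp(right)
        else:
            rna, dna = revcomp(right), revcomp(left)
    else:
        rna, dna = (left, right) if rna_on_left else (right, left)
    result = SplitRead(
        read_id=read.read_id,
        rna_seq=rna,
        dna_seq=dna,
        bridge_orientation=hit.orientation,
    )
    if not rna or not dna:
        result.drop_reason = ONE_SIDED
    elif len(rna) < spec.min_flank or len(dna) < spec.min_flank:
        result.drop_reason = SHORT_FLANK
    return result


def split_reads(
    reads: Iterable[RawRead], spec: BridgeSpec
) -> Iterator[SplitRead]:
    """find_bridge + split_read over a read stream."""
    for read in reads:
        yield split_read(read, find_bridge(read, spec), spec)
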