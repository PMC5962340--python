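"""Seeded synthetic datasets with ground truth for every pipeline stage.

The simulator emits a toy genome with planted GATC restriction sites, a
catalog of non-overlapping annotated transcripts in three localization
classes (cis-local, genome-wide trans, X-coating with a planted enrichment
fold), domain (TAD) coordinates, an expression table, spike-in transcripts
absent from the genome, and chimeric reads (RNA fragment + bridge + DNA
fragment) with configurable noise: bridge-less reads, multi-bridge reads,
PCR duplicates, substitution errors, antisense fractions and spike-in leak.
Every read has exactly one truth record; everything is deterministic under a
fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .bridge import BridgeSpec, RawRead, revcomp
from .contacts import Contact
from .tracks import GATC, GenomeIndex, find_gatc_sites

#: invented adapter for tests/simulations; real runs supply their own spec
DEFAULT_BRIDGE_SEQUENCE = "AACCGGTTCAGCTTAGCGATCCTAGTGC"

SIGNAL = "signal"
SPIKE = "spike"
NO_BRIDGE_NOISE = "no_bridge"
MULTI_BRIDGE_NOISE = "multi_bridge"
DUPLICATE = "duplicate"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Full specification of one synthetic dataset."""

    seed: int = 0
    # chrX kept a small share of the genome so an X-coating fold of 8 is
    # representable (fold * chrX_share must stay <= 1)
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr2L": 180_000, "chr3R": 150_000, "chrX": 45_000}
    )
    x_chrom: str = "chrX"
    gatc_per_kb: float = 5.0
    n_transcripts: int = 60
    transcript_length: tuple[int, int] = (300, 1500)
    category_weights: dict[str, float] = field(
        default_factory=lambda: {
            "ncRNA": 0.25,
            "transcript": 0.45,
            "exon": 0.20,
            "tRNA": 0.05,
            "miscRNA": 0.05,
        }
    )
    class_weights: tuple[float, float, float] = (0.4, 0.4, 0.2)  # (I, II, III)
    class3_fold: float = 8.0
    cis_window: int = 20_000
    n_reads: int = 10_000
    read_length: int = 152
    bridge: BridgeSpec = field(
        default_factory=lambda: BridgeSpec(sequence=DEFAULT_BRIDGE_SEQUENCE)
    )
    no_bridge_fraction: float = 0.0
    multi_bridge_fraction: float = 0.0
    duplicate_rate: float = 0.0
    error_rate: float = 0.0
    antisense_fraction: float = 0.0
    spike_leak_rate: float = 0.0
    n_spike_transcripts: int = 3
    spike_length: int = 500
    rnase_mode: bool = False
    tad_size: int = 10_000
    boundary_factor: float = 1.0
    boundary_half: int = 10_000

    def __post_init__(self) -> None:
        if abs(sum(self.class_weights) - 1.0) > 1e-9:
            raise ValueError("class_weights must sum to 1")
        for name in (
            "no_bridge_fraction",
            "multi_bridge_fraction",
            "duplicate_rate",
            "error_rate",
            "antisense_fraction",
            "spike_leak_rate",
        ):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        min_len = len(self.bridge) + 2 * self.bridge.min_flank
        if self.read_length < min_len:
            raise ValueError(
                f"read_length {self.read_length} shorter than bridge + 2*min_flank ({min_len})"
            )

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass(frozen=True)
class Transcript:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    category: str
    loc_class: str  # 'I' | 'II' | 'III' | 'spike'
    sequence: str

    @property
    def genomic(self) -> bool:
        return self.loc_class != "spike"


@dataclass(frozen=True)
class SimTruthRecord:
    read_id: str
    gene_id: str
    category: str
    sense: bool
    chrom: str
    start: int
    end: int
    noise_class: str


def _random_bases(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _scrub_gatc(arr: np.ndarray, rng: np.random.Generator) -> int:
    """Mutate accidental GATC occurrences until none remain; return count."""
    removed = 0
    while True:
        hits = np.flatnonzero(
            (arr[:-3] == ord("G"))
            & (arr[1:-2] == ord("A"))
            & (arr[2:-1] == ord("T"))
            & (arr[3:] == ord("C"))
        )
        if not hits.size:
            return removed
        removed += hits.size
        # change the terminal C to a non-C base
        arr[hits + 3] = _BASES[[0, 1, 3]][rng.integers(0, 3, size=hits.size)]


def make_genome(config: SimConfig) -> tuple[dict[str, str], GenomeIndex, dict]:
    """Random genome with GATC sites planted at the target density.

    Accidental GATC occurrences are scrubbed before planting, so the final
    site count per chromosome equals the target exactly (reported); with
    density 0 the raw random sequence is kept and background sites counted.
    """
    rng = config.rng(1)
    genome: dict[str, str] = {}
    sites: dict[str, np.ndarray] = {}
    report: dict[str, dict] = {}
    for chrom, length in config.chromosomes.items():
        arr = _random_bases(rng, length)
        n_target = int(round(config.gatc_per_kb * length / 1000.0))
        if n_target * 2 * len(GATC) > length:
            raise ValueError(f"{chrom}: GATC density {config.gatc_per_kb}/kb infeasible")
        scrubbed = 0
        if n_target > 0:
            scrubbed = _scrub_gatc(arr, rng)
            spacing = length / n_target
            jitter = rng.random(n_target) * max(spacing - len(GATC) - 1, 1)
            positions = np.minimum(
                (np.arange(n_target) * spacing + jitter).astype(np.int64),
                length - len(GATC),
            )
            pattern = np.frombuffer(GATC.encode(), dtype=np.uint8)
            for pos in positions:
                arr[pos : pos + len(GATC)] = pattern
        seq = arr.tobytes().decode("ascii")
        genome[chrom] = seq
        found = find_gatc_sites(seq)
        sites[chrom] = found
        report[chrom] = {
            "length": length,
            "target_sites": n_target,
            "observed_sites": int(found.size),
            "background_scrubbed": int(scrubbed),
        }
        if n_target > 0 and found.size != n_target:
            raise AssertionError(f"{chrom}: planted {n_target} sites, observed {found.size}")
    index = GenomeIndex(chrom_lengths=dict(config.chromosomes), sites=sites)
    return genome, index, report


def make_transcripts(
    config: SimConfig, genome: Mapping[str, str]
) -> tuple[list[Transcript], list[Transcript], dict[str, float]]:
    """Non-overlapping annotated transcripts plus spike-ins and expression.

    Transcripts are placed in evenly spaced slots with jitter (never
    overlapping), stranded at random, and given a category and a
    localization class by configured weights.  Spike-in transcripts are
    random sequences absent from the genome with expression 0.
    """
    rng = config.rng(2)
    chroms = list(config.chromosomes)
    lengths = np.array([config.chromosomes[c] for c in chroms], dtype=float)
    per_chrom = np.maximum(1, np.round(config.n_transcripts * lengths / lengths.sum()).astype(int))
    categories = list(config.category_weights)
    cat_p = np.array([config.category_weights[c] for c in categories], dtype=float)
    cat_p = cat_p / cat_p.sum()
    class_labels = ("I", "II", "III")
    lmin, lmax = config.transcript_length
    transcripts: list[Transcript] = []
    counter = 0
    for chrom, n_here in zip(chroms, per_chrom):
        length = config.chromosomes[chrom]
        slot = length // int(n_here)
        if slot <= lmax + 10:
            raise ValueError(f"{chrom}: too many transcripts for chromosome length")
        for i in range(int(n_here)):
            counter += 1
            t_len = int(rng.integers(lmin, lmax + 1))
            start = i * slot + int(rng.integers(0, slot - t_len))
            end = start + t_len
            strand = "+" if rng.random() < 0.5 else "-"
            seq = genome[chrom][start:end]
            if strand == "-":
                seq = revcomp(seq)
            transcripts.append(
                Transcript(
                    gene_id=f"gene{counter:04d}",
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    category=categories[rng.choice(len(categories), p=cat_p)],
                    loc_class=class_labels[
                        rng.choice(3, p=np.asarray(config.class_weights, dtype=float))
                    ],
                    sequence=seq,
                )
            )
    spikes = [
        Transcript(
            gene_id=f"spike{i + 1:02d}",
            chrom="*",
            start=0,
            end=config.spike_length,
            strand="+",
            category="ncRNA",
            loc_class="spike",
            sequence=_random_bases(rng, config.spike_length).tobytes().decode("ascii"),
        )
        for i in range(config.n_spike_transcripts)
    ]
    expression = {
        t.gene_id: float(np.exp(rng.normal(2.0, 1.0))) for t in transcripts
    }
    expression.update({s.gene_id: 0.0 for s in spikes})
    return transcripts, spikes, expression


def make_tads(config: SimConfig, chrom_lengths: Optional[Mapping[str, int]] = None) -> list[tuple[str, int, int]]:
    """Non-overlapping fixed-width domains tiling each chromosome."""
    lengths = config.chromosomes if chrom_lengths is None else chrom_lengths
    tads = []
    for chrom, length in lengths.items():
        for i in range(length // config.tad_size):
            tads.append((chrom, i * config.tad_size, (i + 1) * config.tad_size))
    return tads


class _SiteSampler:
    """Uniform / stratified sampling over the genome's restriction sites."""

    def __init__(
        self,
        config: SimConfig,
        index: GenomeIndex,
        tads: Optional[Sequence[tuple[str, int, int]]],
    ):
        self.index = index
        self.chroms = list(index.chroms)
        self.site_chrom: list[str] = []
        pos_parts = []
        for chrom in self.chroms:
            arr = index.sites[chrom]
            self.site_chrom.extend([chrom] * arr.size)
            pos_parts.append(arr)
        self.site_pos = (
            np.concatenate(pos_parts) if pos_parts else np.empty(0, dtype=np.int64)
        )
        if not self.site_pos.size:
            raise ValueError("genome has no restriction sites")
        self.site_chrom_arr = np.asarray(self.site_chrom)
        self.x_idx = np.flatnonzero(self.site_chrom_arr == config.x_chrom)
        self.auto_idx = np.flatnonzero(self.site_chrom_arr != config.x_chrom)
        lx = index.chrom_lengths.get(config.x_chrom, 0)
        self.p_x = min(1.0, config.class3_fold * lx / index.genome_length())
        self.boundary_idx = None
        self.nonboundary_idx = None
        self.p_boundary = None
        if tads is not None and config.boundary_factor != 1.0:
            edge_regions: dict[str, list[tuple[int, int]]] = {}
            for chrom, start, end in tads:
                for edge in (start, end):
                    edge_regions.setdefault(chrom, []).append(
                        (edge - config.boundary_half, edge + config.boundary_half)
                    )
            flags = np.zeros(self.site_pos.size, dtype=bool)
            offset = 0
            for chrom in self.chroms:
                arr = index.sites[chrom]
                for lo, hi in edge_regions.get(chrom, ()):
                    i0 = np.searchsorted(arr, lo)
                    i1 = np.searchsorted(arr, hi)
                    flags[offset + i0 : offset + i1] = True
                offset += arr.size
            self.boundary_idx = np.flatnonzero(flags)
            self.nonboundary_idx = np.flatnonzero(~flags)
            nb = self.boundary_idx.size
            nn = self.nonboundary_idx.size
            f = config.boundary_factor
            self.p_boundary = (f * nb) / (f * nb + nn) if (nb and nn) else None

    def uniform(self, rng: np.random.Generator) -> int:
        if self.p_boundary is not None:
            if rng.random() < self.p_boundary:
                return int(self.boundary_idx[rng.integers(0, self.boundary_idx.size)])
            return int(self.nonboundary_idx[rng.integers(0, self.nonboundary_idx.size)])
        return int(rng.integers(0, self.site_pos.size))

    def x_coating(self, rng: np.random.Generator) -> int:
        if self.x_idx.size and rng.random() < self.p_x:
            return int(self.x_idx[rng.integers(0, self.x_idx.size)])
        pool = self.auto_idx if self.auto_idx.size else self.x_idx
        return int(pool[rng.integers(0, pool.size)])

    def cis(self, rng: np.random.Generator, transcript: Transcript, window: int) -> Optional[int]:
        arr = self.index.sites[transcript.chrom]
        i0 = np.searchsorted(arr, transcript.start - window)
        i1 = np.searchsorted(arr, transcript.end + window)
        if i1 <= i0:
            if not arr.size:
                return None
            i0, i1 = 0, arr.size
        local = int(rng.integers(i0, i1))
        offset = 0
        for chrom in self.chroms:
            if chrom == transcript.chrom:
                return offset + local
            offset += self.index.sites[chrom].size
        return None


def make_reads(
    config: SimConfig,
    genome: Mapping[str, str],
    index: GenomeIndex,
    transcripts: Sequence[Transcript],
    spikes: Sequence[Transcript] = (),
    tads: Optional[Sequence[tuple[str, int, int]]] = None,
) -> tuple[list[RawRead], list[SimTruthRecord]]:
    """Chimeric reads plus one truth record per read.

    Signal reads are rna_fragment + bridge + dna_fragment (presented on a
    random sequencing strand); DNA fragments start at a GATC site and run to
    the next site, clamped into [min_flank, remaining read budget].  Noise
    reads, duplicates and substitution errors follow the configured rates;
    truth stores pre-error identities.  rnase_mode emits bridge-less reads
    only.
    """
    rng = config.rng(3)
    bridge = config.bridge
    blen = len(bridge)
    min_flank = bridge.min_flank
    max_rna = config.read_length - blen - min_flank
    sampler = _SiteSampler(config, index, tads)
    chrom_names = list(config.chromosomes)
    chrom_weights = np.array([config.chromosomes[c] for c in chrom_names], dtype=float)
    chrom_weights /= chrom_weights.sum()

    reads: list[RawRead] = []
    truth: list[SimTruthRecord] = []

    def random_genomic(length: int) -> tuple[str, int, str]:
        chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_weights)]
        start = int(rng.integers(0, config.chromosomes[chrom] - length))
        return chrom, start, genome[chrom][start : start + length]

    def dna_fragment(site_idx: int, budget: int) -> tuple[str, int, int, str]:
        chrom = sampler.site_chrom[site_idx]
        pos = int(sampler.site_pos[site_idx])
        arr = index.sites[chrom]
        local = int(np.searchsorted(arr, pos))
        next_pos = int(arr[local + 1]) if local + 1 < arr.size else index.chrom_lengths[chrom]
        frag_len = min(max(next_pos - pos, min_flank), budget, index.chrom_lengths[chrom] - pos)
        return chrom, pos, pos + frag_len, genome[chrom][pos : pos + frag_len]

    def build_signal(read_id: str, noise_class: str) -> tuple[RawRead, SimTruthRecord]:
        if noise_class == SPIKE:
            transcript = spikes[int(rng.integers(0, len(spikes)))]
        else:
            transcript = transcripts[int(rng.integers(0, len(transcripts)))]
        rna_len = int(rng.integers(min_flank, min(max_rna, len(transcript.sequence)) + 1))
        rna_start = int(rng.integers(0, len(transcript.sequence) - rna_len + 1))
        frag = transcript.sequence[rna_start : rna_start + rna_len]
        sense = rng.random() >= config.antisense_fraction
        rna_part = frag if sense else revcomp(frag)
        budget = config.read_length - blen - rna_len
        if noise_class == SPIKE or transcript.loc_class in ("II", "spike"):
            site_idx = sampler.uniform(rng)
        elif transcript.loc_class == "III":
            site_idx = sampler.x_coating(rng)
        else:  # class I, cis-local
            site_idx = sampler.cis(rng, transcript, config.cis_window)
            if site_idx is None:
                site_idx = sampler.uniform(rng)
        for _ in range(10):
            chrom, start, end, dna_part = dna_fragment(site_idx, budget)
            if end - start >= min_flank:
                break
            site_idx = sampler.uniform(rng)
        if bridge.rna_end == "left":
            seq = rna_part + bridge.sequence + dna_part
        else:
            seq = dna_part + bridge.sequence + rna_part
        if rng.random() < 0.5:
            seq = revcomp(seq)
        record = SimTruthRecord(
            read_id=read_id,
            gene_id=transcript.gene_id,
            category=transcript.category,
            sense=sense,
            chrom=chrom,
            start=start,
            end=end,
            noise_class=noise_class,
        )
        return RawRead(read_id=read_id, sequence=seq, qualities="I" * len(seq)), record

    for i in range(config.n_reads):
        read_id = f"r{i:07d}"
        if reads and config.duplicate_rate > 0 and rng.random() < config.duplicate_rate:
            j = int(rng.integers(0, len(reads)))
            original = truth[j]
            reads.append(
                RawRead(
                    read_id=read_id,
                    sequence=reads[j].sequence,
                    qualities=reads[j].qualities,
                )
            )
            truth.append(dataclasses.replace(original, read_id=read_id, noise_class=DUPLICATE))
            continue
        draw = rng.random()
        if config.rnase_mode or draw < config.no_bridge_fraction:
            chrom, start, seq = random_genomic(config.read_length)
            reads.append(RawRead(read_id=read_id, sequence=seq, qualities="I" * len(seq)))
            truth.append(
                SimTruthRecord(
                    read_id=read_id,
                    gene_id="",
                    category="",
                    sense=True,
                    chrom=chrom,
                    start=start,
                    end=start + config.read_length,
                    noise_class=NO_BRIDGE_NOISE,
                )
            )
            continue
        if draw < config.no_bridge_fraction + config.multi_bridge_fraction:
            spacer = _random_bases(rng, 8).tobytes().decode("ascii")
            _, _, rna_seq = random_genomic(min_flank + 5)
            _, _, dna_seq = random_genomic(min_flank + 5)
            seq = rna_seq + bridge.sequence + spacer + bridge.sequence + dna_seq
            reads.append(RawRead(read_id=read_id, sequence=seq, qualities="I" * len(seq)))
            truth.append(
                SimTruthRecord(
                    read_id=read_id,
                    gene_id="",
                    category="",
                    sense=True,
                    chrom="*",
                    start=0,
                    end=1,
                    noise_class=MULTI_BRIDGE_NOISE,
                )
            )
            continue
        is_spike = (
            spikes
            and config.spike_leak_rate > 0
            and rng.random() < config.spike_leak_rate
        )
        read, record = build_signal(read_id, SPIKE if is_spike else SIGNAL)
        reads.append(read)
        truth.append(record)

    if config.error_rate > 0:
        for i, read in enumerate(reads):
            arr = np.frombuffer(read.sequence.encode(), dtype=np.uint8).copy()
            hits = np.flatnonzero(rng.random(arr.size) < config.error_rate)
            if hits.size:
                # substitute with a uniformly chosen different base
                arr[hits] = _BASES[(rng.integers(1, 4, size=hits.size) +
                                    np.searchsorted(_BASES, arr[hits])) % 4]
                reads[i] = RawRead(
                    read_id=read.read_id,
                    sequence=arr.tobytes().decode("ascii"),
                    qualities=read.qualities,
                )
    return reads, truth


@dataclass
class SimData:
    """One fully materialized synthetic dataset."""

    config: SimConfig
    genome: dict[str, str]
    index: GenomeIndex
    genome_report: dict
    transcripts: list[Transcript]
    spikes: list[Transcript]
    expression: dict[str, float]
    tads: list[tuple[str, int, int]]
    reads: list[RawRead]
    truth: list[SimTruthRecord]

    def category_references(self) -> dict[str, dict[str, str]]:
        """Per-category reference sets (spikes included under their category)."""
        refs: dict[str, dict[str, str]] = {}
        for t in list(self.transcripts) + list(self.spikes):
            refs.setdefault(t.category, {})[t.gene_id] = t.sequence
        return refs

    def truth_by_id(self) -> dict[str, SimTruthRecord]:
        return {t.read_id: t for t in self.truth}

    def transcript_lengths(self) -> dict[str, int]:
        return {
            t.gene_id: len(t.sequence) for t in list(self.transcripts) + list(self.spikes)
        }

    def spike_ids(self) -> set[str]:
        return {s.gene_id for s in self.spikes}


def simulate_dataset(config: SimConfig) -> SimData:
    """Generate genome, annotations, domains, reads and truth for a config."""
    genome, index, report = make_genome(config)
    transcripts, spikes, expression = make_transcripts(config, genome)
    tads = make_tads(config)
    reads, truth = make_reads(
        config, genome, index, transcripts, spikes,
        tads=tads if config.boundary_factor != 1.0 else None,
    )
    return SimData(
        config=config,
        genome=genome,
        index=index,
        genome_report=report,
        transcripts=transcripts,
        spikes=spikes,
        expression=expression,
        tads=tads,
        reads=reads,
        truth=truth,
    )


def simulate_boundary_contacts(
    chrom_lengths: Mapping[str, int],
    tads: Sequence[tuple[str, int, int]],
    n_contacts: int,
    factor: float = 1.0,
    seed: int = 0,
    region_half: int = 10_000,
    site_spacing: int = 200,
    gene_id: str = "simRNA",
) -> tuple[list[Contact], GenomeIndex]:
    """Contact-level sampler with a planted boundary:elsewhere density ratio.

    Builds a uniform restriction-site lattice, marks sites within
    +/-region_half of any domain edge as boundary sites, and samples contact
    positions so the per-site density ratio boundary:elsewhere equals
    ``factor``.  Used for calibration/power checks of the boundary test.
    """
    rng = np.random.default_rng(seed)
    sites = {
        chrom: np.arange(site_spacing // 2, length - 4, site_spacing, dtype=np.int64)
        for chrom, length in chrom_lengths.items()
    }
    index = GenomeIndex(chrom_lengths=dict(chrom_lengths), sites=sites)
    chroms = list(chrom_lengths)
    flat_chrom: list[str] = []
    flat_pos = []
    for chrom in chroms:
        flat_chrom.extend([chrom] * sites[chrom].size)
        flat_pos.append(sites[chrom])
    flat_pos = np.concatenate(flat_pos)
    flags = np.zeros(flat_pos.size, dtype=bool)
    offset = 0
    for chrom in chroms:
        arr = sites[chrom]
        for t_chrom, start, end in tads:
            if t_chrom != chrom:
                continue
            for edge in (start, end):
                i0 = np.searchsorted(arr, edge - region_half)
                i1 = np.searchsorted(arr, edge + region_half)
                flags[offset + i0 : offset + i1] = True
        offset += arr.size
    boundary = np.flatnonzero(flags)
    elsewhere = np.flatnonzero(~flags)
    p_boundary = factor * boundary.size / (factor * boundary.size + elsewhere.size)
    contacts = []
    for i in range(n_contacts):
        if boundary.size and rng.random() < p_boundary:
            idx = int(boundary[rng.integers(0, boundary.size)])
        else:
            idx = int(elsewhere[rng.integers(0, elsewhere.size)])
        pos = int(flat_pos[idx])
        contacts.append(
            Contact(
                read_id=f"c{i:07d}",
                gene_id=gene_id,
                rna_category="ncRNA",
                sense=True,
                chrom=flat_chrom[idx],
                start=pos,
                end=pos + 50,
            )
        )
    return contacts, index


def write_dataset(data: SimData, outdir) -> dict:
    """Write FASTA/FASTQ/BED/TSV artifacts plus a manifest; returns the manifest."""
    from . import io as ckio

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ckio.write_fasta(out / "genome.fa", data.genome)
    ckio.write_fastq(out / "reads.fastq", data.reads)
    refdir = out / "references"
    refdir.mkdir(exist_ok=True)
    for category, refs in data.category_references().items():
        ckio.write_fasta(refdir / f"{category}.fa", refs)
    with open(out / "genes.bed", "w") as handle:
        for t in data.transcripts:
            handle.write(
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.gene_id}\t0\t{t.strand}\t"
                f"{t.category}\t{t.loc_class}\n"
            )
    with open(out / "tads.bed", "w") as handle:
        for chrom, start, end in data.tads:
            handle.write(f"{chrom}\t{start}\t{end}\n")
    with open(out / "expression.tsv", "w") as handle:
        handle.write("gene_id\texpression\n")
        for gene_id, value in data.expression.items():
            handle.write(f"{gene_id}\t{value:.6g}\n")
    with open(out / "truth.tsv", "w") as handle:
        handle.write("read_id\tgene_id\tcategory\tsense\tchrom\tstart\tend\tnoise_class\n")
        for t in data.truth:
            handle.write(
                f"{t.read_id}\t{t.gene_id}\t{t.category}\t{int(t.sense)}\t"
                f"{t.chrom}\t{t.start}\t{t.end}\t{t.noise_class}\n"
            )
    manifest = {
        "seed": data.config.seed,
        "n_reads": len(data.reads),
        "n_transcripts": len(data.transcripts),
        "n_spikes": len(data.spikes),
        "genome": data.genome_report,
        "files": [
            "genome.fa",
            "reads.fastq",
            "genes.bed",
            "tads.bed",
            "expression.tsv",
            "truth.tsv",
        ],
    }
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2)
    return manifest
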