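"""Restriction-site-normalized coverage tracks, z-score transforms, metaprofiles.

Coverage is computed per fixed-width bin (tiled, or sliding when step <
bin_size) from DNA-fragment midpoints, normalized by the number of GATC
restriction sites per bin; bins without a site are excluded rather than
written as zero.  Observed/expected z-score tracks use a uniform null that
distributes each RNA's total contacts proportionally to per-bin site counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .contacts import Contact

GATC = "GATC"


class DegenerateTrackError(ValueError):
    """Raised when a z-score transform is requested for a constant track."""


@dataclass
class GenomeIndex:
    """Chromosome lengths plus sorted GATC site coordinates per chromosome."""

    chrom_lengths: dict[str, int]
    sites: dict[str, np.ndarray] = field(default_factory=dict)
    heterochromatic: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_lengths.items():
            arr = np.asarray(self.sites.get(chrom, ()), dtype=np.int64)
            if arr.size and (arr.min() < 0 or arr.max() + len(GATC) > length):
                raise ValueError(f"{chrom}: site out of bounds")
            if arr.size and np.any(np.diff(arr) < 0):
                arr = np.sort(arr)
            self.sites[chrom] = arr

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_lengths)

    def genome_length(self, chroms: Optional[Iterable[str]] = None) -> int:
        chroms = self.chroms if chroms is None else list(chroms)
        return sum(self.chrom_lengths[c] for c in chroms)

    def total_sites(self, chroms: Optional[Iterable[str]] = None) -> int:
        chroms = self.chroms if chroms is None else list(chroms)
        return int(sum(self.sites[c].size for c in chroms))

    def sites_in(self, chrom: str, start: int, end: int) -> int:
        arr = self.sites.get(chrom)
        if arr is None or not arr.size:
            return 0
        return int(np.searchsorted(arr, end) - np.searchsorted(arr, start))


def find_gatc_sites(sequence: str) -> np.ndarray:
    """0-based start positions of every GATC occurrence (forward strand).

    The GATC site is strand-symmetric (its reverse complement is itself), so
    a forward scan records each site exactly once.
    """
    seq = sequence.upper()
    positions = []
    pos = seq.find(GATC)
    while pos != -1:
        positions.append(pos)
        pos = seq.find(GATC, pos + 1)
    return np.asarray(positions, dtype=np.int64)


def dpnII_sites(
    genome: Mapping[str, str], heterochromatic: Iterable[str] = ()
) -> GenomeIndex:
    """Build a GenomeIndex (lengths + GATC sites) from chromosome sequences."""
    return GenomeIndex(
        chrom_lengths={chrom: len(seq) for chrom, seq in genome.items()},
        sites={chrom: find_gatc_sites(seq) for chrom, seq in genome.items()},
        heterochromatic=frozenset(heterochromatic),
    )


@dataclass
class BinnedTrack:
    """Fixed-width per-chromosome signal vectors with an inclusion mask.

    Bin i of a chromosome covers [i*step, i*step + bin_size); vectors have
    ceil(length / step) entries.  Excluded bins (mask False) hold NaN.
    """

    bin_size: int
    step: int
    values: dict[str, np.ndarray]
    mask: dict[str, np.ndarray]
    normalization: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.step > self.bin_size:
            raise ValueError("step must be <= bin_size")
        for chrom, vec in self.values.items():
            if vec.shape != self.mask[chrom].shape:
                raise ValueError(f"{chrom}: values/mask shape mismatch")

    @property
    def chroms(self) -> list[str]:
        return list(self.values)

    def included(self, chroms: Optional[Iterable[str]] = None) -> np.ndarray:
        """Concatenated values over included bins, in (chrom, bin) order."""
        chroms = self.chroms if chroms is None else list(chroms)
        parts = [self.values[c][self.mask[c]] for c in chroms if c in self.values]
        if not parts:
            return np.empty(0)
        return np.concatenate(parts)

    def included_bins(
        self, chroms: Optional[Iterable[str]] = None
    ) -> list[tuple[str, int, float]]:
        """(chrom, bin index, value) triples for included bins, coordinate order."""
        chroms = self.chroms if chroms is None else list(chroms)
        out = []
        for chrom in chroms:
            if chrom not in self.values:
                continue
            for i in np.flatnonzero(self.mask[chrom]):
                out.append((chrom, int(i), float(self.values[chrom][i])))
        return out

    def value_at(self, chrom: str, position: int) -> float:
        """Track value of the tile containing a position (NaN when excluded)."""
        vec = self.values.get(chrom)
        if vec is None or position < 0:
            return math.nan
        i = min(position // self.step, vec.size - 1)
        return float(vec[i])


def _n_bins(length: int, step: int) -> int:
    return -(-length // step)


def _windowed_site_counts(
    sites: np.ndarray, length: int, bin_size: int, step: int
) -> np.ndarray:
    n = _n_bins(length, step)
    starts = np.arange(n, dtype=np.int64) * step
    ends = np.minimum(starts + bin_size, length)
    return np.searchsorted(sites, ends) - np.searchsorted(sites, starts)


def _windowed_counts(
    midpoints: np.ndarray, length: int, bin_size: int, step: int
) -> np.ndarray:
    """Per-bin count of midpoints falling in [i*step, i*step + bin_size)."""
    n = _n_bins(length, step)
    counts = np.zeros(n, dtype=np.float64)
    if not midpoints.size:
        return counts
    hi = midpoints // step  # last bin whose window contains the midpoint
    lo = np.maximum(0, (midpoints - bin_size) // step + 1)
    span = bin_size // step
    for offset in range(span):
        idx = hi - offset
        valid = (idx >= lo) & (idx >= 0) & (idx < n)
        np.add.at(counts, idx[valid], 1.0)
    return counts


def coverage_track(
    contacts: Sequence[Contact],
    index: GenomeIndex,
    bin_size: int = 200,
    step: Optional[int] = None,
    normalization: str = "dpnii",
    male_x_doubling: bool = False,
    x_chroms: Sequence[str] = ("chrX", "chrXHet"),
    chroms: Optional[Sequence[str]] = None,
) -> BinnedTrack:
    """Binned contact coverage, optionally normalized per-bin by GATC sites.

    Contacts are assigned to bins by DNA-fragment midpoint.  With
    ``male_x_doubling`` the raw counts on ``x_chroms`` are doubled before
    site normalization.  In 'dpnii' mode, bins lacking a GATC site are
    excluded (masked, NaN); 'raw' mode keeps every bin.
    """
    if normalization not in ("raw", "dpnii"):
        raise ValueError(f"unknown normalization {normalization!r}")
    step = bin_size if step is None else step
    if step > bin_size:
        raise ValueError("step must be <= bin_size")
    if bin_size % step:
        raise ValueError("bin_size must be a multiple of step")
    chroms = list(index.chroms) if chroms is None else list(chroms)
    mids: dict[str, list[int]] = {c: [] for c in chroms}
    for contact in contacts:
        if contact.chrom in mids:
            mids[contact.chrom].append(contact.midpoint)
    values: dict[str, np.ndarray] = {}
    mask: dict[str, np.ndarray] = {}
    for chrom in chroms:
        length = index.chrom_lengths[chrom]
        counts = _windowed_counts(
            np.asarray(sorted(mids[chrom]), dtype=np.int64), length, bin_size, step
        )
        if male_x_doubling and chrom in x_chroms:
            counts = counts * 2.0
        if normalization == "dpnii":
            site_counts = _windowed_site_counts(index.sites[chrom], length, bin_size, step)
            included = site_counts > 0
            vec = np.full(counts.shape, np.nan)
            vec[included] = counts[included] / site_counts[included]
        else:
            included = np.ones(counts.shape, dtype=bool)
            vec = counts
        values[chrom] = vec
        mask[chrom] = included
    return BinnedTrack(
        bin_size=bin_size,
        step=step,
        values=values,
        mask=mask,
        normalization=normalization,
        meta={"male_x_doubling": male_x_doubling, "n_contacts": len(contacts)},
    )


def standardize(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """(x - mu)/sigma over a 1-D vector; raises on empty or constant input."""
    values = np.asarray(values, dtype=float)
    if not values.size:
        raise DegenerateTrackError("no included bins")
    mu = float(values.mean())
    sigma = float(values.std(ddof=0))
    if sigma == 0.0:
        raise DegenerateTrackError("constant log2 ratio track (sigma = 0)")
    return (values - mu) / sigma, mu, sigma


def zscore_track(
    track: BinnedTrack,
    index: GenomeIndex,
    pseudocount: float = 1.0,
) -> BinnedTrack:
    """Observed/expected log2 ratio standardized by the genome-wide mean/sd.

    ``track`` must be a raw tiled count track.  The expected count per bin
    distributes the track's total contacts uniformly over GATC sites:
    expected = total * sites_in_bin / total_sites.  Bins without sites are
    excluded.  z = (log2((obs+pc)/(exp+pc)) - mu) / sigma with mu, sigma over
    all included bins; a constant ratio track raises DegenerateTrackError.
    """
    if track.normalization != "raw":
        raise ValueError("zscore_track expects a raw count track")
    if track.step != track.bin_size:
        raise ValueError("zscore_track expects a tiled track")
    total_sites = index.total_sites(track.chroms)
    if total_sites == 0:
        raise DegenerateTrackError("no restriction sites on track chromosomes")
    total = float(sum(np.nansum(track.values[c]) for c in track.chroms))
    ratios: dict[str, np.ndarray] = {}
    mask: dict[str, np.ndarray] = {}
    pooled = []
    for chrom in track.chroms:
        length = index.chrom_lengths[chrom]
        site_counts = _windowed_site_counts(
            index.sites[chrom], length, track.bin_size, track.step
        )
        included = (site_counts > 0) & track.mask[chrom]
        expected = total * site_counts / total_sites
        obs = track.values[chrom]
        vec = np.full(obs.shape, np.nan)
        vec[included] = np.log2(
            (obs[included] + pseudocount) / (expected[included] + pseudocount)
        )
        ratios[chrom] = vec
        mask[chrom] = included
        pooled.append(vec[included])
    pooled_arr = np.concatenate(pooled) if pooled else np.empty(0)
    _, mu, sigma = standardize(pooled_arr)
    values = {c: (ratios[c] - mu) / sigma for c in ratios}
    return BinnedTrack(
        bin_size=track.bin_size,
        step=track.step,
        values=values,
        mask=mask,
        normalization="zscore",
        meta={**track.meta, "mu": mu, "sigma": sigma, "pseudocount": pseudocount},
    )


def metaprofile(
    track: BinnedTrack,
    regions: Sequence[tuple],
    flank: int = 2000,
    n_bins: int = 50,
    flank_bins: Optional[int] = None,
    random_regions: Optional[Sequence[tuple]] = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> dict:
    """Length-scaled mean signal profile over regions, with fixed flanks.

    Each region body is rescaled into ``n_bins`` meta-bins and flanked by
    ``flank`` bp sampled into ``flank_bins`` meta-bins on each side; the
    profile is the across-region mean (NaN-aware).  When ``random_regions``
    are supplied the profile is additionally divided by the mean of the
    random-region profile (fold-change normalization).  Regions reaching past
    chromosome ends are clipped and counted.
    """
    if not regions:
        raise ValueError("regions must be non-empty")
    if flank_bins is None:
        flank_bins = max(1, n_bins // 2)

    def profile_of(region_list: Sequence[tuple]) -> tuple[np.ndarray, int]:
        width = 2 * flank_bins + n_bins
        acc = np.zeros(width)
        cnt = np.zeros(width)
        clipped = 0
        for region in region_list:
            chrom, start, end = region[0], int(region[1]), int(region[2])
            strand = region[3] if len(region) > 3 else "+"
            if chrom not in track.values:
                continue
            body = start + (np.arange(n_bins) + 0.5) / n_bins * (end - start)
            left = start - flank + (np.arange(flank_bins) + 0.5) * flank / flank_bins
            right = end + (np.arange(flank_bins) + 0.5) * flank / flank_bins
            positions = np.concatenate([left, body, right])
            if strand == "-":
                positions = positions[::-1]
            length = (
                chrom_lengths[chrom]
                if chrom_lengths is not None
                else track.values[chrom].size * track.step
            )
            if positions.min() < 0 or positions.max() >= length:
                clipped += 1
            for i, pos in enumerate(positions):
                if pos < 0 or pos >= length:
                    continue
                value = track.value_at(chrom, int(pos))
                if not math.isnan(value):
                    acc[i] += value
                    cnt[i] += 1
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan), clipped

    profile, clipped = profile_of(regions)
    result = {"profile": profile, "n_regions": len(regions), "n_clipped": clipped}
    if random_regions:
        random_profile, _ = profile_of(random_regions)
        baseline = float(np.nanmean(random_profile))
        result["random_profile"] = random_profile
        result["normalized"] = profile / baseline if baseline else profile * np.nan
    return result


def shift_atac_insertions(
    fragments: Iterable[tuple[str, int, int, str]]
) -> list[tuple[str, int]]:
    """Transposase insertion sites from stranded fragments.

    The 5' end (start on '+', end-1 on '-') is shifted +4 bp on the plus
    strand and -5 bp on the minus strand.  Unstranded records are an error.
    """
    out = []
    for chrom, start, end, strand in fragments:
        if strand == "+":
            out.append((chrom, start + 4))
        elif strand == "-":
            out.append((chrom, (end - 1) - 5))
        else:
            raise ValueError(f"unstranded fragment {chrom}:{start}-{end}")
    return out


def write_bedgraph(track: BinnedTrack, path) -> None:
    """Write included bins as bedGraph; excluded bins are omitted entirely."""
    with open(path, "w") as handle:
        for chrom in track.chroms:
            vec = track.values[chrom]
            included = track.mask[chrom]
            for i in np.flatnonzero(included):
                start = int(i) * track.step
                end = start + track.bin_size
                handle.write(f"{chrom}\t{start}\t{end}\t{vec[i]:.6g}\n")
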