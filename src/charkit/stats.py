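"""Enrichment, specificity, resolution, and domain-boundary statistics.

Implements the contact-level statistics used downstream of track building:
length/depth-normalized contact rates per RNA (CPKM), chromosome enrichment
with a one-tailed binomial test, signal-to-noise against randomly sampled
autosomal bins, cross-track resolution curves, the boundary-versus-midpoint
domain test with masked-length-matched subsampling, and the spike-in
false-positive estimator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .contacts import Contact, IntervalSet
from .tracks import BinnedTrack, GenomeIndex

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# binomial upper tail
# ---------------------------------------------------------------------------

def binom_sf_geq(k: int, n: int, q: float):
    """P[X >= k] for X ~ Binomial(n, q), computed stably.

    For n <= 2000 the tail is summed term-by-term in extended precision via
    the descending pmf recurrence (exact to ~n*eps relative); larger n falls
    back to the regularized incomplete beta function.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if k <= 0:
        return 1.0
    if k > n:
        return 0.0
    if n > 2000:
        return float(sps.binom.sf(k - 1, n, q))
    qld = np.longdouble(q)
    one_minus = np.longdouble(1.0) - qld
    pmf = qld ** n  # pmf at j = n
    total = np.longdouble(0.0)
    for j in range(n, k - 1, -1):
        total += pmf
        if j > k:
            pmf *= (np.longdouble(j) * one_minus) / (np.longdouble(n - j + 1) * qld)
    return min(total, np.longdouble(1.0))


def binom_sf_vector(n: int, q: float) -> np.ndarray:
    """P[X >= k] for k = 0..n as a longdouble vector (same recurrence as
    :func:`binom_sf_geq`, amortized over all k)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    qld = np.longdouble(q)
    one_minus = np.longdouble(1.0) - qld
    sf = np.empty(n + 1, dtype=np.longdouble)
    pmf = qld ** n
    total = np.longdouble(0.0)
    for j in range(n, 0, -1):
        total += pmf
        sf[j] = total
        pmf *= (np.longdouble(j) * one_minus) / (np.longdouble(n - j + 1) * qld)
    sf[0] = np.longdouble(1.0)
    return np.minimum(sf, np.longdouble(1.0))


# ---------------------------------------------------------------------------
# per-RNA contact summaries
# ---------------------------------------------------------------------------

def cpkm_table(
    contacts: Sequence[Contact],
    transcript_lengths: Mapping[str, int],
    total_contacts: Optional[int] = None,
    cpkm_floor: float = 10.0,
) -> pd.DataFrame:
    """Contacts per kilobase of transcript per million total contacts, per RNA.

    cpkm = count / (length/1000) / (total/1e6).  The denominator defaults to
    the size of the supplied (final filtered) contact set.  RNAs with no
    recorded length are skipped with a log message; RNAs below ``cpkm_floor``
    are flagged rather than dropped.
    """
    total = len(contacts) if total_contacts is None else total_contacts
    if total <= 0:
        raise ValueError("total_contacts must be positive")
    counts: dict[str, int] = {}
    for contact in contacts:
        counts[contact.gene_id] = counts.get(contact.gene_id, 0) + 1
    rows = []
    for gene_id in sorted(set(counts) | set(transcript_lengths)):
        length = transcript_lengths.get(gene_id)
        if length is None:
            logger.warning("no transcript length for %s; skipped", gene_id)
            continue
        if length <= 0:
            raise ValueError(f"{gene_id}: transcript length must be positive")
        count = counts.get(gene_id, 0)
        cpkm = count / (length / 1000.0) / (total / 1e6)
        rows.append(
            {
                "gene_id": gene_id,
                "contact_count": count,
                "transcript_length": length,
                "cpkm": cpkm,
                "below_floor": cpkm < cpkm_floor,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["gene_id", "contact_count", "transcript_length", "cpkm", "below_floor"],
    )
    frame.attrs["total_contacts"] = total
    frame.attrs["cpkm_floor"] = cpkm_floor
    return frame


def select_enriched(
    summaries: pd.DataFrame,
    expression: Mapping[str, float],
    cpkm_floor: float = 100.0,
    fold_floor: float = 10.0,
    pseudocount: float = 0.1,
) -> pd.DataFrame:
    """Select RNAs by CPKM and fold-enrichment over expression (strict >).

    Expression values are median-scaled onto the CPKM scale (the cross-unit
    normalization is otherwise arbitrary), then
    fold_enrichment = (cpkm + pc) / (scaled_expression + pc).  An RNA is
    selected when cpkm > cpkm_floor and fold_enrichment > fold_floor.
    """
    frame = summaries.copy()
    frame["expression"] = frame["gene_id"].map(expression).astype(float)
    if frame["expression"].isna().any():
        missing = frame.loc[frame["expression"].isna(), "gene_id"].tolist()
        raise ValueError(f"missing expression for {missing[:5]}{'...' if len(missing) > 5 else ''}")
    pos_cpkm = frame.loc[frame["cpkm"] > 0, "cpkm"]
    pos_expr = frame.loc[frame["expression"] > 0, "expression"]
    scale = 1.0
    if len(pos_cpkm) and len(pos_expr) and pos_expr.median() > 0:
        scale = pos_cpkm.median() / pos_expr.median()
    frame["expression_scaled"] = frame["expression"] * scale
    frame["fold_enrichment"] = (frame["cpkm"] + pseudocount) / (
        frame["expression_scaled"] + pseudocount
    )
    frame["selected"] = (frame["cpkm"] > cpkm_floor) & (frame["fold_enrichment"] > fold_floor)
    frame.attrs["expression_scale"] = scale
    frame.attrs["pseudocount"] = pseudocount
    return frame


# ---------------------------------------------------------------------------
# chromosome enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    fold: float
    p_value: float
    n_total: int
    n_target: int
    expected_fraction: float

    def as_dict(self) -> dict:
        return {
            "fold": self.fold,
            "p_value": float(self.p_value),
            "n_total": self.n_total,
            "n_target": self.n_target,
            "expected_fraction": self.expected_fraction,
        }


def chrom_enrichment(
    contacts: Sequence[Contact],
    target_chrom: str,
    index: GenomeIndex,
    chroms: Optional[Sequence[str]] = None,
) -> EnrichmentResult:
    """Enrichment of one RNA's contacts on a target chromosome.

    The expected fraction is the target's share of total chromosomal
    sequence; the p-value is the one-tailed upper binomial tail
    P[X >= n_target] under random placement.
    """
    chroms = index.chroms if chroms is None else list(chroms)
    if target_chrom not in chroms or target_chrom not in index.chrom_lengths:
        raise ValueError(f"target chromosome {target_chrom!r} not in index")
    n_total = len(contacts)
    if n_total == 0:
        raise ValueError("no contacts")
    expected = index.chrom_lengths[target_chrom] / index.genome_length(chroms)
    n_target = sum(1 for c in contacts if c.chrom == target_chrom)
    fold = (n_target / n_total) / expected
    p = binom_sf_geq(n_target, n_total, expected) if n_target > 0 else 1.0
    return EnrichmentResult(
        fold=fold,
        p_value=p,
        n_total=n_total,
        n_target=n_target,
        expected_fraction=expected,
    )


# ---------------------------------------------------------------------------
# signal-to-noise
# ---------------------------------------------------------------------------

@dataclass
class SNRResult:
    signal_mean: float
    noise_mean: float
    snr: float
    n_bins: int
    seed: int


def snr(
    track: BinnedTrack,
    x_chrom: str = "chrX",
    autosomes: Sequence[str] = (),
    n_bins: int = 300,
    seed: int = 0,
) -> SNRResult:
    """Top-bin signal on the target chromosome over random autosomal noise.

    Signal is the mean of the ``n_bins`` included bins with the highest
    values on ``x_chrom`` (ties at the cutoff broken by coordinate order);
    noise is the mean of ``n_bins`` bins sampled uniformly without
    replacement (seeded) from included autosomal bins.  Chromosome/locus
    exclusions are applied by the caller via the track mask and the
    ``autosomes`` list.
    """
    x_values = track.values.get(x_chrom)
    if x_values is None:
        raise ValueError(f"{x_chrom!r} not in track")
    x_included = x_values[track.mask[x_chrom]]
    pool = track.included(autosomes)
    if x_included.size < n_bins or pool.size < n_bins:
        raise ValueError(
            f"need >= {n_bins} included bins on {x_chrom} and autosomes "
            f"(have {x_included.size} / {pool.size})"
        )
    # stable sort by descending value keeps coordinate order among ties
    order = np.argsort(-x_included, kind="stable")
    signal = float(x_included[order[:n_bins]].mean())
    rng = np.random.default_rng(seed)
    noise_bins = pool[rng.choice(pool.size, size=n_bins, replace=False)]
    noise = float(noise_bins.mean())
    if noise == 0.0:
        raise ValueError("degenerate noise estimate (mean 0)")
    return SNRResult(
        signal_mean=signal, noise_mean=noise, snr=signal / noise, n_bins=n_bins, seed=seed
    )


# ---------------------------------------------------------------------------
# resolution curve
# ---------------------------------------------------------------------------

def resolution_curve(
    track_a: BinnedTrack,
    track_b: BinnedTrack,
    windows: Sequence[int],
) -> list[tuple[int, float]]:
    """Spearman correlation between two tracks re-binned at each window size.

    Both tracks must share the base bin size, chromosomes and inclusion
    mask (identical upstream filtering).  For each window the base bins are
    summed in groups of window/base and the rank correlation computed over
    coarse bins containing at least one included base bin; windows with
    fewer than three usable bins are skipped with a log message.
    """
    if track_a.bin_size != track_b.bin_size or track_a.step != track_a.bin_size:
        raise ValueError("tracks must be tiled at the same base bin size")
    if list(track_a.chroms) != list(track_b.chroms):
        raise ValueError("tracks must cover the same chromosomes")
    base = track_a.bin_size
    curve = []
    for window in windows:
        factor = max(1, int(round(window / base)))
        pooled_a, pooled_b = [], []
        for chrom in track_a.chroms:
            mask = track_a.mask[chrom] & track_b.mask[chrom]
            a = np.where(mask, np.nan_to_num(track_a.values[chrom]), 0.0)
            b = np.where(mask, np.nan_to_num(track_b.values[chrom]), 0.0)
            n = a.size
            n_coarse = -(-n // factor)
            pad = n_coarse * factor - n
            if pad:
                a = np.concatenate([a, np.zeros(pad)])
                b = np.concatenate([b, np.zeros(pad)])
                mask = np.concatenate([mask, np.zeros(pad, dtype=bool)])
            coarse_mask = mask.reshape(n_coarse, factor).any(axis=1)
            pooled_a.append(a.reshape(n_coarse, factor).sum(axis=1)[coarse_mask])
            pooled_b.append(b.reshape(n_coarse, factor).sum(axis=1)[coarse_mask])
        a_all = np.concatenate(pooled_a)
        b_all = np.concatenate(pooled_b)
        if a_all.size < 3:
            logger.warning("window %d: fewer than 3 shared bins; skipped", window)
            continue
        rho = float(sps.spearmanr(a_all, b_all).statistic)
        curve.append((int(window), rho))
    return curve


# ---------------------------------------------------------------------------
# domain-boundary enrichment test
# ---------------------------------------------------------------------------

@dataclass
class BoundaryTestResult:
    fold: float
    statistic: float
    p_value: float
    n_boundary: int
    n_midpoint: int
    match_p: float
    seed: int

    def as_dict(self) -> dict:
        return {
            "fold": self.fold,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_boundary": self.n_boundary,
            "n_midpoint": self.n_midpoint,
            "match_p": self.match_p,
            "seed": self.seed,
        }


def _mask_length_bins() -> np.ndarray:
    # 50 bp strata up to 1 kb, 500 bp strata up to the full 20 kb region
    return np.concatenate([np.arange(0, 1000, 50), np.arange(1000, 20001, 500)])


def tad_boundary_test(
    contacts: Sequence[Contact],
    tads: Sequence[tuple[str, int, int]],
    index: GenomeIndex,
    masks: Optional[IntervalSet] = None,
    blacklist: Optional[IntervalSet] = None,
    parent_locus: Optional[tuple[str, int, int]] = None,
    region_half: int = 10_000,
    cis_pad: int = 2_000,
    chroms: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> BoundaryTestResult:
    """Contact enrichment at domain boundaries versus domain midpoints.

    Boundary regions are +/- ``region_half`` around each domain edge;
    midpoint regions are +/- ``region_half`` around the domain midpoint
    rounded down to a ``region_half`` multiple.  Regions overlapping the
    blacklist are removed; contacts within the RNA's parent locus +/-
    ``cis_pad`` are excluded as cis.  Per-region counts are normalized by
    GATC sites.  Regions are stratified by masked bp (50-bp strata to 1 kb,
    500-bp strata to 20 kb) and each stratum subsampled to the smaller class
    count (seeded); the test is a one-sided Wilcoxon rank-sum
    (boundary > midpoint) and fold is mean(boundary)/mean(midpoint).
    ``match_p`` is the two-sided Wilcoxon p for matched masked lengths.
    """
    tad_list = [t for t in tads if chroms is None or t[0] in chroms]
    if not tad_list:
        raise ValueError("no domains on the requested chromosomes")
    boundary_regions: list[tuple[str, int, int]] = []
    seen_edges: set[tuple[str, int]] = set()
    for chrom, start, end in tad_list:
        for edge in (start, end):
            if (chrom, edge) in seen_edges:
                continue
            seen_edges.add((chrom, edge))
            boundary_regions.append((chrom, edge - region_half, edge + region_half))
    midpoint_regions = []
    for chrom, start, end in tad_list:
        mid = ((start + end) // 2 // region_half) * region_half
        midpoint_regions.append((chrom, mid - region_half, mid + region_half))

    def usable(regions):
        out = []
        for chrom, start, end in regions:
            if start < 0 or end > index.chrom_lengths.get(chrom, 0):
                continue
            if blacklist is not None and blacklist.overlaps(chrom, start, end):
                continue
            if index.sites_in(chrom, start, end) == 0:
                continue
            out.append((chrom, start, end))
        return out

    boundary_regions = usable(boundary_regions)
    midpoint_regions = usable(midpoint_regions)
    if not boundary_regions or not midpoint_regions:
        raise ValueError("no usable regions after filtering")

    mids_by_chrom: dict[str, np.ndarray] = {}
    kept_contacts: list[Contact] = []
    for contact in contacts:
        if parent_locus is not None:
            p_chrom, p_start, p_end = parent_locus
            if (
                contact.chrom == p_chrom
                and contact.midpoint >= p_start - cis_pad
                and contact.midpoint < p_end + cis_pad
            ):
                continue
        kept_contacts.append(contact)
    for contact in kept_contacts:
        mids_by_chrom.setdefault(contact.chrom, [])
        mids_by_chrom[contact.chrom].append(contact.midpoint)
    mids_by_chrom = {c: np.sort(np.asarray(v)) for c, v in mids_by_chrom.items()}

    def region_stats(regions):
        density = np.empty(len(regions))
        masked = np.empty(len(regions))
        for i, (chrom, start, end) in enumerate(regions):
            mids = mids_by_chrom.get(chrom)
            count = 0
            if mids is not None and mids.size:
                count = int(np.searchsorted(mids, end) - np.searchsorted(mids, start))
            density[i] = count / index.sites_in(chrom, start, end)
            masked[i] = masks.overlap_bp(chrom, start, end) if masks is not None else 0
        return density, masked

    b_density, b_masked = region_stats(boundary_regions)
    m_density, m_masked = region_stats(midpoint_regions)

    rng = np.random.default_rng(seed)
    edges = _mask_length_bins()
    b_strata = np.digitize(b_masked, edges)
    m_strata = np.digitize(m_masked, edges)
    b_pick: list[int] = []
    m_pick: list[int] = []
    for stratum in np.union1d(b_strata, m_strata):
        b_idx = np.flatnonzero(b_strata == stratum)
        m_idx = np.flatnonzero(m_strata == stratum)
        n = min(b_idx.size, m_idx.size)
        if n == 0:
            continue
        b_pick.extend(rng.choice(b_idx, size=n, replace=False))
        m_pick.extend(rng.choice(m_idx, size=n, replace=False))
    if not b_pick:
        raise ValueError("masked-length matching left no regions")
    b_sel = b_density[np.asarray(sorted(b_pick))]
    m_sel = m_density[np.asarray(sorted(m_pick))]
    test = sps.mannwhitneyu(b_sel, m_sel, alternative="greater", method="auto")
    match = sps.mannwhitneyu(
        b_masked[np.asarray(sorted(b_pick))],
        m_masked[np.asarray(sorted(m_pick))],
        alternative="two-sided",
        method="auto",
    )
    m_mean = float(m_sel.mean())
    fold = float(b_sel.mean()) / m_mean if m_mean else float("inf")
    return BoundaryTestResult(
        fold=fold,
        statistic=float(test.statistic),
        p_value=float(test.pvalue),
        n_boundary=len(b_sel),
        n_midpoint=len(m_sel),
        match_p=float(match.pvalue),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# spike-in false-positive rate
# ---------------------------------------------------------------------------

@dataclass
class SpikeInResult:
    fraction: float
    ci_low: float
    ci_high: float
    n_spike: int
    n_total: int


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k/n."""
    low = 0.0 if k == 0 else float(sps.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(sps.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def spike_in_fp_rate(
    contacts: Sequence[Contact], spike_gene_ids: Iterable[str]
) -> SpikeInResult:
    """Fraction of contacts attributed to spike-in transcripts, with 95% CI."""
    if not contacts:
        raise ValueError("no contacts")
    spikes = set(spike_gene_ids)
    k = sum(1 for c in contacts if c.gene_id in spikes)
    n = len(contacts)
    low, high = clopper_pearson(k, n)
    return SpikeInResult(fraction=k / n, ci_low=low, ci_high=high, n_spike=k, n_total=n)
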