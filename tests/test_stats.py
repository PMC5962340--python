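"""Tests for enrichment, SNR, resolution, boundary and spike-in statistics."""

import math
from fractions import Fraction

import numpy as np
import pytest

from charkit import stats as ckstats
from charkit.contacts import Contact, IntervalSet
from charkit.simulate import simulate_boundary_contacts
from charkit.tracks import BinnedTrack, GenomeIndex, coverage_track


def contact(read_id, chrom="chr2L", start=1000, gene="g1", sense=True):
    return Contact(read_id=read_id, gene_id=gene, rna_category="ncRNA", sense=sense,
                   chrom=chrom, start=start, end=start + 50)


# ---------------------------------------------------------------------------
# exact binomial oracle (integer arithmetic; independent of scipy/longdouble)
# ---------------------------------------------------------------------------

def exact_binom_tail(k, n, q_num, q_den):
    """P[X >= k] as an exact Fraction for q = q_num/q_den."""
    a, b, d = q_num, q_den - q_num, q_den
    num = sum(math.comb(n, j) * a**j * b ** (n - j) for j in range(k, n + 1))
    return Fraction(num, d**n)


def frac_to_longdouble(frac):
    num, den = frac.numerator, frac.denominator
    if num == 0:
        return np.longdouble(0.0)
    shift = 64 - (num.bit_length() - den.bit_length())
    if shift > 0:
        quotient = (num << shift) // den
    else:
        quotient = num // (den << -shift)
    return np.longdouble(quotient) * np.longdouble(2.0) ** np.longdouble(-shift)


class TestBinomTail:
    def test_degenerate_cases(self):
        assert ckstats.binom_sf_geq(0, 10, 0.2) == 1.0
        assert ckstats.binom_sf_geq(11, 10, 0.2) == 0.0

    def test_spec_worked_example(self):
        p = ckstats.binom_sf_geq(80, 100, 0.2)
        exact = exact_binom_tail(80, 100, 1, 5)
        assert float(p) == pytest.approx(float(exact), rel=1e-12)

    @pytest.mark.parametrize("n", [1, 2, 5, 17, 100, 250, 1000])
    @pytest.mark.parametrize("q_num,q_den", [(1, 10), (1, 5), (1, 2)])
    def test_exact_oracle_grid(self, n, q_num, q_den):
        q = q_num / q_den
        for k in sorted({1, n // 4, n // 2, (3 * n) // 4, n}):
            if k < 1:
                continue
            p = np.longdouble(ckstats.binom_sf_geq(k, n, q))
            exact = frac_to_longdouble(exact_binom_tail(k, n, q_num, q_den))
            assert abs(p / exact - 1) < 1e-12

    def test_large_n_path(self):
        # falls back to the beta-function tail; sanity against scipy directly
        from scipy import stats as sps

        p = ckstats.binom_sf_geq(600, 5000, 0.1)
        assert p == pytest.approx(float(sps.binom.sf(599, 5000, 0.1)), rel=1e-12)


# ---------------------------------------------------------------------------
# CPKM and enrichment selection
# ---------------------------------------------------------------------------

class TestCpkm:
    def test_zero_contacts(self):
        table = ckstats.cpkm_table([], {"g1": 1000}, total_contacts=100)
        assert table.loc[0, "cpkm"] == 0.0

    def test_arithmetic(self):
        contacts = [contact(f"r{i}", gene="g1") for i in range(500)]
        table = ckstats.cpkm_table(contacts, {"g1": 2000}, total_contacts=10_000_000)
        assert table.loc[0, "cpkm"] == pytest.approx(25.0)

    def test_missing_length_skipped(self, caplog):
        contacts = [contact("r1", gene="gMissing")]
        table = ckstats.cpkm_table(contacts, {"gOther": 500})
        assert "gMissing" not in set(table["gene_id"])

    def test_floor_flag_matches_recount(self, rng):
        genes = [f"g{i}" for i in range(50)]
        lengths = {g: int(rng.integers(300, 3000)) for g in genes}
        contacts = []
        for i in range(3000):
            contacts.append(contact(f"r{i}", gene=genes[rng.integers(0, 50)]))
        table = ckstats.cpkm_table(contacts, lengths)
        total = len(contacts)
        for row in table.itertuples():
            cpkm = row.contact_count / (lengths[row.gene_id] / 1000) / (total / 1e6)
            assert row.below_floor == (cpkm < 10.0)
        below = (table["cpkm"] < 10.0).sum()
        assert table["below_floor"].sum() == below


class TestSelectEnriched:
    def _table(self, rows):
        import pandas as pd

        return pd.DataFrame(rows)

    def test_boundary_cpkm_not_selected(self):
        table = self._table([
            {"gene_id": "g1", "contact_count": 1, "transcript_length": 1000, "cpkm": 100.0},
        ])
        out = ckstats.select_enriched(table, {"g1": 0.0001})
        assert not out.loc[0, "selected"]  # strict >

    def test_clear_selection(self):
        table = self._table([
            {"gene_id": "g1", "contact_count": 1, "transcript_length": 1000, "cpkm": 200.0},
            {"gene_id": "g2", "contact_count": 1, "transcript_length": 1000, "cpkm": 200.0},
        ])
        out = ckstats.select_enriched(table, {"g1": 0.01, "g2": 200.0})
        assert bool(out.loc[0, "selected"]) and not bool(out.loc[1, "selected"])

    def test_planted_mixture_fully_recovered(self, rng):
        """10 planted chromatin-enriched RNAs among 200; exact recovery."""
        genes = [f"g{i:03d}" for i in range(200)]
        planted = set(genes[:10])
        expression = {g: float(np.exp(rng.normal(3.0, 1.0))) for g in genes}
        contacts = []
        i = 0
        for g in genes:
            rate = expression[g] * (100.0 if g in planted else 1.0)
            for _ in range(int(rng.poisson(rate))):
                contacts.append(contact(f"r{i}", gene=g))
                i += 1
        lengths = {g: 1000 for g in genes}
        table = ckstats.cpkm_table(contacts, lengths)
        out = ckstats.select_enriched(table, expression)
        selected = set(out.loc[out["selected"], "gene_id"])
        assert selected == planted

    def test_missing_expression_rejected(self):
        table = self._table([
            {"gene_id": "g1", "contact_count": 0, "transcript_length": 1000, "cpkm": 0.0},
        ])
        with pytest.raises(ValueError):
            ckstats.select_enriched(table, {})


# ---------------------------------------------------------------------------
# chromosome enrichment
# ---------------------------------------------------------------------------

def simple_index(lengths):
    return GenomeIndex(chrom_lengths=dict(lengths))


class TestChromEnrichment:
    def test_uniform_fold_one(self):
        index = simple_index({"chrX": 200, "chr2L": 800})
        contacts = [contact(f"r{i}", chrom="chrX", start=10) for i in range(20)]
        contacts += [contact(f"r{i + 20}", chrom="chr2L", start=10) for i in range(80)]
        result = ckstats.chrom_enrichment(contacts, "chrX", index)
        assert result.fold == pytest.approx(1.0)

    def test_worked_example_fold_and_p(self):
        index = simple_index({"chrX": 200, "chr2L": 800})
        contacts = [contact(f"r{i}", chrom="chrX", start=10) for i in range(80)]
        contacts += [contact(f"r{i + 80}", chrom="chr2L", start=10) for i in range(20)]
        result = ckstats.chrom_enrichment(contacts, "chrX", index)
        assert result.fold == pytest.approx(4.0)
        exact = exact_binom_tail(80, 100, 1, 5)
        assert float(result.p_value) == pytest.approx(float(exact), rel=1e-12)

    def test_zero_target_degenerate(self):
        index = simple_index({"chrX": 200, "chr2L": 800})
        contacts = [contact(f"r{i}", chrom="chr2L", start=10) for i in range(10)]
        result = ckstats.chrom_enrichment(contacts, "chrX", index)
        assert result.fold == 0.0 and result.p_value == 1.0

    def test_missing_chrom_rejected(self):
        index = simple_index({"chr2L": 800})
        with pytest.raises(ValueError):
            ckstats.chrom_enrichment([contact("r1")], "chrX", index)


# ---------------------------------------------------------------------------
# SNR
# ---------------------------------------------------------------------------

def make_track(per_chrom_values):
    return BinnedTrack(
        bin_size=2000, step=2000,
        values={c: np.asarray(v, dtype=float) for c, v in per_chrom_values.items()},
        mask={c: ~np.isnan(np.asarray(v, dtype=float)) for c, v in per_chrom_values.items()},
        normalization="dpnii",
    )


def snr_oracle(track, x_chrom, autosomes, n_bins, seed):
    """Quadratic top-k selection + seeded noise mean."""
    x_vals = list(track.values[x_chrom][track.mask[x_chrom]])
    chosen = []
    remaining = list(enumerate(x_vals))
    for _ in range(n_bins):
        best_idx = 0
        for j in range(1, len(remaining)):
            if remaining[j][1] > remaining[best_idx][1]:
                best_idx = j  # strictly greater keeps earlier coord on ties
        chosen.append(remaining.pop(best_idx)[1])
    signal = sum(chosen) / n_bins
    pool = np.concatenate([track.values[c][track.mask[c]] for c in autosomes])
    rng = np.random.default_rng(seed)
    noise = pool[rng.choice(pool.size, size=n_bins, replace=False)].mean()
    return signal / noise


class TestSnr:
    def test_uniform_track_snr_one(self):
        track = make_track({"chrX": np.full(500, 3.0), "chr2L": np.full(500, 3.0)})
        for seed in (0, 7, 123):
            result = ckstats.snr(track, autosomes=["chr2L"], seed=seed)
            assert result.snr == pytest.approx(1.0)

    def test_constructed_five_fold(self, rng):
        x = np.full(2000, 1.0)
        top = rng.choice(2000, size=300, replace=False)
        x[top] = 10.0
        track = make_track({"chrX": x, "chr2L": np.full(2000, 2.0)})
        result = ckstats.snr(track, autosomes=["chr2L"], seed=5)
        assert result.snr == pytest.approx(5.0)

    def test_quadratic_oracle_10k_bins(self, rng):
        x = rng.gamma(2.0, 2.0, size=5000)
        a = rng.gamma(2.0, 2.0, size=5000)
        track = make_track({"chrX": x, "chr2L": a})
        result = ckstats.snr(track, autosomes=["chr2L"], seed=11)
        assert result.snr == pytest.approx(
            snr_oracle(track, "chrX", ["chr2L"], 300, 11), rel=1e-12
        )

    def test_ties_broken_by_coordinate_order(self):
        x = np.zeros(600)
        x[100:500] = 7.0  # 400 tied bins; first 300 in coordinate order win
        track = make_track({"chrX": x, "chr2L": np.full(600, 1.0)})
        result = ckstats.snr(track, autosomes=["chr2L"], seed=0)
        assert result.signal_mean == pytest.approx(7.0)

    def test_insufficient_bins_rejected(self):
        track = make_track({"chrX": np.ones(100), "chr2L": np.ones(600)})
        with pytest.raises(ValueError):
            ckstats.snr(track, autosomes=["chr2L"])

    def test_zero_noise_rejected(self):
        track = make_track({"chrX": np.ones(600), "chr2L": np.zeros(600)})
        with pytest.raises(ValueError):
            ckstats.snr(track, autosomes=["chr2L"])


# ---------------------------------------------------------------------------
# resolution curve
# ---------------------------------------------------------------------------

def raw_track(values, bin_size=50):
    arr = np.asarray(values, dtype=float)
    return BinnedTrack(bin_size=bin_size, step=bin_size, values={"chr1": arr},
                       mask={"chr1": np.ones(arr.size, dtype=bool)},
                       normalization="raw")


class TestResolutionCurve:
    def test_identical_tracks_rho_one(self, rng):
        track = raw_track(rng.poisson(5, size=4000))
        curve = ckstats.resolution_curve(track, track, [50, 200, 1000, 5000])
        assert all(rho == pytest.approx(1.0) for _, rho in curve)

    def test_anti_ranked_rho_minus_one(self):
        a = raw_track([1, 2, 3, 4, 5, 6])
        b = raw_track([6, 5, 4, 3, 2, 1])
        curve = ckstats.resolution_curve(a, b, [50])
        assert curve == [(50, pytest.approx(-1.0))]

    def test_symmetry(self, rng):
        a = raw_track(rng.poisson(5, size=2000))
        b = raw_track(rng.poisson(5, size=2000))
        ab = ckstats.resolution_curve(a, b, [50, 500, 2500])
        ba = ckstats.resolution_curve(b, a, [50, 500, 2500])
        assert [w for w, _ in ab] == [w for w, _ in ba]
        assert [r for _, r in ab] == pytest.approx([r for _, r in ba], abs=1e-12)

    def test_nested_noise_non_decreasing(self):
        rng = np.random.default_rng(20)
        n = 40_000
        smooth = np.convolve(rng.normal(0, 1, n), np.ones(400) / 400, mode="same")
        lam = np.exp(smooth * 3.0) * 5.0
        a = raw_track(rng.poisson(lam))
        b = raw_track(rng.poisson(lam))
        windows = [50, 100, 250, 500, 1000, 2500, 5000, 10_000]
        curve = ckstats.resolution_curve(a, b, windows)
        rhos = [rho for _, rho in curve]
        assert all(b >= a for a, b in zip(rhos, rhos[1:]))
        assert rhos[-1] > rhos[0]

    def test_too_few_bins_skipped(self):
        a = raw_track([1, 2, 3, 4])
        b = raw_track([1, 2, 3, 4])
        curve = ckstats.resolution_curve(a, b, [200])  # one coarse bin -> skipped
        assert curve == []


# ---------------------------------------------------------------------------
# domain boundary test
# ---------------------------------------------------------------------------

class TestTadBoundaryTest:
    LENGTHS = {"chr1": 10_000_000, "chr2": 10_000_000}

    def _tads(self, n_per_chrom, size=50_000):
        tads = []
        for chrom in self.LENGTHS:
            for i in range(n_per_chrom):
                tads.append((chrom, i * size, (i + 1) * size))
        return tads

    def test_null_calibrated(self):
        tads = self._tads(100)
        contacts, index = simulate_boundary_contacts(
            self.LENGTHS, tads, n_contacts=30_000, factor=1.0, seed=3
        )
        result = ckstats.tad_boundary_test(contacts, tads, index, seed=3)
        assert result.p_value >= 0.05
        assert 0.9 <= result.fold <= 1.1

    def test_planted_two_fold(self):
        tads = self._tads(250)  # 500 domains total
        contacts, index = simulate_boundary_contacts(
            self.LENGTHS, tads, n_contacts=120_000, factor=2.0, seed=4
        )
        result = ckstats.tad_boundary_test(contacts, tads, index, seed=4)
        assert 1.8 <= result.fold <= 2.2
        assert result.p_value < 0.01

    def test_seed_reproducibility(self):
        tads = self._tads(50)
        contacts, index = simulate_boundary_contacts(
            self.LENGTHS, tads, n_contacts=10_000, factor=1.5, seed=5
        )
        r1 = ckstats.tad_boundary_test(contacts, tads, index, seed=9)
        r2 = ckstats.tad_boundary_test(contacts, tads, index, seed=9)
        assert r1 == r2

    def test_masked_length_matching(self, rng):
        tads = self._tads(100)
        contacts, index = simulate_boundary_contacts(
            self.LENGTHS, tads, n_contacts=30_000, factor=1.0, seed=6
        )
        masks = IntervalSet(
            "repeats",
            [("chr1", int(s), int(s) + int(rng.integers(50, 2000)))
             for s in rng.integers(0, 9_900_000, size=400)]
            + [("chr2", int(s), int(s) + int(rng.integers(50, 2000)))
               for s in rng.integers(0, 9_900_000, size=400)],
        )
        result = ckstats.tad_boundary_test(contacts, tads, index, masks=masks, seed=6)
        assert result.match_p > 0.05
        assert result.n_boundary == result.n_midpoint

    def test_cis_exclusion_removes_parent_contacts(self):
        tads = self._tads(20)
        contacts, index = simulate_boundary_contacts(
            self.LENGTHS, tads, n_contacts=5000, factor=1.0, seed=7
        )
        locus = ("chr1", 0, 500_000)
        with_cis = ckstats.tad_boundary_test(contacts, tads, index, seed=1)
        without = ckstats.tad_boundary_test(contacts, tads, index,
                                            parent_locus=locus, seed=1)
        assert isinstance(without.fold, float)
        assert with_cis != without

    def test_no_tads_rejected(self):
        contacts, index = simulate_boundary_contacts(
            self.LENGTHS, self._tads(10), n_contacts=100, factor=1.0, seed=8
        )
        with pytest.raises(ValueError):
            ckstats.tad_boundary_test(contacts, [], index)


# ---------------------------------------------------------------------------
# spike-in estimator
# ---------------------------------------------------------------------------

class TestSpikeIn:
    def test_no_spikes(self):
        contacts = [contact(f"r{i}") for i in range(100)]
        result = ckstats.spike_in_fp_rate(contacts, {"spike01"})
        assert result.fraction == 0.0 and result.ci_low == 0.0

    def test_arithmetic(self):
        contacts = [contact(f"r{i}", gene="spike01" if i < 10 else "g1")
                    for i in range(5000)]
        result = ckstats.spike_in_fp_rate(contacts, {"spike01"})
        assert result.fraction == pytest.approx(0.002)
        assert result.ci_low < 0.002 < result.ci_high

    def test_ci_covers_configured_leak(self):
        leak = 0.003
        n = 100_000
        k = np.random.default_rng(2).binomial(n, leak)
        contacts = [contact(f"r{i}", gene="spike01" if i < k else "g1")
                    for i in range(n)]
        result = ckstats.spike_in_fp_rate(contacts, {"spike01"})
        assert result.ci_low <= leak <= result.ci_high

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ckstats.spike_in_fp_rate([], {"s"})
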