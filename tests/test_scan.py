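"""SNP-index, Δ(SNP-index), ED, smoothing, thresholds and region calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bsamap.scan import (
    ScanConfig,
    call_regions,
    compute_scan_points,
    delta_regions,
    delta_snp_index,
    ed_threshold,
    euclidean_distance,
    filter_offspring_index,
    fit_ed,
    select_candidate_snps,
    smooth_delta,
    snp_index,
)
from bsamap.variant_io import BASES, ROLE_POOL_LONG, ROLE_POOL_SHORT

from helpers import (
    lowess_oracle,
    make_record,
    random_snp_record,
    region_oracle,
    snp_index_oracle,
    window_mean_oracle,
)


class TestSnpIndex:
    def test_direct_formula(self):
        # long pool: 30 reads of the mutant-parent allele, 10 of the other
        rec = make_record(ref="G", alt="A", POOL_LONG=(30, 0, 10, 0))
        assert snp_index(rec, ROLE_POOL_LONG, index_parent="mut") == pytest.approx(0.75)
        assert snp_index(rec, ROLE_POOL_LONG, index_parent="wt") == pytest.approx(0.25)

    def test_zero_numerator(self):
        rec = make_record(ref="G", alt="A", POOL_LONG=(0, 0, 25, 0))
        assert snp_index(rec, ROLE_POOL_LONG, index_parent="mut") == 0.0

    def test_undefined_when_no_parental_reads(self):
        rec = make_record(ref="G", alt="A", POOL_LONG=(0, 17, 0, 9))  # C/T only
        assert snp_index(rec, ROLE_POOL_LONG) is None

    def test_matches_read_by_read_oracle(self, rng):
        """1000 random depth quadruples equal a per-read tally (with the
        mutant allele taken from the wild-type parent's majority reads,
        exactly as the scan orients it)."""
        for _ in range(1000):
            rec = random_snp_record(rng)
            got = snp_index(rec, ROLE_POOL_LONG, index_parent="mut")
            wt_is_ref = rec.allele_depth("P_WT", "ref") >= rec.allele_depth("P_WT", "alt")
            m_base = rec.alt if wt_is_ref else rec.ref
            p_base = rec.ref if wt_is_ref else rec.alt
            want = snp_index_oracle(rec.quadruple(ROLE_POOL_LONG), m_base, p_base)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want)

    def test_delta_examples_and_antisymmetry(self, rng):
        rec = make_record(ref="G", alt="A", POOL_LONG=(40, 0, 0, 0), POOL_SHORT=(0, 0, 35, 0))
        assert delta_snp_index(rec, index_parent="mut") == pytest.approx(1.0)
        rec2 = make_record(ref="G", alt="A", POOL_LONG=(10, 0, 10, 0), POOL_SHORT=(20, 0, 20, 0))
        assert delta_snp_index(rec2) == pytest.approx(0.0)
        for _ in range(50):
            rec3 = random_snp_record(rng)
            d = delta_snp_index(rec3)
            if d is None:
                continue
            swapped = make_record(
                ref=rec3.ref, alt=rec3.alt,
                P_WT=tuple(rec3.base_depths["P_WT"]),
                P_MUT=tuple(rec3.base_depths["P_MUT"]),
                POOL_LONG=tuple(rec3.base_depths["POOL_SHORT"]),
                POOL_SHORT=tuple(rec3.base_depths["POOL_LONG"]),
            )
            assert delta_snp_index(swapped) == pytest.approx(-d)


class TestOffspringIndexFloor:
    def _pts(self, pairs):
        return pd.DataFrame(
            [("chr1", i + 1, aa, ab, aa - ab, 0.1, 0.5) for i, (aa, ab) in enumerate(pairs)],
            columns=["chrom", "pos", "index_aa", "index_ab", "delta", "ed", "maf_mut"],
        )

    def test_both_below_floor_removed(self):
        kept, removed = filter_offspring_index(self._pts([(0.2, 0.25)]), 0.30, "both")
        assert len(kept) == 0 and removed == 1

    def test_one_sided_extreme_retained(self):
        kept, removed = filter_offspring_index(self._pts([(0.2, 0.9)]), 0.30, "both")
        assert len(kept) == 1 and removed == 0

    def test_any_mode_stricter(self):
        kept, _ = filter_offspring_index(self._pts([(0.2, 0.9)]), 0.30, "any")
        assert len(kept) == 0

    def test_matches_brute_force_on_random_points(self, rng):
        pairs = [(rng.random(), rng.random()) for _ in range(1000)]
        pts = self._pts(pairs)
        kept, removed = filter_offspring_index(pts, 0.30, "both")
        want = [(aa, ab) for aa, ab in pairs if not (aa < 0.30 and ab < 0.30)]
        assert len(kept) == len(want) and removed == 1000 - len(want)
        assert list(zip(kept["index_aa"], kept["index_ab"])) == pytest.approx(want)


class TestEuclideanDistance:
    def test_maximal_divergence(self):
        assert euclidean_distance([1, 0, 0, 0], [0, 1, 0, 0]) == pytest.approx(math.sqrt(2))

    def test_identical_pools(self):
        assert euclidean_distance([0.25] * 4, [0.25] * 4) == 0.0

    def test_worked_example(self):
        got = euclidean_distance([0.75, 0, 0.25, 0], [0.25, 0, 0.75, 0])
        assert got == pytest.approx(math.sqrt(0.5))

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError):
            euclidean_distance([0.5, 0.2, 0, 0], [0.25] * 4)

    @settings(max_examples=200, deadline=None)
    @given(
        a=st.lists(st.floats(0.01, 1), min_size=4, max_size=4),
        b=st.lists(st.floats(0.01, 1), min_size=4, max_size=4),
    )
    def test_symmetry_and_bounds(self, a, b):
        fa = np.array(a) / np.sum(a)
        fb = np.array(b) / np.sum(b)
        d = euclidean_distance(fa, fb)
        assert d == pytest.approx(euclidean_distance(fb, fa))
        assert 0 <= d <= math.sqrt(2) + 1e-12

    def test_scan_point_invariants_on_random_records(self, rng):
        records = [random_snp_record(rng) for _ in range(300)]
        points, dropped = compute_scan_points(records)
        assert len(points) + dropped == len(records)
        assert points["index_aa"].between(0, 1).all()
        assert points["index_ab"].between(0, 1).all()
        assert points["delta"].between(-1, 1).all()
        assert points["ed"].between(0, math.sqrt(2) + 1e-12).all()
        assert np.allclose(points["delta"], points["index_aa"] - points["index_ab"])


class TestSmoothDelta:
    def _pts(self, positions, deltas, chrom="chr1"):
        return pd.DataFrame(
            {
                "chrom": chrom,
                "pos": positions,
                "index_aa": 0.5,
                "index_ab": 0.5,
                "delta": deltas,
                "ed": 0.1,
                "maf_mut": 0.5,
            }
        )

    def test_constant_delta_gives_constant_windows(self):
        pts = self._pts(range(1000, 900_000, 3000), 0.4)
        win = smooth_delta(pts, 500_000, 500_000, 3)
        assert np.allclose(win["mean_delta"].dropna(), 0.4)

    def test_two_marker_window_mean(self):
        pts = self._pts([1000, 2000, 600_000, 601_000, 602_000], [0.9, 1.0, 0.1, 0.1, 0.1])
        win = smooth_delta(pts, 500_000, 500_000, 2)
        assert win.loc[0, "mean_delta"] == pytest.approx(0.95)

    def test_window_boundaries_on_grid(self):
        pts = self._pts([1_200_000], [0.5])
        win = smooth_delta(pts, 500_000, 500_000, 1)
        starts = set(win["start"])
        assert starts <= {1, 500_001, 1_000_001}
        assert all(e - s == 500_000 for s, e in zip(win["start"], win["end"]))

    def test_sparse_windows_masked(self):
        pts = self._pts([1000, 2000], [0.9, 0.9])
        win = smooth_delta(pts, 500_000, 500_000, 3)
        assert win["mean_delta"].isna().all()

    def test_matches_brute_force_window_means(self, rng):
        positions = np.sort(rng.choice(np.arange(1, 2_000_000), 400, replace=False))
        deltas = rng.uniform(-1, 1, 400)
        pts = self._pts(positions, deltas)
        win = smooth_delta(pts, 500_000, 500_000, 1)
        for _, row in win.iterrows():
            n, mean = window_mean_oracle(positions, deltas, row["start"], 500_000)
            assert row["n_markers"] == n
            if mean is None:
                assert np.isnan(row["mean_delta"])
            else:
                assert row["mean_delta"] == pytest.approx(mean)


class TestFitEd:
    def _pts(self, positions, eds):
        return pd.DataFrame(
            {
                "chrom": "chr1", "pos": positions,
                "index_aa": 0.5, "index_ab": 0.5, "delta": 0.0,
                "ed": eds, "maf_mut": 0.5,
            }
        )

    def test_constant_input_constant_fit(self):
        pts = self._pts(np.arange(1, 101) * 1000, 0.2)
        out = fit_ed(pts, power=1.0, span=0.2)
        assert np.allclose(out["fitted_ed"], 0.2)

    def test_smoothing_contracts_an_isolated_spike(self):
        eds = np.full(101, 0.1)
        eds[50] = 1.2
        pts = self._pts(np.arange(1, 102) * 1000, eds)
        out = fit_ed(pts, span=0.15)
        peak = out["fitted_ed"].idxmax()
        assert abs(peak - 50) <= 1
        assert 0.1 < out.loc[50, "fitted_ed"] < 1.2

    def test_matches_independent_tricube_regression(self, rng):
        """50-point fixture: fitted values equal an independent tricube
        local linear regression."""
        x = np.sort(rng.choice(np.arange(1, 500_000), 50, replace=False)).astype(float)
        y = 0.3 + 0.2 * np.sin(x / 40_000) + rng.normal(0, 0.02, 50)
        pts = self._pts(x.astype(int), y)
        out = fit_ed(pts, span=0.3)
        want = lowess_oracle(x, y, 0.3)
        assert np.allclose(out["fitted_ed"].to_numpy(), want, atol=1e-8)

    def test_single_site_chromosome_skipped(self):
        pts = self._pts([1000], [0.4])
        out = fit_ed(pts)
        assert np.isnan(out["fitted_ed"]).all()


class TestEdThreshold:
    def test_constant_values(self):
        assert ed_threshold(np.full(10, 0.3), 3) == pytest.approx(0.3)

    def test_hand_computed_population_sd(self):
        # values {0,0,0,0,10}: median 0, population SD 4.0 -> 0 + 3*4 = 12
        assert ed_threshold(np.array([0, 0, 0, 0, 10.0]), 3) == pytest.approx(12.0)

    def test_k_zero_is_median(self, rng):
        v = rng.random(101)
        assert ed_threshold(v, 0) == pytest.approx(np.median(v))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ed_threshold(np.array([]))

    def test_matches_independent_statistics(self, rng):
        """1000 random draws: agrees with a from-scratch median + 3*sqrt of
        the mean squared deviation."""
        for _ in range(20):
            v = rng.random(rng.integers(5, 200))
            srt = sorted(v)
            n = len(srt)
            med = srt[n // 2] if n % 2 else (srt[n // 2 - 1] + srt[n // 2]) / 2
            mean = sum(v) / n
            sd = math.sqrt(sum((x - mean) ** 2 for x in v) / n)
            assert ed_threshold(v, 3) == pytest.approx(med + 3 * sd)


class TestCallRegions:
    def _iv(self, chroms, positions):
        return pd.DataFrame({"chrom": chroms, "start": positions, "end": positions})

    def test_all_below_threshold_empty(self):
        iv = self._iv(["chr1"] * 5, [10, 20, 30, 40, 50])
        assert call_regions(iv, np.full(5, 0.1), 0.5) == []

    def test_gap_splits_regions(self):
        pos = [100, 200, 300, 400, 500, 600_000, 600_400, 600_900]
        iv = self._iv(["chr1"] * 8, pos)
        regions = call_regions(iv, np.ones(8), 0.5, max_gap_bp=1000)
        assert len(regions) == 2
        assert (regions[0].interval.start, regions[0].interval.end) == (100, 500)
        assert (regions[1].interval.start, regions[1].interval.end) == (600_000, 600_900)

    def test_chromosome_change_splits(self):
        iv = self._iv(["chr1", "chr1", "chr2"], [10, 20, 30])
        regions = call_regions(iv, np.ones(3), 0.5, max_gap_bp=10**9)
        assert [r.interval.chrom for r in regions] == ["chr1", "chr2"]

    def test_matches_run_length_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 80))
            chroms = sorted(rng.choice(["chr1", "chr2"], n))
            positions = np.sort(rng.choice(np.arange(1, 10_000), n, replace=False))
            values = rng.random(n)
            gap = int(rng.integers(1, 3000))
            iv = self._iv(chroms, positions)
            got = call_regions(iv, values, 0.6, max_gap_bp=gap)
            want = region_oracle(chroms, positions, values, 0.6, gap)
            assert [
                (r.interval.chrom, r.interval.start, r.interval.end, r.n_markers)
                for r in got
            ] == want

    def test_marker_counts_sum_to_above_threshold_sites(self, rng):
        n = 200
        positions = np.sort(rng.choice(np.arange(1, 10**6), n, replace=False))
        values = rng.random(n)
        iv = self._iv(["chr1"] * n, positions)
        regions = call_regions(iv, values, 0.7, max_gap_bp=50_000)
        assert sum(r.n_markers for r in regions) == int((values > 0.7).sum())
        ivs = [r.interval for r in regions]
        for a, b in zip(ivs, ivs[1:]):
            assert a.end < b.start  # non-overlapping, ordered


class TestCandidateSnps:
    def _pts(self, rows):
        return pd.DataFrame(
            rows, columns=["chrom", "pos", "index_aa", "index_ab", "delta", "ed", "maf_mut"]
        )

    def test_selection_rules(self):
        from bsamap.regions import CandidateRegion, GenomicInterval

        region = [CandidateRegion(GenomicInterval("chr1", 1, 1000), "ed")]
        pts = self._pts(
            [
                ("chr1", 10, 0.9, 0.1, 0.8, 0.60, 0.80),   # selected
                ("chr1", 20, 0.9, 0.1, 0.8, 0.40, 0.80),   # ED too low
                ("chr1", 30, 0.9, 0.1, 0.8, 0.60, 0.70),   # maf too low
                ("chr2", 40, 0.9, 0.1, 0.8, 0.60, 0.80),   # outside region
            ]
        )
        got = select_candidate_snps(pts, region, ScanConfig())
        assert list(got["pos"]) == [10]

    def test_main_allele_frequency_from_quadruple(self):
        rec = make_record(ref="G", alt="A", POOL_LONG=(40, 10, 0, 0))
        points, _ = compute_scan_points([rec])
        assert points.loc[0, "maf_mut"] == pytest.approx(0.8)


class TestDeltaRegions:
    def test_absolute_mode_calls_high_windows_two_sided(self):
        win = pd.DataFrame(
            {
                "chrom": ["chr1"] * 4,
                "start": [1, 500_001, 1_000_001, 1_500_001],
                "end": [500_001, 1_000_001, 1_500_001, 2_000_001],
                "n_markers": [10] * 4,
                "mean_delta": [0.2, 0.96, -0.97, 0.1],
            }
        )
        regs = delta_regions(win, ScanConfig(delta_mode="absolute", max_gap_bp=0))
        assert len(regs) == 1  # adjacent windows merge (share a boundary bp)
        assert (regs[0].interval.start, regs[0].interval.end) == (500_001, 1_500_001)
        assert regs[0].n_markers == 20

    def test_masked_windows_never_called(self):
        win = pd.DataFrame(
            {
                "chrom": ["chr1"],
                "start": [1],
                "end": [500_001],
                "n_markers": [1],
                "mean_delta": [np.nan],
            }
        )
        assert delta_regions(win, ScanConfig(delta_mode="absolute")) == []
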