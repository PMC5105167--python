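import numpy as np
import pytest

from glycosim import (
    MzSpectrum,
    UndefinedCorrelationError,
    bin_spectrum,
    binwidth_scan,
    match_peak_pairs,
    optimal_bin_width,
    pearson_similarity,
)


def _spec(mz, inten=None, mode="centroid"):
    mz = np.asarray(mz, float)
    inten = np.ones_like(mz) if inten is None else np.asarray(inten, float)
    return MzSpectrum(mz, inten, mode)


class TestBinSpectrum:
    def test_point_lands_in_floor_bin(self):
        b = bin_spectrum(_spec([1000.5], [2.0]), width=1.0, mz_range=(1000.0, 1005.0),
                         origin=1000.0)
        assert b.intensities[0] == 2.0
        assert b.intensities[1:].sum() == 0.0

    def test_total_intensity_conserved_in_range(self, rng):
        mz = np.sort(rng.uniform(900.0, 1100.0, 200))
        mz = np.unique(mz)
        inten = rng.uniform(0, 1, mz.size)
        spec = _spec(mz, inten)
        b = bin_spectrum(spec, width=3.7, mz_range=(950.0, 1050.0))
        in_range = inten[(mz >= 950.0) & (mz < 1050.0)].sum()
        assert b.intensities.sum() == pytest.approx(in_range, rel=1e-6)

    def test_cobinning_guarantee_origin_sweep(self):
        """Two points 0.4 Th apart may split at width 0.5 for some phases,
        but at width >= 2x separation they are co-binned or adjacent for
        every origin."""
        pair = _spec([1000.0, 1000.4], [1.0, 1.0])
        split_seen = False
        for origin in np.arange(999.5, 1000.5, 0.01):
            b = bin_spectrum(pair, 0.5, (999.0, 1001.5), origin=float(origin))
            occupied = np.flatnonzero(b.intensities)
            if occupied.size == 2:
                split_seen = True
        assert split_seen
        for origin in np.arange(999.5, 1000.5, 0.01):
            b = bin_spectrum(pair, 0.8, (999.0, 1001.5), origin=float(origin))
            occupied = np.flatnonzero(b.intensities)
            assert occupied.size <= 2
            if occupied.size == 2:
                assert occupied[1] - occupied[0] == 1

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError):
            bin_spectrum(_spec([1000.0]), width=0.0)


class TestPearson:
    def test_self_similarity_is_one(self, rng):
        mz = np.unique(np.sort(rng.uniform(2_000, 4_000, 50)))
        spec = _spec(mz, rng.uniform(0.1, 1.0, mz.size))
        for w in (0.5, 2.0, 10.0):
            assert pearson_similarity(spec, spec, w).r == pytest.approx(1.0, abs=1e-12)

    def test_affine_intensity_invariance(self, rng):
        # one peak per bin so that a per-point offset is a per-bin offset
        mz = 2_000.5 + 2.0 * np.arange(50)
        inten = rng.uniform(0.1, 1.0, mz.size)
        a = _spec(mz, inten)
        b = _spec(mz, 5.0 * inten + 0.3)
        r = pearson_similarity(a, b, 2.0, mz_range=(2_000.0, 2_100.0)).r
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_symmetry_and_bounds(self, rng):
        a = _spec(np.unique(np.sort(rng.uniform(2_000, 4_000, 60))),
                  rng.uniform(0, 1, 60)[:60])
        mzb = np.unique(np.sort(rng.uniform(2_000, 4_000, 60)))
        b = _spec(mzb, rng.uniform(0, 1, mzb.size))
        r_ab = pearson_similarity(a, b, 5.0).r
        r_ba = pearson_similarity(b, a, 5.0).r
        assert r_ab == pytest.approx(r_ba, abs=1e-12)
        assert -1.0 <= r_ab <= 1.0

    def test_separating_distributions_decreases_r(self):
        """Pairs of sialylation-ladder spectra: r falls as the two
        abundance distributions move apart."""
        sia = 291.2579
        base = 26_000.0
        masses = base + sia * np.arange(16)

        def ladder(center):
            w = np.exp(-0.5 * ((np.arange(16) - center) / 2.0) ** 2)
            return _spec(masses, w / w.sum())

        ref = ladder(5.0)
        rs = [pearson_similarity(ref, ladder(5.0 + d), 50.0).r for d in (0.0, 2.0, 4.0, 6.0)]
        assert rs[0] == pytest.approx(1.0, abs=1e-12)
        assert all(x > y for x, y in zip(rs, rs[1:]))
        assert rs[-1] < 0.5

    def test_zero_variance_is_an_error(self):
        flat = _spec([1000.0, 1001.0, 1002.0], [1.0, 1.0, 1.0])
        other = _spec([1000.0, 1001.0, 1002.0], [1.0, 2.0, 3.0])
        with pytest.raises(UndefinedCorrelationError):
            pearson_similarity(flat, other, 1.0)

    def test_disjoint_ranges_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            pearson_similarity(_spec([100.0, 110.0]), _spec([500.0, 510.0]), 1.0)

    def test_rescoring_is_bit_identical(self, rng):
        mz = np.unique(np.sort(rng.uniform(2_000, 4_000, 80)))
        a = _spec(mz, rng.uniform(0, 1, mz.size))
        b = _spec(mz, rng.uniform(0, 1, mz.size))
        assert pearson_similarity(a, b, 3.3).r == pearson_similarity(a, b, 3.3).r


class TestMatchPeakPairs:
    def test_identical_spectra_pair_at_zero_delta(self, rng):
        mz = np.unique(np.sort(rng.uniform(2_000, 3_000, 25)))
        spec = _spec(mz, rng.uniform(0.1, 1.0, mz.size))
        pairs = match_peak_pairs(spec, spec, top_n=10, tol=0.5)
        assert len(pairs) == 10
        assert all(p.delta == 0.0 for p in pairs)

    def test_uniform_shift_matched_within_tol(self, rng):
        mz = np.unique(np.sort(rng.uniform(2_000, 3_000, 20)))
        inten = rng.uniform(0.1, 1.0, mz.size)
        a = _spec(mz, inten)
        b = _spec(mz + 0.2, inten)
        pairs = match_peak_pairs(a, b, top_n=20, tol=0.5)
        assert len(pairs) == 20
        assert all(p.delta == pytest.approx(0.2, abs=1e-9) for p in pairs)

    def test_low_intensity_decoys_excluded_from_top_n(self):
        main_mz = np.arange(2_000.0, 2_010.0)
        decoy_mz = main_mz + 0.5
        mz = np.sort(np.concatenate([main_mz, decoy_mz]))
        inten = np.where(np.isin(mz, main_mz), 1.0, 0.05)
        a = _spec(mz, inten)
        pairs = match_peak_pairs(a, a, top_n=10, tol=0.1)
        assert len(pairs) == 10
        assert all(p.intensity_a == 1.0 for p in pairs)

    def test_fewer_matches_warns(self):
        a = _spec([2_000.0, 2_100.0])
        with pytest.warns(UserWarning, match="peak pairs"):
            pairs = match_peak_pairs(a, a, top_n=20, tol=0.5)
        assert len(pairs) == 2


class TestOptimalBinWidth:
    def test_identical_spectra_return_minimum_width(self, rng):
        mz = np.unique(np.sort(rng.uniform(25_000, 33_000, 30)))
        spec = _spec(mz, rng.uniform(0.1, 1.0, mz.size))
        assert optimal_bin_width(spec, spec) == 1.0

    def test_median_of_60_matches_hand_oracle(self, rng):
        """20 pairs x 3 charges gives exactly 60 candidates whose median
        matches an independently hand-computed value."""
        deltas = np.round(rng.uniform(-8.0, 8.0, 20), 3)
        deltas[0] = 0.5
        masses = 26_000.0 + 400.0 * np.arange(20)
        inten = np.linspace(1.0, 0.5, 20)
        a = _spec(masses, inten)
        b = _spec(masses + deltas, inten)
        charges = (8, 9, 10)
        # independent oracle: explicit 60-element list, plain arithmetic
        candidates = []
        for d in deltas:
            for z in charges:
                candidates.append(2.0 * abs(d) / z)
        assert len(candidates) == 60
        expected = max(float(np.median(candidates)), 1.0)
        got = optimal_bin_width(a, b, charges=charges, top_n=20, tol=50.0)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_alternative_delta_rule(self, rng):
        masses = 26_000.0 + 400.0 * np.arange(20)
        a = _spec(masses)
        b = _spec(masses + 18.0)
        w2 = optimal_bin_width(a, b, tol=50.0, rule="two_delta")
        w1 = optimal_bin_width(a, b, tol=50.0, rule="delta")
        assert w2 == pytest.approx(2 * w1, abs=1e-9)


class TestBinWidthScan:
    def test_default_grid_has_191_points(self, rng):
        mz = np.unique(np.sort(rng.uniform(2_500, 3_500, 60)))
        a = _spec(mz, rng.uniform(0.1, 1.0, mz.size))
        b = _spec(mz, rng.uniform(0.1, 1.0, mz.size))
        scan = binwidth_scan(a, b)
        assert scan.widths.size == 191
        assert scan.widths[0] == pytest.approx(1.0)
        assert scan.widths[-1] == pytest.approx(20.0)

    def test_identical_spectra_flat_scan_flagged(self, rng):
        mz = np.unique(np.sort(rng.uniform(2_500, 3_500, 60)))
        spec = _spec(mz, rng.uniform(0.1, 1.0, mz.size))
        scan = binwidth_scan(spec, spec)
        assert scan.flat
        assert np.all(scan.r_values == pytest.approx(1.0, abs=1e-12))
        report = scan.selection_report(1.0)
        assert report["close"] is None

    def test_jittered_peaks_rise_then_plateau_with_inflection(self, rng):
        mz = np.unique(np.sort(rng.uniform(2_500, 3_500, 80)))
        inten = rng.uniform(0.2, 1.0, mz.size)
        jitter = rng.normal(0.0, 1.2, mz.size)
        a = _spec(mz, inten)
        b = _spec(np.sort(mz + jitter), inten)
        scan = binwidth_scan(a, b)
        assert not scan.flat
        assert scan.inflection is not None
        # r at wide bins beats r at the narrowest bins
        assert scan.smoothed[-20:].mean() > scan.smoothed[:10].mean()
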