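"""ALFF, ReHo, smoothing, vectorization and z-score normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mkmri import (
    BrainMask,
    FeatureMatrix,
    alff_map,
    compute_alff,
    compute_reho,
    discard_volumes,
    extract_feature_matrices,
    full_mask,
    generate_cohort,
    map_from_vector,
    reho_map,
    single_effect_config,
    smooth_gaussian,
    vectorize,
    zscore_apply,
    zscore_fit,
)
from mkmri.features import BandError, FeatureMap

from conftest import brute_force_kendall_w, random_mask


def centered_cosine(n, tr, freq, amplitude=1.0, phase=0.0):
    """Sinusoid at an exact DFT bin, symmetric about the series center so the
    linear-detrend step leaves it untouched."""
    k = round(freq * n * tr)
    t = np.arange(n) - (n - 1) / 2.0
    return amplitude * np.cos(2 * np.pi * k * t / n + phase), k / (n * tr)


class TestALFF:
    def test_constant_series_is_zero(self):
        assert compute_alff(np.full(190, 3.7), tr=2.0) == 0.0

    def test_exact_bin_sinusoid_amplitude(self):
        """In-band sinusoid of amplitude A at an exact bin -> A / n_bins."""
        n, tr, A = 190, 2.0, 2.5
        x, f = centered_cosine(n, tr, 0.05, amplitude=A)
        assert 0.01 <= f <= 0.08
        freqs = np.fft.rfftfreq(n, d=tr)
        n_bins = int(((freqs >= 0.01 - 1e-12) & (freqs <= 0.08 + 1e-12)).sum())
        assert compute_alff(x, tr) == pytest.approx(A / n_bins, rel=1e-10)

    def test_out_of_band_sinusoid_ignored(self):
        n, tr, A = 190, 2.0, 5.0
        x, f = centered_cosine(n, tr, 0.2, amplitude=A)
        assert f > 0.08
        assert compute_alff(x, tr) <= 1e-8 * A

    def test_matches_direct_dft_oracle(self, rng):
        """Random series against an explicit per-bin DFT summation."""
        n, tr = 48, 2.0
        x = rng.normal(size=n)
        # oracle: explicit line fit + direct DFT sums per bin
        t = np.arange(n)
        slope, intercept = np.polyfit(t, x, 1)
        d = x - (slope * t + intercept)
        freqs = [k / (n * tr) for k in range(n // 2 + 1)]
        amps = [2.0 * abs(sum(d[ti] * np.exp(-2j * np.pi * k * ti / n)
                              for ti in range(n))) / n
                for k in range(n // 2 + 1)]
        band = [a for a, f in zip(amps, freqs) if 0.01 <= f <= 0.08]
        expected = float(np.mean(band))
        assert compute_alff(x, tr) == pytest.approx(expected, abs=1e-10)

    def test_offset_invariance_and_linearity(self, rng):
        x = rng.normal(size=190)
        a = compute_alff(x, 2.0)
        assert compute_alff(x + 42.0, 2.0) == pytest.approx(a, abs=1e-12)
        assert compute_alff(3.0 * x, 2.0) == pytest.approx(3.0 * a, rel=1e-12)

    def test_empty_band_error_names_resolution(self):
        with pytest.raises(BandError, match="resolution"):
            compute_alff(np.arange(10.0), tr=0.1, band=(0.001, 0.002))

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            compute_alff(np.arange(20.0), tr=2.0, band=(0.01, 0.5))


class TestALFFMap:
    def test_voxel_matches_scalar_alff_and_mean_one(self, rng):
        func = rng.normal(size=(4, 4, 3, 60))
        mask = random_mask(rng, (4, 4, 3))
        fmap = alff_map(func, 2.0, (0.01, 0.08), mask)
        assert fmap.values[mask.grid].mean() == pytest.approx(1.0, abs=1e-9)
        # pre-scaling value of one voxel equals compute_alff of its series
        idx = tuple(np.argwhere(mask.grid)[0])
        raw = compute_alff(func[idx], 2.0)
        raw_mean = np.mean([compute_alff(func[tuple(i)], 2.0)
                            for i in np.argwhere(mask.grid)])
        assert fmap.values[idx] == pytest.approx(raw / raw_mean, rel=1e-10)

    def test_map_noise_cv_shrinks_with_longer_series(self):
        """Homogeneous noise: across-voxel CV of ALFF falls as n grows."""
        mask = full_mask((4, 4, 4))
        cvs = {n: [] for n in (64, 256)}
        for seed in range(20):
            r = np.random.default_rng(seed)
            for n in cvs:
                fmap = alff_map(r.normal(size=(4, 4, 4, n)), 2.0, (0.01, 0.08), mask)
                vals = fmap.values[mask.grid]
                cvs[n].append(vals.std() / vals.mean())
        assert np.mean(cvs[256]) < np.mean(cvs[64])


class TestReHo:
    def test_identical_series_perfect_concordance(self, rng):
        s = rng.normal(size=20)
        assert compute_reho(np.tile(s, (27, 1))) == pytest.approx(1.0, abs=1e-12)

    def test_opposed_ranks_zero_concordance(self):
        assert compute_reho([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]) == pytest.approx(0.0, abs=1e-15)

    def test_all_constant_series_zero(self):
        assert compute_reho(np.ones((5, 8))) == 0.0

    def test_matches_brute_force_oracle(self):
        """200 random small instances against an independent rank-and-sum
        concordance implementation, to 1e-12; includes tied values."""
        for seed in range(200):
            r = np.random.default_rng(seed)
            K = int(r.integers(2, 11))
            n = int(r.integers(2, 21))
            x = r.normal(size=(K, n))
            if seed % 3 == 0:  # discretize to force ties
                x = np.round(x)
            assert compute_reho(x) == pytest.approx(
                brute_force_kendall_w(x), abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bounded_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        w = compute_reho(r.normal(size=(int(r.integers(2, 8)), int(r.integers(2, 12)))))
        assert -1e-12 <= w <= 1.0 + 1e-12

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            compute_reho([[1.0, 2.0], [1.0, 2.0, 3.0]])


class TestReHoMap:
    def test_identical_series_everywhere_interior_prescaling_one(self):
        series = np.sin(np.arange(30))
        func = np.broadcast_to(series, (5, 5, 5, 30)).copy()
        mask = full_mask((5, 5, 5))
        fmap = reho_map(func, mask)
        # all raw values are 1, so scaling leaves a map of ones
        np.testing.assert_allclose(fmap.values, 1.0, atol=1e-12)

    def test_within_mask_mean_is_one(self, rng):
        func = rng.normal(size=(6, 5, 4, 20))
        mask = random_mask(rng, (6, 5, 4))
        fmap = reho_map(func, mask)
        assert fmap.values[mask.grid].mean() == pytest.approx(1.0, abs=1e-9)

    def test_interior_voxel_matches_gathered_neighborhood(self, rng):
        """One voxel against compute_reho on its manually gathered series."""
        func = rng.normal(size=(5, 5, 5, 24))
        mask = full_mask((5, 5, 5))
        fmap = reho_map(func, mask)
        neigh = func[1:4, 1:4, 1:4].reshape(27, 24)
        expected = compute_reho(neigh)
        raw = fmap.values * np.float64(_raw_mean(func, mask))
        assert raw[2, 2, 2] == pytest.approx(expected, abs=1e-12)

    def test_partial_neighborhoods_at_edges_and_min_neighbors(self, rng):
        """Corner voxels use the 8 in-mask neighbors; isolated voxels get 0."""
        func = rng.normal(size=(4, 4, 4, 16))
        grid = np.zeros((4, 4, 4), bool)
        grid[:2, :2, :2] = True   # 8-voxel block
        grid[3, 3, 3] = True      # isolated voxel -> fewer than 2 series
        mask = BrainMask(grid)
        fmap = reho_map(func, mask)
        assert fmap.values[3, 3, 3] == 0.0
        block = func[:2, :2, :2].reshape(8, 16)
        raw = fmap.values * np.float64(_raw_mean(func, mask))
        assert raw[0, 0, 0] == pytest.approx(compute_reho(block), abs=1e-12)

    def test_synchrony_effect_raises_patient_in_box_reho(self):
        """Shared-signal mixing at 0.8 separates the groups' in-box ReHo."""
        wins = 0
        for seed in range(20):
            cfg = single_effect_config(
                "synchrony", seed=seed, n_pos=4, n_neg=4, grid_dims=(8, 8, 8),
                n_volumes=48, n_discard=0)
            scans = generate_cohort(cfg)
            mask = full_mask(cfg.grid_dims)
            box = cfg.effects[0].slices
            pos, neg = [], []
            for s in scans:
                fmap = reho_map(s.functional, mask)
                (pos if s.label == 1 else neg).append(fmap.values[box].mean())
            wins += np.mean(pos) > np.mean(neg)
        assert wins >= 18


def _raw_mean(func, mask):
    """In-mask mean of the unscaled ReHo map (for undoing the scaling)."""
    from scipy.stats import rankdata

    n = func.shape[-1]
    vals = []
    for idx in np.argwhere(mask.grid):
        lo = np.maximum(idx - 1, 0)
        hi = np.minimum(idx + 2, mask.grid.shape)
        sl = tuple(slice(a, b) for a, b in zip(lo, hi))
        sub_mask = mask.grid[sl]
        series = func[sl][sub_mask]
        vals.append(compute_reho(series) if series.shape[0] >= 2 else 0.0)
    return np.mean(vals)


class TestSmoothing:
    def test_zero_fwhm_identity(self, rng):
        vol = rng.normal(size=(5, 5, 5))
        np.testing.assert_array_equal(smooth_gaussian(vol, 0.0, 3.0), vol)

    def test_constant_volume_unchanged(self):
        vol = np.full((6, 6, 6), 2.5)
        np.testing.assert_allclose(smooth_gaussian(vol, 4.0, 3.0), vol, atol=1e-12)

    def test_delta_peak_matches_discrete_kernel(self):
        """Delta image, 4 mm FWHM on 3 mm voxels: center equals the discrete
        normalized Gaussian peak cubed (separable kernel)."""
        sigma = 4.0 / (2.0 * np.sqrt(2.0 * np.log(2.0))) / 3.0
        radius = int(4.0 * sigma + 0.5)  # same truncation as the filter
        k = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma) ** 2)
        k /= k.sum()
        peak = k[radius] ** 3
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        sm = smooth_gaussian(vol, 4.0, 3.0)
        assert sm[7, 7, 7] == pytest.approx(peak, rel=1e-9)

    def test_total_sum_preserved(self, rng):
        vol = rng.normal(size=(7, 6, 5))
        sm = smooth_gaussian(vol, 6.0, 3.0)
        assert sm.sum() == pytest.approx(vol.sum(), rel=1e-6)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_gaussian(np.zeros((3, 3, 3)), -1.0, 3.0)


class TestDiscard:
    def test_drops_exactly_the_leading_volumes(self, rng):
        func = rng.normal(size=(3, 3, 3, 200))
        out = discard_volumes(func, 10)
        assert out.shape[-1] == 190
        np.testing.assert_array_equal(out[..., 0], func[..., 10])

    def test_zero_discard_identity(self, rng):
        func = rng.normal(size=(2, 2, 2, 5))
        np.testing.assert_array_equal(discard_volumes(func, 0), func)

    def test_discarding_all_rejected(self, rng):
        with pytest.raises(ValueError):
            discard_volumes(rng.normal(size=(2, 2, 2, 5)), 5)


class TestVectorize:
    def test_full_mask_row_order(self):
        mask = BrainMask(np.ones((2, 1, 1), bool))
        fmap = FeatureMap("s1", "GMV", np.array([3.0, 5.0]).reshape(2, 1, 1))
        fm = vectorize([fmap], mask)
        np.testing.assert_array_equal(fm.values, [[3.0, 5.0]])

    def test_masked_voxel_excluded(self):
        grid = np.array([False, True]).reshape(2, 1, 1)
        fmap = FeatureMap("s1", "GMV", np.array([3.0, 5.0]).reshape(2, 1, 1))
        fm = vectorize([fmap], BrainMask(grid))
        np.testing.assert_array_equal(fm.values, [[5.0]])

    def test_roundtrip_restores_map_within_mask(self, rng):
        mask = random_mask(rng, (4, 3, 5))
        values = rng.normal(size=(4, 3, 5))
        fm = vectorize([FeatureMap("s", "ALFF", values)], mask)
        back = map_from_vector(fm.values[0], mask)
        np.testing.assert_array_equal(back[mask.grid], values[mask.grid])
        assert (back[~mask.grid] == 0).all()

    def test_mixed_features_rejected(self, rng):
        mask = full_mask((2, 2, 2))
        a = FeatureMap("s", "GMV", np.zeros((2, 2, 2)))
        b = FeatureMap("s", "ALFF", np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            vectorize([a, b], mask)


class TestZScore:
    def test_train_columns_standardized(self, rng):
        X = rng.normal(2.0, 3.0, size=(10, 6))
        fm = FeatureMatrix("GMV", X, [f"s{i}" for i in range(10)])
        train = np.arange(7)
        params = zscore_fit(fm, train)
        Z = zscore_apply(fm, params).values
        np.testing.assert_allclose(Z[train].mean(0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z[train].std(0), 1.0, atol=1e-9)

    def test_population_variance_convention(self):
        fm = FeatureMatrix("GMV", np.array([[1.0], [3.0]]), ["a", "b"])
        Z = zscore_apply(fm, zscore_fit(fm, [0, 1])).values
        # population SD of (1,3) is 1, so the transform is (-1, +1)
        np.testing.assert_allclose(Z, [[-1.0], [1.0]], atol=1e-12)

    def test_heldout_rows_use_train_statistics_only(self, rng):
        X = np.vstack([rng.normal(size=(5, 3)), [[100.0, 100.0, 100.0]]])
        fm = FeatureMatrix("GMV", X, list("abcdef"))
        params = zscore_fit(fm, np.arange(5))
        Z = zscore_apply(fm, params).values
        expected = (X[5] - params.mean) / params.sd
        np.testing.assert_allclose(Z[5], expected)

    def test_constant_column_flagged_and_zeroed(self, rng):
        X = rng.normal(size=(6, 3))
        X[:4, 1] = 7.0  # constant on the training rows only
        fm = FeatureMatrix("GMV", X, list("abcdef"))
        params = zscore_fit(fm, np.arange(4))
        assert params.constant.tolist() == [False, True, False]
        Z = zscore_apply(fm, params).values
        assert (Z[:, 1] == 0).all()

    def test_matches_sklearn_standard_scaler(self, rng):
        from sklearn.preprocessing import StandardScaler

        X = rng.normal(size=(8, 5))
        fm = FeatureMatrix("GMV", X, [str(i) for i in range(8)])
        Z = zscore_apply(fm, zscore_fit(fm, np.arange(8))).values
        np.testing.assert_allclose(Z, StandardScaler().fit_transform(X), atol=1e-10)

    def test_single_training_row_rejected(self, rng):
        fm = FeatureMatrix("GMV", rng.normal(size=(4, 2)), list("abcd"))
        with pytest.raises(ValueError):
            zscore_fit(fm, [2])


class TestExtractionPipeline:
    def test_shapes_and_scaling(self, tiny_features):
        mats, labels, mask = tiny_features
        assert set(mats) == {"GMV", "ALFF", "ReHo"}
        for m in mats.values():
            assert m.values.shape == (8, mask.D)
            assert np.isfinite(m.values).all()

    def test_feature_subset(self, tiny_cohort):
        cfg, scans, mask = tiny_cohort
        mats = extract_feature_matrices(scans, mask, n_discard=cfg.n_discard,
                                        features=("GMV",))
        assert list(mats) == ["GMV"]
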