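"""Preprocessing chain: each step against an independent oracle or invariant."""

import numpy as np
import pytest

from serumpep.spectrum import RawSpectrum
from serumpep import preprocess as pp
from serumpep.preprocess import (DegenerateSpectrumError, FeatureMatrix,
                                 PeakDefinition, RecalibrationError,
                                 build_feature_matrix, detect_peaks,
                                 estimate_noise, integrate_areas, normalize_tic,
                                 opening, recalibrate, smooth,
                                 subtract_baseline_tophat)
from serumpep.simulate import simulate_cohort, draw_peak_areas, MUTANT, WILD
from tests.conftest import small_config


def flat_grid(lo=1000.0, hi=2000.0, step=0.25):
    n = int(round((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


def gaussian(grid, centroid, area, sigma):
    amp = area / (sigma * np.sqrt(2 * np.pi))
    return amp * np.exp(-0.5 * ((grid - centroid) / sigma) ** 2)


class TestNormalize:
    def test_sets_target_and_is_idempotent(self, rng):
        grid = flat_grid()
        spec = RawSpectrum("s", grid, 1.0 + rng.random(len(grid)))
        once = normalize_tic(spec, target_tic=7.5)
        assert once.tic() == pytest.approx(7.5, rel=1e-12)
        twice = normalize_tic(once, target_tic=7.5)
        np.testing.assert_allclose(twice.intensity, once.intensity, rtol=1e-12)

    def test_zero_tic_rejected(self):
        grid = flat_grid()
        with pytest.raises(DegenerateSpectrumError):
            normalize_tic(RawSpectrum("s", grid, np.zeros(len(grid))))


class TestSmooth:
    def test_constant_is_fixed_point(self):
        grid = flat_grid()
        spec = RawSpectrum("s", grid, np.full(len(grid), 3.3))
        out = smooth(spec, window=2.0, order=3)
        np.testing.assert_allclose(out.intensity, 3.3, rtol=1e-9)

    def test_moving_average_noise_variance_reduction(self, rng):
        # order 0 degenerates to a moving average of w points: white-noise
        # variance shrinks by ~1/w
        grid = flat_grid(step=0.25)
        noise = rng.standard_normal(len(grid))
        spec = RawSpectrum("s", grid, noise + 100.0)
        w_da = 4.0
        w_pts = int(round(w_da / 0.25)) | 1
        out = smooth(spec, window=w_da, order=0)
        interior = slice(w_pts, -w_pts)
        ratio = noise[interior].var() / out.intensity[interior].var()
        assert 0.6 * w_pts < ratio < 1.4 * w_pts

    def test_wide_peak_area_preserved(self):
        grid = flat_grid()
        sigma = 2.0
        spec = RawSpectrum("s", grid, gaussian(grid, 1500.0, 40.0, sigma))
        out = smooth(spec, window=2.0, order=3)
        assert np.trapezoid(out.intensity, grid) == pytest.approx(40.0, rel=0.01)

    def test_window_wider_than_spectrum_rejected(self):
        spec = RawSpectrum("s", [1.0, 2.0, 3.0], [0.0, 1.0, 0.0])
        with pytest.raises(ValueError, match="wider"):
            smooth(spec, window=100.0)


class TestBaseline:
    def test_opening_matches_brute_force_oracle(self, rng):
        y = rng.random(300)
        size = 7
        # oracle: sliding minimum then sliding maximum with edge replication
        def slide(arr, fn):
            half = size // 2
            padded = np.concatenate([np.full(half, arr[0]), arr,
                                     np.full(half, arr[-1])])
            return np.array([fn(padded[i:i + size]) for i in range(len(arr))])
        expected = slide(slide(y, np.min), np.max)
        np.testing.assert_allclose(opening(y, size), expected)

    def test_opening_is_idempotent(self, rng):
        y = rng.random(500)
        once = opening(y, 15)
        np.testing.assert_allclose(opening(once, 15), once)

    def test_flat_and_slow_baselines_annihilated(self):
        grid = flat_grid(800, 4000, 0.5)
        flat = RawSpectrum("s", grid, np.full(len(grid), 5.0))
        out = subtract_baseline_tophat(flat)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)
        slow = RawSpectrum("s", grid, 2.0 * np.exp(-(grid - 800) / 2000.0) + 0.2)
        out = subtract_baseline_tophat(slow)
        # the opening cannot track the baseline within half an element of the
        # left edge; beyond that boundary zone the residual must vanish
        half_element = 0.5 * 0.10 * (grid[-1] - grid[0])
        interior = grid >= grid[0] + half_element
        assert np.all(out.intensity[interior] < 1e-9)
        assert out.intensity.max() < 0.1 * slow.intensity.max()

    def test_narrow_peak_preserved_on_baseline(self):
        grid = flat_grid(800, 4000, 0.5)
        peak = gaussian(grid, 2000.0, 30.0, 1.0)
        spec = RawSpectrum("s", grid, peak + 4.0)
        out = subtract_baseline_tophat(spec)
        sel = np.abs(grid - 2000.0) < 5.0
        assert np.trapezoid(out.intensity[sel], grid[sel]) == pytest.approx(
            30.0, rel=0.02)

    def test_bad_width_rejected(self):
        grid = flat_grid()
        spec = RawSpectrum("s", grid, np.ones(len(grid)))
        with pytest.raises(ValueError):
            subtract_baseline_tophat(spec, min_width_frac=0.0)


class TestNoise:
    def test_recovers_known_sigma(self, rng):
        grid = flat_grid(800, 5000, 0.25)
        sigma = 0.7
        spec = RawSpectrum("s", grid, 100.0 + sigma * rng.standard_normal(len(grid)))
        est = estimate_noise(spec)
        assert np.median(est) == pytest.approx(sigma, rel=0.15)

    def test_robust_to_sparse_tall_peaks(self, rng):
        grid = flat_grid(800, 5000, 0.25)
        sigma = 0.5
        y = sigma * rng.standard_normal(len(grid))
        for c in (1200.0, 2500.0, 3900.0):
            y += gaussian(grid, c, 200.0, c / 3000.0)
        est = estimate_noise(RawSpectrum("s", grid, y + 10.0))
        assert np.median(est) == pytest.approx(sigma, rel=0.3)

    def test_zero_noise_gives_near_zero(self):
        grid = flat_grid()
        est = estimate_noise(RawSpectrum("s", grid, np.full(len(grid), 2.0)))
        assert np.all(est < 1e-9)


class TestDetect:
    def test_injected_peaks_recovered_with_correct_centroids(self, rng):
        grid = flat_grid(800, 5000, 0.25)
        centroids = [1234.5, 2345.6, 3456.7]
        y = 0.2 * rng.standard_normal(len(grid))
        for c in centroids:
            y += gaussian(grid, c, 50.0, c / 3000.0)
        spec = RawSpectrum("s", grid, np.maximum(y, 0.0))
        defs = detect_peaks(spec, estimate_noise(spec), snr_threshold=5.0)
        found = np.array([d.centroid for d in defs])
        for c in centroids:
            assert np.min(np.abs(found - c)) < 0.5

    def test_pure_noise_yields_few_detections(self, rng):
        counts = []
        grid = flat_grid(800, 3000, 0.25)
        for _ in range(20):
            y = np.maximum(0.3 * rng.standard_normal(len(grid)), 0.0)
            defs = detect_peaks(RawSpectrum("s", grid, y),
                                np.full(len(grid), 0.3), snr_threshold=5.0)
            counts.append(len(defs))
        assert np.mean(counts) < 1.0

    def test_bounds_bracket_centroid_and_do_not_overlap(self, rng):
        grid = flat_grid(800, 5000, 0.25)
        y = 0.1 * rng.standard_normal(len(grid))
        for c in np.linspace(1000, 4800, 12):
            y += gaussian(grid, float(c), 30.0, c / 3000.0)
        spec = RawSpectrum("s", grid, np.maximum(y, 0.0))
        defs = detect_peaks(spec, estimate_noise(spec))
        assert len(defs) >= 10
        for a, b in zip(defs, defs[1:]):
            assert a.left_bound < a.centroid < a.right_bound
            assert a.right_bound <= b.left_bound + 1e-9


class TestIntegrate:
    def test_gaussian_area_analytic(self):
        grid = flat_grid(800, 3000, 0.25)
        spec = RawSpectrum("s", grid, gaussian(grid, 1500.0, 12.0, 0.5))
        defs = [PeakDefinition(1500.0, 1495.0, 1505.0)]
        area = integrate_areas(spec, defs)[0]
        assert area == pytest.approx(12.0, rel=1e-3)

    def test_zero_signal_zero_area(self):
        grid = flat_grid()
        spec = RawSpectrum("s", grid, np.zeros(len(grid)))
        assert integrate_areas(spec, [PeakDefinition(1500.0, 1495.0, 1505.0)])[0] == 0.0

    def test_recentering_absorbs_small_shift(self):
        grid = flat_grid(800, 3000, 0.25)
        shift = 1.5
        spec = RawSpectrum("s", grid, gaussian(grid, 1500.0 + shift, 12.0, 0.5))
        defs = [PeakDefinition(1500.0, 1497.5, 1502.5)]
        area = integrate_areas(spec, defs)[0]
        assert area == pytest.approx(12.0, rel=0.01)

    def test_out_of_range_bounds_rejected(self):
        grid = flat_grid(1000, 2000)
        spec = RawSpectrum("s", grid, np.ones(len(grid)))
        with pytest.raises(ValueError, match="outside"):
            integrate_areas(spec, [PeakDefinition(999.0, 990.0, 1005.0)])

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError, match="bracket"):
            PeakDefinition(1500.0, 1505.0, 1510.0)


class TestRecalibrate:
    def _cohort_with_warps(self, warps):
        grid = flat_grid(800, 5000, 0.25)
        y = np.zeros(len(grid))
        for c in np.linspace(1000, 4800, 10):
            y += gaussian(grid, float(c), 40.0, c / 3000.0)
        y += 0.5
        specs = []
        for i, (a, b) in enumerate(warps):
            specs.append(RawSpectrum(f"s{i}", a * grid + b, y.copy()))
        return grid, specs

    def test_identity_cohort_untouched(self):
        grid, specs = self._cohort_with_warps([(1.0, 0.0)] * 4)
        warped, fits = recalibrate(specs, reference_grid=grid)
        for a, b in fits:
            assert a == pytest.approx(1.0, abs=1e-6)
            assert b == pytest.approx(0.0, abs=5e-3)

    def test_known_affine_warp_recovered(self):
        true = [(1.0, 0.0), (1.0002, 0.25), (0.9998, -0.3), (1.0001, 0.1)]
        grid, specs = self._cohort_with_warps(true)
        warped, fits = recalibrate(specs, reference_grid=grid)
        for (a_true, b_true), (a_fit, b_fit) in zip(true, fits):
            # the fitted map must approximately invert the injected distortion
            test_mz = np.array([1000.0, 2500.0, 4500.0])
            recovered = a_fit * (a_true * test_mz + b_true) + b_fit
            np.testing.assert_allclose(recovered, test_mz, atol=0.3)
        # peak apexes align across warped spectra
        apex = [w.mz[np.argmax(w.intensity)] for w in warped]
        assert np.ptp(apex) <= 0.5

    def test_too_few_spectra_rejected(self):
        grid, specs = self._cohort_with_warps([(1.0, 0.0)])
        with pytest.raises(RecalibrationError):
            recalibrate(specs)

    def test_featureless_cohort_rejected(self, rng):
        grid = flat_grid()
        specs = [RawSpectrum(f"s{i}", grid, np.full(len(grid), 1.0))
                 for i in range(3)]
        with pytest.raises(RecalibrationError):
            recalibrate(specs)


class TestFeatureMatrix:
    def test_shape_validation(self):
        with pytest.raises(ValueError, match="shape"):
            FeatureMatrix(["a"], [PeakDefinition(10.0, 9.0, 11.0)],
                          np.zeros((2, 1)), ["ok"])

    def test_negative_areas_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            FeatureMatrix(["a"], [PeakDefinition(10.0, 9.0, 11.0)],
                          np.array([[-1.0]]), ["ok"])

    def test_cohort_matrix_structure(self, small_cohort):
        cfg, spectra, meta, fm = small_cohort
        assert len(fm.sample_ids) == cfg.n_mutant + cfg.n_wild
        assert all(f == "ok" for f in fm.qc_flags)
        # every informative centroid appears as a consensus peak
        for row in cfg.discriminating_peaks:
            assert np.min(np.abs(fm.centroids - row[0])) < 1.0

    def test_full_chain_area_recovery(self):
        """Near-noise-free cohort: recovered areas match the drawn truth.

        The per-spectrum TIC normalization rescales everything by
        nominal/actual TIC; correcting for that known factor, each
        informative peak's integrated area must sit within 5% of the area the
        generator actually drew for that patient.
        """
        cfg = small_config(n_mutant=6, n_wild=6, noise_sigma=0.01,
                           tic_variation=0.0, calibration_scale_max=0.0,
                           calibration_offset_max=0.0, seed=19)
        spectra, meta = simulate_cohort(cfg)
        raw_tics = [s.trimmed(cfg.mz_min, cfg.mz_max).tic() for s in spectra]
        fm = build_feature_matrix(spectra, mz_min=cfg.mz_min, mz_max=cfg.mz_max,
                                  target_tic=cfg.nominal_tic())
        centroids = fm.centroids
        for i, cls in enumerate(meta["true_class"]):
            rng = np.random.default_rng([cfg.seed, 1, i])
            rng.random()  # the cohort loop's invalid-flag draw
            truth = draw_peak_areas(cls, cfg, rng)
            scale = raw_tics[i] / cfg.nominal_tic()
            for c, a_true in truth.items():
                if a_true < 3.0:
                    continue  # below the resolvable scale at this noise floor
                j = int(np.argmin(np.abs(centroids - c)))
                assert abs(centroids[j] - c) < 1.0
                a_rec = fm.areas[i, j] * scale
                assert a_rec == pytest.approx(a_true, rel=0.05), (
                    f"sample {i}, peak {c}")

    def test_attenuated_spectrum_flagged_invalid(self):
        cfg = small_config(n_mutant=8, n_wild=8, invalid_rate=0.3, seed=23)
        spectra, meta = simulate_cohort(cfg)
        assert meta["invalid_flag"].any() and not meta["invalid_flag"].all()
        from serumpep.pipeline import preprocess_cohort
        fm = preprocess_cohort(spectra, cfg)
        flagged = np.array([f != "ok" for f in fm.qc_flags])
        np.testing.assert_array_equal(flagged, meta["invalid_flag"].to_numpy())
        assert np.all(np.isnan(fm.areas[flagged]))
        assert np.all(np.isfinite(fm.areas[~flagged]))

    def test_pinned_definitions_are_reused(self, small_cohort):
        cfg, spectra, meta, fm = small_cohort
        fm2 = build_feature_matrix(spectra[:4], mz_min=cfg.mz_min,
                                   mz_max=cfg.mz_max,
                                   target_tic=cfg.nominal_tic(),
                                   peak_definitions=fm.peak_definitions)
        assert [p.centroid for p in fm2.peak_definitions] == \
            [p.centroid for p in fm.peak_definitions]

    def test_chain_is_deterministic(self, small_cohort):
        cfg, spectra, meta, fm = small_cohort
        from serumpep.pipeline import preprocess_cohort
        fm2 = preprocess_cohort(spectra, cfg)
        np.testing.assert_array_equal(fm.areas, fm2.areas)
        assert fm.qc_flags == fm2.qc_flags
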