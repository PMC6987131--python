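import numpy as np
import pytest
from scipy import stats

from holotomo.quantify import (FWHM_FACTOR, colocalization, density_per_plane,
                               extract_contacts, fit_durations, fit_profile,
                               motion_blur_limit, segment_by_contrast,
                               slab_area_fraction)


class TestFitProfile:
    def _ridge(self, sigma_px=85.0 / 65.0, amp=1.0, n=64):
        x = np.arange(n)
        profile = amp * np.exp(-0.5 * ((x - n / 2) / sigma_px) ** 2)
        return np.tile(profile[:, None], (1, n))

    def test_gaussian_ridge_fwhm(self):
        image = self._ridge()
        fit = fit_profile(image, ((5.0, 32.0), (58.0, 32.0)), width=5,
                          spacing=65.0)
        assert abs(fit.fwhm - FWHM_FACTOR * 85.0) < 1.0   # 200.2 +/- 1 nm
        assert fit.r_squared > 0.999

    def test_fwhm_sigma_identity(self):
        fit = fit_profile(self._ridge(), ((5.0, 32.0), (58.0, 32.0)),
                          width=3, spacing=65.0)
        assert fit.fwhm == FWHM_FACTOR * fit.sigma       # exact by definition

    def test_flat_image_flagged(self):
        fit = fit_profile(np.zeros((32, 32)), ((2.0, 16.0), (29.0, 16.0)))
        assert abs(fit.amplitude) < 1e-8 or np.isnan(fit.r_squared)

    def test_line_outside_image_raises(self):
        with pytest.raises(ValueError, match="outside"):
            fit_profile(np.zeros((16, 16)), ((0.0, 0.0), (20.0, 0.0)))


def _volume_with_spheres(centers, radius_vox, value, shape=(64, 64, 32),
                         background=1.337):
    vol = np.full(shape, background)
    ii, jj, kk = np.meshgrid(*map(np.arange, shape), indexing="ij")
    for c in centers:
        mask = ((ii - c[0]) ** 2 + (jj - c[1]) ** 2
                + (kk - c[2]) ** 2) <= radius_vox ** 2
        vol[mask] = value
    return vol


class TestSegmentation:
    def test_uniform_volume_yields_no_objects(self):
        labels, stats_ = segment_by_contrast(
            np.full((32, 32, 16), 1.337), voxel_size=(65, 65, 65))
        assert labels.max() == 0 and stats_ == []

    def test_dark_mode_is_class_pure(self):
        vol = _volume_with_spheres([(16, 16, 16), (48, 16, 16)], 5, 1.31)
        vol2 = _volume_with_spheres([(16, 48, 16), (48, 48, 16)], 5, 1.39,
                                    background=0.0)
        vol[vol2 == 1.39] = 1.39
        labels, stats_ = segment_by_contrast(vol, mode="dark", k_sigma=3.0,
                                             min_diameter=0.3,
                                             voxel_size=(65, 65, 65))
        assert len(stats_) == 2
        assert all(s.delta_ri < 0 for s in stats_)
        labels, stats_ = segment_by_contrast(vol, mode="bright", k_sigma=3.0,
                                             min_diameter=0.3,
                                             voxel_size=(65, 65, 65))
        assert len(stats_) == 2
        assert all(s.delta_ri > 0 for s in stats_)

    def test_diameters_accurate_on_sharp_objects(self):
        radius_vox = 6
        vol = _volume_with_spheres([(16, 16, 16), (44, 44, 16)], radius_vox,
                                   1.31)
        _, stats_ = segment_by_contrast(vol, mode="dark", k_sigma=3.0,
                                        min_diameter=0.3,
                                        voxel_size=(65, 65, 65))
        true_d = 2 * radius_vox * 65.0 / 1e3
        for s in stats_:
            assert abs(s.equivalent_diameter - true_d) / true_d < 0.10

    def test_min_diameter_filters_specks(self):
        vol = _volume_with_spheres([(16, 16, 16)], 6, 1.31)
        vol[40, 40, 16] = 1.31                       # single-voxel speck
        labels, stats_ = segment_by_contrast(vol, mode="dark",
                                             min_diameter=0.5,
                                             voxel_size=(65, 65, 65))
        assert len(stats_) == 1
        assert len(np.unique(labels)) == 2           # background + one object


class TestPlaneAndSlab:
    def test_empty_labels_zero_density(self):
        assert density_per_plane(np.zeros((8, 8, 8), int), 4) == 0

    def test_object_counted_once_per_intersected_plane(self):
        labels = np.zeros((8, 8, 8), int)
        labels[3:5, 3:5, 2:5] = 1                   # spans planes 2..4
        for z, expected in [(1, 0), (2, 1), (3, 1), (4, 1), (5, 0)]:
            assert density_per_plane(labels, z) == expected

    def test_plane_out_of_range_raises(self):
        with pytest.raises(ValueError, match="range"):
            density_per_plane(np.zeros((4, 4, 4), int), 9)

    def test_all_objects_inside_slab(self):
        labels = np.zeros((16, 16, 30), int)
        labels[4:8, 4:8, 14:17] = 1
        assert slab_area_fraction(labels, 10) == 1.0

    def test_uniform_axial_distribution(self):
        labels = np.zeros((16, 16, 30), int)
        labels[4:8, 4:8, :] = 1                     # column through all planes
        assert np.isclose(slab_area_fraction(labels, 10), 10.0 / 30.0)

    def test_matches_bruteforce_voxel_count(self):
        rng = np.random.default_rng(7)
        labels = np.zeros((24, 24, 24), int)
        for lab in range(1, 8):
            c = rng.integers(4, 20, 3)
            labels[c[0] - 2:c[0] + 2, c[1] - 2:c[1] + 2,
                   c[2] - 2:c[2] + 2] = lab
        frac = slab_area_fraction(labels, 6, center=12)
        inside = np.count_nonzero(labels[:, :, 9:15])
        assert np.isclose(frac, inside / np.count_nonzero(labels))

    def test_empty_labels_fraction_zero(self):
        assert slab_area_fraction(np.zeros((8, 8, 8), int), 4) == 0.0


class TestContacts:
    @staticmethod
    def _series(on_frames, n=15):
        a, b = [], []
        for t in range(n):
            ma = np.zeros((16, 16), bool)
            mb = np.zeros((16, 16), bool)
            ma[4:8, 4:8] = True
            mb[4:8, 8:12] = True           # edge-adjacent: touches after dilation
            if t not in on_frames:
                mb = np.zeros((16, 16), bool)
            a.append(ma)
            b.append(mb)
        return a, b

    def test_never_touching_gives_no_events(self):
        a, b = self._series(set())
        assert extract_contacts(a, b, dt=5.0) == []

    def test_single_run_duration(self):
        a, b = self._series(set(range(3, 11)))
        events = extract_contacts(a, b, dt=5.0)
        assert len(events) == 1
        assert events[0].duration == 40.0            # 8 frames * 5 s

    def test_gap_tolerance_merges_runs(self):
        a, b = self._series({3, 4, 5, 7, 8, 9})
        assert len(extract_contacts(a, b, dt=1.0, gap_tol=0)) == 2
        merged = extract_contacts(a, b, dt=1.0, gap_tol=1)
        assert len(merged) == 1

    def test_touch_distance_controls_contact(self):
        a, b = self._series(set(range(15)))
        assert len(extract_contacts(a, b, dt=1.0, touch_dist=1)) == 1
        assert extract_contacts(a, b, dt=1.0, touch_dist=0) == []


class TestDurationFits:
    def test_exponential_mle_is_sample_mean(self):
        fit = fit_durations([2.0, 4.0, 6.0, 5.0, 3.0], "exponential")
        assert fit.tau == 4.0

    def test_exponential_requires_five_samples(self):
        with pytest.raises(ValueError, match=">= 5"):
            fit_durations([1.0, 2.0], "exponential")

    @pytest.mark.parametrize("n", [50, 500, 5000])
    def test_exponential_estimator_consistency(self, n):
        rng = np.random.default_rng(n)
        reps = 200
        taus = [fit_durations(rng.exponential(61.0, n), "exponential").tau
                for _ in range(reps)]
        sem = 61.0 / np.sqrt(n * reps)
        assert abs(np.mean(taus) - 61.0) < 5 * sem

    def test_mixture_recovers_bimodal_means(self):
        rng = np.random.default_rng(42)
        n = 1000
        comp = rng.random(n) < 0.6
        d = np.where(comp, rng.normal(45, 12, n), rng.normal(105, 15, n))
        fit = fit_durations(d, "gaussian-mixture", 2, seed=0)
        means = fit.means
        assert means[0] < means[1]                   # sorted ascending
        assert abs(means[1] - 105.0) / 105.0 < 0.10
        assert np.isclose(sum(fit.params["weights"]), 1.0)

    def test_mixture_fit_is_deterministic(self):
        rng = np.random.default_rng(3)
        d = np.concatenate([rng.normal(40, 10, 100), rng.normal(90, 10, 100)])
        f1 = fit_durations(d, "gaussian-mixture", 2, seed=0)
        f2 = fit_durations(d, "gaussian-mixture", 2, seed=0)
        assert f1.params == f2.params

    def test_mixture_sample_size_guard(self):
        with pytest.raises(ValueError, match="40"):
            fit_durations(np.ones(30), "gaussian-mixture", 2)


class TestColocalization:
    def _labels(self):
        labels = np.zeros((40, 40), int)
        for i, (r, c) in enumerate([(5, 5), (5, 25), (25, 5), (25, 25)], 1):
            labels[r:r + 6, c:c + 6] = i
        return labels

    def test_identical_masks_full_association(self):
        labels = self._labels()
        res = colocalization(labels, labels > 0)
        assert res.fraction_odt_in_fluo == 1.0
        assert res.fraction_fluo_in_odt == 1.0

    def test_disjoint_masks_zero_association(self):
        labels = self._labels()
        fluo = np.zeros((40, 40), bool)
        fluo[35:39, 35:39] = True
        res = colocalization(labels, fluo)
        assert res.fraction_odt_in_fluo == 0.0
        assert res.fraction_fluo_in_odt == 0.0

    def test_constructed_fraction_exact(self):
        """100 objects, 61 fully covered by the mask -> fraction 0.61."""
        labels = np.zeros((110, 110), int)
        fluo = np.zeros((110, 110), bool)
        for i in range(100):
            r, c = divmod(i, 10)
            labels[2 + 11 * r:6 + 11 * r, 2 + 11 * c:6 + 11 * c] = i + 1
            if i < 61:
                fluo[2 + 11 * r:6 + 11 * r, 2 + 11 * c:6 + 11 * c] = True
        res = colocalization(labels, fluo, overlap_frac=0.3)
        assert res.fraction_odt_in_fluo == 0.61
        assert res.n_odt == 100 and res.n_odt_associated == 61

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            colocalization(np.zeros((4, 4), int), np.zeros((5, 5), bool))

    def test_fractions_bounded(self):
        rng = np.random.default_rng(0)
        labels = (rng.random((30, 30)) < 0.2).astype(int)
        from skimage import measure
        labels = measure.label(labels)
        fluo = rng.random((30, 30)) < 0.3
        res = colocalization(labels, fluo)
        assert 0.0 <= res.fraction_odt_in_fluo <= 1.0
        assert 0.0 <= res.fraction_fluo_in_odt <= 1.0
        assert res.n_odt_associated <= res.n_odt
        assert res.n_fluo_associated <= res.n_fluo


class TestMotionBlurLimit:
    def test_constant_speeds(self):
        assert motion_blur_limit(np.full(100, 100.0), 200.0, 0.95) == 2.0

    def test_proportional_to_resolution(self):
        rng = np.random.default_rng(1)
        speeds = rng.lognormal(4.0, 0.5, 1000)
        t1 = motion_blur_limit(speeds, 200.0)
        t2 = motion_blur_limit(speeds, 400.0)
        assert np.isclose(t2, 2 * t1)

    def test_lognormal_quantile_closed_form(self):
        rng = np.random.default_rng(2)
        mu, sd = 4.5, 0.6
        speeds = rng.lognormal(mu, sd, 200_000)
        expected = 200.0 / np.exp(mu + sd * stats.norm.ppf(0.95))
        assert np.isclose(motion_blur_limit(speeds, 200.0, 0.95), expected,
                          rtol=0.02)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="empty"):
            motion_blur_limit([], 200.0)
        with pytest.raises(ValueError, match="quantile"):
            motion_blur_limit([1.0], 200.0, 1.5)
        with pytest.raises(ValueError, match="positive"):
            motion_blur_limit([0.0, 1.0], 200.0)
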