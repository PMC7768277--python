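"""Radial line scans, normalization, binning and dispersion profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from punctaquant.golgi import (
    CellGeometry,
    GeometryError,
    LinescanProfile,
    PixelSamples,
    average_profiles,
    bin_profile,
    correct_oversampling,
    dispersion_profile,
    mask_and_normalize,
    radial_linescans,
    subtract_background,
)
from punctaquant.simulate import GolgiSimConfig, simulate_golgi_image


class TestGeometry:
    def test_circle_radii_are_constant(self, circle_geometry):
        assert circle_geometry.cell_radius_at(123.4) == pytest.approx(80.0)
        assert circle_geometry.nucleus_radius_at(10.0) == pytest.approx(24.0)

    def test_nucleus_reaching_cell_rejected(self):
        with pytest.raises(GeometryError):
            CellGeometry.from_ellipses((50, 50), (30.0, 30.0), (30.0, 40.0))

    def test_mask_round_trip_matches_ellipse_radii(self, circle_geometry):
        mask = circle_geometry.to_label_mask((192, 192))
        rec = CellGeometry.from_label_mask(mask)
        assert rec.centroid[0] == pytest.approx(95.5, abs=0.5)
        np.testing.assert_allclose(rec.cell_radii, circle_geometry.cell_radii, atol=1.0)
        np.testing.assert_allclose(rec.nucleus_radii, circle_geometry.nucleus_radii, atol=1.0)


class TestRadialLinescans:
    def test_uniform_image_sampled_uniformly(self, circle_geometry):
        img = np.full((192, 192), 5.0)
        for p in radial_linescans(img, circle_geometry, n_angles=8):
            np.testing.assert_allclose(p.intensities, 5.0)

    def test_symmetric_image_gives_identical_profiles(self, circle_geometry):
        yy, xx = np.mgrid[0:192, 0:192]
        img = np.hypot(xx - 95.5, yy - 95.5)  # radially symmetric
        profiles = radial_linescans(img, circle_geometry, n_angles=4)
        for p in profiles[1:]:
            np.testing.assert_allclose(p.intensities, profiles[0].intensities, atol=1e-9)

    def test_punctum_found_on_nearest_scan(self, circle_geometry):
        r_true, theta = 47.0, 72.0
        cx = 95.5 + r_true * np.cos(np.radians(theta))
        cy = 95.5 + r_true * np.sin(np.radians(theta))
        yy, xx = np.mgrid[0:192, 0:192]
        img = 1000 * np.exp(-0.5 * ((xx - cx) ** 2 + (yy - cy) ** 2) / 1.5**2)
        profiles = radial_linescans(img, circle_geometry)
        scan = profiles[72]
        assert abs(scan.distances[np.argmax(scan.intensities)] - r_true) <= 1.0

    def test_centroid_outside_image_rejected(self):
        geom = CellGeometry.from_ellipses((500.0, 500.0), (24.0, 24.0), (80.0, 80.0))
        with pytest.raises(GeometryError):
            radial_linescans(np.zeros((192, 192)), geom)


class TestBackgroundSubtraction:
    def _profiles(self, n=4, length=60, value=100.0):
        d = np.arange(float(length))
        return [
            LinescanProfile(a, d, np.full(length, value), xs=d, ys=np.full(length, a))
            for a in np.arange(n) * 90.0
        ]

    def test_identical_background_zeroes_profiles(self):
        profs = self._profiles()
        out = subtract_background(profs, profs[0])
        for p in out:
            np.testing.assert_allclose(p.intensities, 0.0)

    def test_zero_background_is_identity(self):
        profs = self._profiles()
        bg = LinescanProfile(200.0, np.arange(60.0), np.zeros(60))
        out = subtract_background(profs, bg)
        for p, q in zip(out, profs):
            np.testing.assert_allclose(p.intensities, q.intensities)

    def test_degenerate_background_rejected(self):
        bg = LinescanProfile(200.0, np.array([0.0]), np.array([1.0]))
        with pytest.raises(GeometryError):
            subtract_background(self._profiles(), bg)

    def test_gradient_removed_puncta_amplitudes_preserved(self):
        """Radial background + one punctum: subtraction keeps the punctum."""
        cfg = GolgiSimConfig(
            cell_axes=(80.0, 80.0), nucleus_axes=(24.0, 24.0),
            n_puncta=1, dispersion_scale=0.5, background_amplitude=200.0, seed=17,
        )
        img, geom, truth = simulate_golgi_image(cfg)
        cfg0 = GolgiSimConfig(
            cell_axes=(80.0, 80.0), nucleus_axes=(24.0, 24.0),
            n_puncta=1, dispersion_scale=0.5, background_amplitude=0.0, seed=17,
        )
        img0, _, _ = simulate_golgi_image(cfg0)
        from punctaquant.golgi import background_scan

        profs = radial_linescans(img, geom)
        cleaned = subtract_background(profs, background_scan(img, geom))
        peak_clean = max(p.intensities.max() for p in cleaned)
        peak_true = max(p.intensities.max() for p in radial_linescans(img0, geom))
        assert peak_clean == pytest.approx(peak_true, rel=0.05)


class TestMaskAndNormalize:
    def test_affine_mapping_of_boundary_and_midpoint(self, circle_geometry):
        d = np.array([24.0, 52.0, 80.0])  # nuclear edge, midway, cell boundary
        p = LinescanProfile(0.0, d, np.array([1.0, 2.0, 3.0]), xs=d + 95.5, ys=np.full(3, 95.5))
        s = mask_and_normalize(p, circle_geometry)
        np.testing.assert_allclose(s.norm_dist, [0.0, 0.5, 1.0], atol=1e-9)

    def test_nuclear_samples_dropped(self, circle_geometry):
        d = np.arange(0.0, 81.0)
        p = LinescanProfile(0.0, d, d, xs=d + 95.5, ys=np.full(81, 95.5))
        s = mask_and_normalize(p, circle_geometry)
        assert s.norm_dist.min() == pytest.approx(0.0)
        assert len(s.norm_dist) == 81 - 24

    def test_degenerate_geometry_rejected(self):
        geom = CellGeometry.from_ellipses((95.5, 95.5), (24.0, 24.0), (80.0, 80.0))
        geom.nucleus_radii = geom.cell_radii.copy()  # force violation post-validation
        p = LinescanProfile(0.0, np.arange(0.0, 81.0), np.zeros(81),
                            xs=np.arange(81.0), ys=np.zeros(81))
        with pytest.raises(GeometryError):
            mask_and_normalize(p, geom)


class TestOversampling:
    def _samples(self, angle, coords, intensities):
        coords = np.asarray(coords, float)
        return PixelSamples(
            norm_dist=np.linspace(0, 1, len(coords)),
            intensity=np.asarray(intensities, float),
            px=coords[:, 0].astype(int),
            py=coords[:, 1].astype(int),
            angle=np.full(len(coords), float(angle)),
        )

    def test_shared_pixel_counted_once_first_angle_wins(self):
        a = self._samples(0.0, [[10, 10], [11, 10]], [5.0, 6.0])
        b = self._samples(1.0, [[10, 10], [12, 10]], [7.0, 8.0])
        merged = correct_oversampling([b, a])  # order given reversed; ascending wins
        key = set(zip(merged.px.tolist(), merged.py.tolist()))
        assert key == {(10, 10), (11, 10), (12, 10)}
        shared = merged.intensity[(merged.px == 10) & (merged.py == 10)]
        assert shared.tolist() == [5.0]  # from angle 0, not angle 1

    def test_centre_nearest_sample_wins_with_coords(self):
        import numpy as np
        from punctaquant.golgi import PixelSamples, correct_oversampling

        far = PixelSamples(np.array([0.2]), np.array([9.0]), np.array([10]),
                           np.array([10]), np.array([0.0]),
                           xs=np.array([10.05]), ys=np.array([10.05]))
        near = PixelSamples(np.array([0.3]), np.array([4.0]), np.array([10]),
                            np.array([10]), np.array([5.0]),
                            xs=np.array([10.45]), ys=np.array([10.55]))
        merged = correct_oversampling([far, near])
        assert merged.intensity.tolist() == [4.0]  # nearest pixel centre wins

    def test_unique_peripheral_pixels_all_retained(self):
        a = self._samples(0.0, [[50, 10], [60, 10]], [1.0, 2.0])
        b = self._samples(90.0, [[10, 50], [10, 60]], [3.0, 4.0])
        merged = correct_oversampling([a, b])
        assert len(merged.intensity) == 4

    def test_retained_count_equals_distinct_pixel_count(self, circle_geometry):
        """Counting oracle: dedup size equals the set of distinct integer pixels."""
        img = np.random.default_rng(0).uniform(0, 100, (192, 192))
        profiles = radial_linescans(img, circle_geometry, n_angles=90)
        samples = [mask_and_normalize(p, circle_geometry) for p in profiles]
        merged = correct_oversampling(samples)
        distinct = {
            (int(x), int(y))
            for s in samples
            for x, y in zip(s.px.tolist(), s.py.tolist())
        }
        assert len(merged.intensity) == len(distinct)


class TestBinProfile:
    def _samples(self, dists, intens):
        dists = np.asarray(dists, float)
        return PixelSamples(dists, np.asarray(intens, float),
                            np.arange(len(dists)), np.arange(len(dists)),
                            np.zeros(len(dists)))

    def test_single_occupied_bin(self):
        prof = bin_profile(self._samples([0.30] * 10, [100.0] * 10))
        assert prof.mean_intensity[6] == pytest.approx(100.0)
        assert np.isnan(np.delete(prof.mean_intensity, 6)).all()

    def test_top_k_selection_arithmetic(self):
        # 300 samples 1..300 in one bin: top 200 are 101..300, mean 200.5
        prof = bin_profile(self._samples([0.52] * 300, np.arange(1.0, 301.0)))
        assert prof.mean_intensity[10] == pytest.approx(200.5)
        assert prof.n_pixels[10] == 200

    def test_top_k_larger_than_population_is_plain_mean(self):
        prof = bin_profile(self._samples([0.1, 0.12, 0.14], [1.0, 2.0, 3.0]), top_k=200)
        assert prof.mean_intensity[2] == pytest.approx(2.0)

    def test_out_of_range_distance_rejected(self):
        with pytest.raises(ValueError):
            bin_profile(self._samples([1.2], [1.0]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50.0), seed=st.integers(0, 100))
    def test_intensity_equivariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        n = 150
        s = self._samples(rng.uniform(0, 1, n), rng.uniform(0, 1000, n))
        a = bin_profile(s)
        s2 = PixelSamples(s.norm_dist, s.intensity * scale, s.px, s.py, s.angle)
        b = bin_profile(s2)
        np.testing.assert_allclose(b.mean_intensity, a.mean_intensity * scale, rtol=1e-9)


class TestDispersionProfile:
    def test_clustered_cell_mass_near_nucleus(self, golgi_cell_factory):
        prof = golgi_cell_factory(0.0, seed=31)
        m = np.nan_to_num(prof.mean_intensity)
        assert m[:5].sum() / m.sum() >= 0.80

    def test_dispersed_cell_has_larger_mean_distance(self, golgi_cell_factory):
        lo = golgi_cell_factory(0.1, seed=41)
        hi = golgi_cell_factory(0.9, seed=42)
        assert hi.weighted_mean_distance() > lo.weighted_mean_distance()

    def test_uniform_cytoplasm_gives_flat_profile(self, circle_geometry):
        img = circle_geometry.to_label_mask((192, 192)).astype(float)
        img[img > 0] = 500.0  # constant intensity everywhere inside the cell
        prof = dispersion_profile(img, circle_geometry, background=False)
        m = prof.mean_intensity[~np.isnan(prof.mean_intensity)]
        assert m.max() / m.min() < 1.2

    def test_image_scaling_scales_profile(self, circle_geometry):
        cfg = GolgiSimConfig(cell_axes=(80.0, 80.0), nucleus_axes=(24.0, 24.0),
                             dispersion_scale=0.5, seed=55)
        img, geom, _ = simulate_golgi_image(cfg)
        a = dispersion_profile(img, geom, background=False)
        b = dispersion_profile(3.0 * img, geom, background=False)
        np.testing.assert_allclose(b.mean_intensity, 3.0 * a.mean_intensity, rtol=1e-9)


class TestAverageProfiles:
    def _profile(self, values):
        from punctaquant.golgi import DispersionProfile

        v = np.asarray(values, float)
        return DispersionProfile(np.arange(20) * 0.05, v, np.ones(20, int))

    def test_identical_cells_have_zero_sem(self):
        cells = [self._profile(np.arange(20.0))] * 3
        grp = average_profiles(cells)
        np.testing.assert_allclose(grp["sem"], 0.0, atol=1e-12)

    def test_two_cell_arithmetic(self):
        grp = average_profiles([self._profile(np.full(20, 1.0)), self._profile(np.full(20, 3.0))])
        np.testing.assert_allclose(grp["mean"], 2.0)
        np.testing.assert_allclose(grp["sem"], 1.0)

    def test_sem_consistent_with_definition(self):
        rng = np.random.default_rng(8)
        mat = rng.normal(100, 10, size=(26, 20))
        cells = [self._profile(row) for row in mat]
        grp = average_profiles(cells)
        np.testing.assert_allclose(grp["sem"], mat.std(axis=0, ddof=1) / np.sqrt(26), rtol=1e-9)

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            average_profiles([self._profile(np.zeros(20))])
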