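"""Image-pipeline operations against brute-force and analytic oracles."""

import numpy as np
import pytest
from scipy.integrate import quad

from _oracles import brute_force_otsu_mask, profile_from_signals, pulse_train_lag
from crossfeed.imaging import (
    AnalysisConfig,
    ColonyGeometry,
    ColonyImage,
    ColonyNotFoundError,
    DegenerateHistogramError,
    ImageAnalysisError,
    NoDecorrelationError,
    analyze_colony,
    arc_length,
    detect_outliers,
    equivalent_circle_transform,
    extract_annulus,
    fit_geometry,
    max_project,
    otsu_threshold,
    read_colony_tiff,
    sector_width,
    write_colony_tiff,
    yellow_frequency,
)


class TestMaxProject:
    def test_single_plane_identity(self):
        plane = np.arange(12.0).reshape(1, 3, 4)
        np.testing.assert_array_equal(max_project(plane), plane[0])

    def test_marks_plane_of_maximum(self):
        stack = np.zeros((5, 4, 4))
        for k in range(5):
            stack[k, 1, 2] = k
        assert max_project(stack)[1, 2] == 4

    def test_matches_exhaustive_loop(self):
        rng = np.random.default_rng(0)
        stack = rng.uniform(size=(7, 9, 11))
        proj = max_project(stack)
        for i in range(9):
            for j in range(11):
                assert proj[i, j] == max(stack[k, i, j] for k in range(7))

    def test_empty_stack_errors(self):
        with pytest.raises(ImageAnalysisError):
            max_project(np.zeros((4, 4)))


class TestOtsu:
    def test_two_valued_image(self):
        img = np.array([[10] * 20 + [200] * 20], dtype=np.uint8)
        t = otsu_threshold(img)
        assert 10 < t < 200

    def test_matches_brute_force_partition(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            # bimodal-ish 8-bit images of varying separation
            n = 400
            a = rng.normal(rng.uniform(40, 90), rng.uniform(5, 25), n)
            b = rng.normal(rng.uniform(140, 220), rng.uniform(5, 25), n)
            img = np.clip(np.concatenate([a, b]), 0, 255).astype(np.uint8)
            img = img.reshape(20, 40)
            mask = img > otsu_threshold(img)
            np.testing.assert_array_equal(mask, brute_force_otsu_mask(img))

    def test_offset_shifts_threshold(self):
        rng = np.random.default_rng(5)
        img = np.concatenate([rng.normal(30, 5, 500),
                              rng.normal(150, 10, 500)]).reshape(20, 50)
        t0 = otsu_threshold(img)
        t1 = otsu_threshold(img + 37.0)
        bin_width = (img.max() - img.min()) / 256
        assert t1 - t0 == pytest.approx(37.0, abs=2 * bin_width)

    def test_constant_image_errors(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(np.full((8, 8), 7.0))


def render_ellipse_mask(n, cx, cy, a, b, phi):
    yy, xx = np.mgrid[0:n, 0:n]
    x, y = xx - cx, yy - cy
    xr = np.cos(phi) * x + np.sin(phi) * y
    yr = -np.sin(phi) * x + np.cos(phi) * y
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


class TestFitGeometry:
    def test_recovers_known_ellipse_within_one_percent(self):
        mask = render_ellipse_mask(900, 450, 440, 400, 320, np.deg2rad(30))
        geom = fit_geometry(mask, pixel_size=2.0, rho_c=100.0)
        assert geom.a == pytest.approx(400 * 2.0, rel=0.01)
        assert geom.b == pytest.approx(320 * 2.0, rel=0.01)
        assert geom.phi == pytest.approx(np.deg2rad(30), abs=0.01)
        assert geom.center[0] == pytest.approx(450, abs=1.0)
        assert geom.center[1] == pytest.approx(440, abs=1.0)
        assert geom.rho_0 == pytest.approx((geom.a + geom.b) / 2)
        assert geom.l_growth == pytest.approx(geom.rho_0 - 100.0)

    def test_circle(self):
        mask = render_ellipse_mask(500, 250, 250, 180, 180, 0.0)
        geom = fit_geometry(mask, pixel_size=1.0, rho_c=50.0)
        assert geom.a == pytest.approx(180, rel=0.01)
        assert geom.b == pytest.approx(180, rel=0.01)
        assert geom.rho_0 == pytest.approx(180, rel=0.01)

    def test_satellite_blobs_ignored(self):
        mask = render_ellipse_mask(600, 300, 300, 200, 160, 0.5)
        clean = fit_geometry(mask, 1.0, 50.0)
        mask[20:30, 20:30] = True                   # far satellite blob
        with_blob = fit_geometry(mask, 1.0, 50.0)
        assert with_blob == clean

    def test_empty_mask_errors(self):
        with pytest.raises(ColonyNotFoundError):
            fit_geometry(np.zeros((10, 10), dtype=bool), 1.0)


class TestEquivalentCircleTransform:
    def geom(self, a, b, phi):
        return ColonyGeometry(center=(0, 0), a=a, b=b, phi=phi,
                              rho_c=1.0, pixel_size=1.0)

    def test_circle_identity(self):
        g = self.geom(100.0, 100.0, 0.0)
        pts = np.array([[3.0, 4.0], [-7.0, 2.0]])
        np.testing.assert_allclose(equivalent_circle_transform(pts, g), pts)

    def test_ellipse_boundary_maps_to_circle(self):
        g = self.geom(120.0, 80.0, 0.7)
        t = np.linspace(0, 2 * np.pi, 200)
        boundary = np.column_stack([120 * np.cos(t), 80 * np.sin(t)])
        c, s = np.cos(0.7), np.sin(0.7)
        rot = np.array([[c, -s], [s, c]])           # place at angle phi
        pts = boundary @ rot.T
        out = equivalent_circle_transform(pts, g)
        radii = np.hypot(out[:, 0], out[:, 1])
        np.testing.assert_allclose(radii, g.rho_0, rtol=0.005)

    def test_composition_with_inverse_is_identity(self):
        g = self.geom(120.0, 80.0, 0.7)
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(50, 2)) * 40
        out = equivalent_circle_transform(pts, g)
        c, s = np.cos(g.phi), np.sin(g.phi)
        m = np.diag([g.rho_0 / g.a, g.rho_0 / g.b]) @ np.array([[c, s], [-s, c]])
        back = out @ np.linalg.inv(m).T
        np.testing.assert_allclose(back, pts, atol=1e-9)


class TestArcLength:
    def test_circle(self):
        assert arc_length(1.3, 50.0, 50.0) == pytest.approx(65.0, rel=1e-12)

    def test_zero_angle(self):
        assert arc_length(0.0, 100.0, 80.0) == 0.0

    @pytest.mark.parametrize("a,b,theta", [
        (1000.0, 800.0, 2 * np.pi),
        (1000.0, 800.0, 1.1),
        (560.0, 520.0, 4.0),
        (50.0, 10.0, 2 * np.pi),
    ])
    def test_matches_adaptive_quadrature(self, a, b, theta):
        expected, _ = quad(
            lambda v: np.sqrt(a ** 2 * np.sin(v) ** 2
                              + b ** 2 * np.cos(v) ** 2),
            0.0, theta, limit=200)
        assert arc_length(theta, a, b) == pytest.approx(expected, rel=1e-6)


class TestExtractAnnulus:
    def make_wedge_planes(self, n, cx, cy, a, b, phi, theta0):
        """Yellow wedge of equivalent-circle angular extent theta0."""
        yy, xx = np.mgrid[0:n, 0:n]
        x, y = (xx - cx) * 1.0, (yy - cy) * 1.0
        xr = np.cos(phi) * x + np.sin(phi) * y
        yr = -np.sin(phi) * x + np.cos(phi) * y
        rho0 = (a + b) / 2
        xe, ye = xr * rho0 / a, yr * rho0 / b
        theta = np.mod(np.arctan2(ye, xe), 2 * np.pi)
        inside = np.hypot(xe, ye) <= rho0
        yellow = (inside & (theta < theta0)).astype(float)
        blue = (inside & (theta >= theta0)).astype(float)
        return {"yellow": yellow, "blue": blue}

    def geometry(self, cx, cy, a, b, phi):
        return ColonyGeometry(center=(cx, cy), a=a, b=b, phi=phi,
                              rho_c=50.0, pixel_size=1.0)

    def test_wedge_occupies_predicted_arc_fraction(self):
        a, b, phi, theta0 = 300.0, 260.0, 0.6, 1.1
        planes = self.make_wedge_planes(700, 350, 350, a, b, phi, theta0)
        geom = self.geometry(350, 350, a, b, phi)
        profile = extract_annulus(planes, geom)
        for i, t in enumerate(profile.fractional_radii):
            frac = np.mean(profile.signals["yellow"][i] > 0.5)
            expected = (arc_length(theta0, t * a, t * b)
                        / arc_length(2 * np.pi, t * a, t * b))
            assert frac == pytest.approx(expected, abs=0.02)

    def test_degenerate_band_gives_single_ellipse(self):
        planes = self.make_wedge_planes(700, 350, 350, 300, 260, 0.0, 1.0)
        geom = self.geometry(350, 350, 300.0, 260.0, 0.0)
        profile = extract_annulus(planes, geom, band=(0.9, 0.9))
        assert profile.n_ellipses == 1

    def test_uniform_colony_gives_constant_profiles(self):
        planes = {"yellow": np.full((500, 500), 5.0),
                  "blue": np.full((500, 500), 2.0)}
        geom = self.geometry(250, 250, 200.0, 180.0, 0.3)
        profile = extract_annulus(planes, geom)
        for sig in profile.signals["yellow"]:
            np.testing.assert_allclose(sig, 5.0, rtol=1e-9)

    def test_band_leaving_image_errors(self):
        planes = {"yellow": np.zeros((100, 100)), "blue": np.zeros((100, 100))}
        geom = self.geometry(50, 50, 80.0, 70.0, 0.0)
        with pytest.raises(ImageAnalysisError):
            extract_annulus(planes, geom)


class TestYellowFrequency:
    def test_blue_zero_gives_one(self):
        profile = profile_from_signals(
            {"yellow": [np.ones(100)], "blue": [np.zeros(100)]})
        assert yellow_frequency(profile) == 1.0

    def test_equal_channels_give_half(self):
        sig = np.random.default_rng(0).uniform(size=100)
        profile = profile_from_signals({"yellow": [sig], "blue": [sig.copy()]})
        assert yellow_frequency(profile) == pytest.approx(0.5)

    def test_zero_intensity_errors(self):
        profile = profile_from_signals(
            {"yellow": [np.zeros(10)], "blue": [np.zeros(10)]})
        with pytest.raises(ImageAnalysisError):
            yellow_frequency(profile)


def square_wave(n, s_a, s_b, high_first=True):
    """Periodic two-level pattern with widths s_a (high) and s_b (low)."""
    period = s_a + s_b
    pos = np.arange(n) % period
    x = (pos < s_a).astype(float)
    return x if high_first else 1.0 - x


class TestSectorWidth:
    def test_equal_sectors_match_pulse_train_lag(self):
        s = 50
        sig = square_wave(1000, s, s)
        profile = profile_from_signals({"yellow": [sig], "blue": [1 - sig]})
        lag = sector_width(profile, "yellow")
        assert lag == pytest.approx(pulse_train_lag(s, s), abs=1.0)
        assert lag == pytest.approx(0.4 * s, abs=1.0)

    @pytest.mark.parametrize("s_y,s_b", [(80, 20), (30, 70), (60, 60)])
    def test_unequal_sectors_and_channel_symmetry(self, s_y, s_b):
        n = (s_y + s_b) * 12
        y = square_wave(n, s_y, s_b)
        profile = profile_from_signals({"yellow": [y], "blue": [1 - y]})
        expected = pulse_train_lag(s_y, s_b)
        lag_y = sector_width(profile, "yellow")
        lag_b = sector_width(profile, "blue")
        assert lag_y == pytest.approx(expected, abs=1.0)
        assert lag_b == pytest.approx(lag_y, abs=1e-9)

    def test_threshold_one_gives_near_zero_lag(self):
        sig = square_wave(1000, 50, 50)
        profile = profile_from_signals({"yellow": [sig], "blue": [1 - sig]})
        assert sector_width(profile, "yellow", threshold=1.0) <= 1.0

    def test_affine_intensity_invariance(self):
        sig = square_wave(900, 40, 60)
        profile1 = profile_from_signals({"yellow": [sig], "blue": [1 - sig]})
        profile2 = profile_from_signals(
            {"yellow": [7.0 + 3.5 * sig], "blue": [1 - sig]})
        assert sector_width(profile2, "yellow") == pytest.approx(
            sector_width(profile1, "yellow"), abs=1e-9)

    def test_constant_signal_errors(self):
        profile = profile_from_signals(
            {"yellow": [np.full(100, 3.0)], "blue": [np.ones(100)]})
        with pytest.raises(ImageAnalysisError):
            sector_width(profile, "yellow")

    def test_averaging_across_ellipses(self):
        # two ellipses with different sector widths -> lag between the two
        a = square_wave(1000, 40, 40)
        b = square_wave(1000, 60, 60)
        profile = profile_from_signals({"yellow": [a, b],
                                        "blue": [1 - a, 1 - b]})
        lag = sector_width(profile, "yellow")
        assert 0.4 * 40 < lag < 0.4 * 60


class TestDetectOutliers:
    def test_identical_values_kept(self):
        kept, excl = detect_outliers([5, 5, 5, 5, 5])
        assert not excl.any() and kept.size == 5

    def test_gross_outlier_gets_zero_weight(self):
        kept, excl = detect_outliers([5, 5, 5, 5, 500])
        assert list(excl) == [False, False, False, False, True]

    def test_moderate_spread_with_outlier(self):
        kept, excl = detect_outliers([1, 2, 3, 4, 100])
        assert list(kept) == [1, 2, 3, 4]

    def test_two_equal_clusters_not_excluded(self):
        kept, excl = detect_outliers([1, 1, 1, 100, 100, 100])
        assert not excl.any()

    def test_needs_three_values(self):
        with pytest.raises(ValueError):
            detect_outliers([1, 2])


class TestAnalyzeColony:
    def test_blank_image_raises_colony_not_found(self):
        img = ColonyImage({"yellow": np.zeros((2, 64, 64)),
                           "blue": np.zeros((2, 64, 64))}, pixel_size=1.0)
        with pytest.raises(ColonyNotFoundError):
            analyze_colony(img, AnalysisConfig(rho_c=10.0))

    def test_border_touching_colony_warns_but_measures(self, small_colony,
                                                       small_config):
        spec, image, _ = small_colony
        cropped = ColonyImage(
            {ch: arr[:, 25:, :] for ch, arr in image.channels.items()},
            pixel_size=image.pixel_size)
        meas, geom = analyze_colony(cropped, small_config)
        assert "touches_border" in meas.flags
        assert 0.0 < meas.f_yellow < 1.0

    def test_frequencies_of_both_channels_sum_to_one(self, small_colony,
                                                     small_config):
        spec, image, _ = small_colony
        meas, _ = analyze_colony(image, small_config)
        f_blue = meas.F_B / (meas.F_Y + meas.F_B)
        assert meas.f_yellow + f_blue == pytest.approx(1.0, abs=1e-12)


class TestTiffRoundTrip:
    def test_write_read_preserves_data_and_pixel_size(self, tmp_path):
        rng = np.random.default_rng(0)
        img = ColonyImage(
            {"yellow": rng.uniform(size=(3, 32, 32)).astype(np.float32),
             "blue": rng.uniform(size=(3, 32, 32)).astype(np.float32)},
            pixel_size=1.3)
        path = tmp_path / "colony.tif"
        write_colony_tiff(path, img)
        back = read_colony_tiff(path)
        assert back.pixel_size == pytest.approx(1.3, rel=1e-4)
        np.testing.assert_allclose(back.channels["yellow"],
                                   img.channels["yellow"], rtol=1e-6)
        np.testing.assert_allclose(back.channels["blue"],
                                   img.channels["blue"], rtol=1e-6)

    def test_missing_pixel_size_errors(self, tmp_path):
        import tifffile
        arr = np.zeros((2, 2, 16, 16), dtype=np.float32)
        path = tmp_path / "noscale.tif"
        tifffile.imwrite(path, arr)
        with pytest.raises(ImageAnalysisError):
            read_colony_tiff(path)
        img = read_colony_tiff(path, pixel_size=2.0)
        assert img.pixel_size == 2.0
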