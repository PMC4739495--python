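"""Detection, Gaussian fitting, drift correction, rendering."""

import numpy as np
import pandas as pd
import pytest

from spineneck import (correct_drift, detect_spots, estimate_pointing_accuracy,
                       fit_gaussian_2d, render_superres, simulate_spot_movie)
from spineneck.localize import cluster_detections
from spineneck.synthetic import _integrated_gaussian


def psf_image(center, shape=(21, 21), sigma=1.3, photons=1000.0, offset=0.0):
    img = _integrated_gaussian(shape, np.array([center]), sigma, photons)
    return img + offset


class TestDetect:
    def test_blank_frame_yields_nothing(self):
        assert len(detect_spots(np.zeros((32, 32)))) == 0

    def test_single_psf_found_within_one_pixel(self):
        img = psf_image((10.3, 7.75), photons=2000.0)
        stack, _ = simulate_spot_movie([np.array([[10.3, 7.75]])], 1.3,
                                       2000.0, 10.0, (21, 21), 1)
        for frame in (img, stack[0]):
            cands = detect_spots(frame)
            assert len(cands) == 1
            r, c = cands[0]
            assert abs(c - 10.3) <= 1.0 and abs(r - 7.75) <= 1.0

    def test_two_psfs_found(self):
        img = psf_image((5.0, 10.0)) + psf_image((15.0, 10.0))
        assert len(detect_spots(img, threshold=1.0)) == 2


class TestGaussianFit:
    def test_noiseless_center_to_milli_pixel(self):
        img = psf_image((10.30, 7.75))
        loc = fit_gaussian_2d(img, (8, 10), pixel_nm=1.0, psf_sigma_px=1.3)
        assert loc.valid
        assert abs(loc.x_nm - 10.30) < 1e-3
        assert abs(loc.y_nm - 7.75) < 1e-3

    def test_flat_window_invalid_not_exception(self):
        loc = fit_gaussian_2d(np.full((21, 21), 7.0), (10, 10))
        assert not loc.valid

    def test_window_outside_image_raises(self):
        with pytest.raises(ValueError):
            fit_gaussian_2d(np.zeros((21, 21)), (1, 1), window=7)

    def test_poisson_precision_near_closed_form(self):
        # closed-form shot-noise precision of the unweighted LSQ estimator:
        # twice the information-bound variance, sigma^2 = 2 (s^2 + a^2/12) / N
        sigma, photons, n_rep = 1.3, 1500.0, 300
        stack, _ = simulate_spot_movie([np.array([[10.3, 10.6]])] * n_rep,
                                       sigma, photons, 0.0, (21, 21), 77)
        xs = []
        for frame in stack:
            loc = fit_gaussian_2d(frame, (11, 10), pixel_nm=1.0,
                                  psf_sigma_px=sigma)
            if loc.valid:
                xs.append(loc.x_nm)
        measured = np.std(xs)
        theory = np.sqrt(2.0 * (sigma ** 2 + 1.0 / 12.0) / photons)
        assert abs(measured - theory) / theory < 0.25

    def test_precision_scales_inverse_sqrt_photons(self):
        sigma = 1.3
        photon_grid = [300.0, 1000.0, 3000.0]
        sds = []
        for i, photons in enumerate(photon_grid):
            stack, _ = simulate_spot_movie([np.array([[10.3, 10.6]])] * 150,
                                           sigma, photons, 2.0, (21, 21), 50 + i)
            xs = [fit_gaussian_2d(f, (11, 10), pixel_nm=1.0,
                                  psf_sigma_px=sigma).x_nm for f in stack]
            sds.append(np.std(xs))
        slope = np.polyfit(np.log(photon_grid), np.log(sds), 1)[0]
        assert -0.6 <= slope <= -0.4


class TestDrift:
    @staticmethod
    def _fiducials(n_frames, drift_x, drift_y, noise, n_fid=2, seed=0):
        rng = np.random.default_rng(seed)
        frames = np.arange(n_frames)
        parts = []
        for k in range(n_fid):
            parts.append(pd.DataFrame({
                "fid_id": k, "frame": frames,
                "x_nm": 1000.0 * k + drift_x(frames) + rng.normal(0, noise, n_frames),
                "y_nm": 500.0 * k + drift_y(frames) + rng.normal(0, noise, n_frames)}))
        return pd.concat(parts, ignore_index=True)

    def test_zero_drift_leaves_locs_unchanged(self):
        fid = self._fiducials(200, lambda f: 0.0 * f, lambda f: 0.0 * f, 0.0)
        locs = pd.DataFrame({"frame": np.arange(200), "x_nm": 50.0,
                             "y_nm": 80.0})
        corrected, trace = correct_drift(locs, fid, n_frames=200)
        assert np.allclose(corrected["x_nm"], 50.0)
        assert np.allclose(trace.dx, 0.0) and trace.residual_rms_nm < 1e-9

    def test_linear_drift_corrected_below_2nm(self):
        fid = self._fiducials(500, lambda f: 0.5 * f, lambda f: -0.2 * f,
                              noise=1.0, seed=3)
        true_x, true_y = 2000.0, 300.0
        locs = pd.DataFrame({"frame": np.arange(500),
                             "x_nm": true_x + 0.5 * np.arange(500),
                             "y_nm": true_y - 0.2 * np.arange(500)})
        corrected, trace = correct_drift(locs, fid, n_frames=500)
        err = np.hypot(corrected["x_nm"] - true_x, corrected["y_nm"] - true_y)
        assert np.sqrt(np.mean(err ** 2)) < 2.0
        assert trace.residual_rms_nm < 2.0

    def test_trace_is_mean_of_fiducials(self):
        # two noiseless fiducials with different linear drifts -> average
        frames = np.arange(100)
        fid = pd.concat([
            pd.DataFrame({"fid_id": 0, "frame": frames, "x_nm": 1.0 * frames,
                          "y_nm": 0.0}),
            pd.DataFrame({"fid_id": 1, "frame": frames, "x_nm": 3.0 * frames,
                          "y_nm": 0.0})], ignore_index=True)
        locs = pd.DataFrame({"frame": [0], "x_nm": [0.0], "y_nm": [0.0]})
        _, trace = correct_drift(locs, fid, n_frames=100, smooth_window=0)
        assert np.allclose(trace.dx, 2.0 * frames)

    def test_idempotent_on_corrected_table(self):
        fid = self._fiducials(300, lambda f: 0.4 * f, lambda f: 0.1 * f, 0.5,
                              seed=9)
        locs = pd.DataFrame({"frame": np.arange(300),
                             "x_nm": 0.4 * np.arange(300),
                             "y_nm": 0.1 * np.arange(300)})
        corrected, trace = correct_drift(locs, fid, n_frames=300)
        fid2 = fid.copy()
        idx = fid2["frame"].to_numpy().astype(int)
        fid2["x_nm"] -= trace.dx[idx]
        fid2["y_nm"] -= trace.dy[idx]
        _, trace2 = correct_drift(corrected, fid2, n_frames=300)
        assert np.max(np.abs(trace2.dx)) < 1.5  # second pass ~ fiducial noise

    def test_missing_coverage_raises(self):
        fid = self._fiducials(100, lambda f: 0.0 * f, lambda f: 0.0 * f, 0.0)
        sparse = fid[fid["frame"] < 50]
        locs = pd.DataFrame({"frame": [0], "x_nm": [0.0], "y_nm": [0.0]})
        with pytest.raises(ValueError, match="coverage"):
            correct_drift(locs, sparse, n_frames=100)


class TestPointingAccuracy:
    def test_identical_detections_give_zero(self):
        locs = pd.DataFrame({"x_nm": [5.0] * 10, "y_nm": [7.0] * 10})
        pa = estimate_pointing_accuracy(locs)
        assert pa.sigma_x == 0.0 and pa.sigma_y == 0.0

    def test_gaussian_cluster_sd_recovered(self, rng):
        locs = pd.DataFrame({"x_nm": rng.normal(0, 12.2, 500),
                             "y_nm": rng.normal(0, 12.2, 500)})
        pa = estimate_pointing_accuracy(locs)
        assert 11.2 <= pa.sigma_x <= 13.2
        assert 11.2 <= pa.sigma_y <= 13.2

    def test_axes_reported_independently(self, rng):
        locs = pd.DataFrame({"x_nm": rng.normal(0, 5.0, 400),
                             "y_nm": rng.normal(0, 20.0, 400)})
        pa = estimate_pointing_accuracy(locs)
        assert pa.sigma_x < 10.0 < pa.sigma_y

    def test_too_few_detections_raise(self):
        with pytest.raises(ValueError, match="5"):
            estimate_pointing_accuracy(pd.DataFrame({"x_nm": [1.0] * 4,
                                                     "y_nm": [1.0] * 4}))

    def test_cluster_selection_radius(self):
        locs = pd.DataFrame({"x_nm": [0.0, 10.0, 200.0],
                             "y_nm": [0.0, 0.0, 0.0]})
        sel = cluster_detections(locs, seed_xy=(0.0, 0.0), radius_nm=50.0)
        assert len(sel) == 2


class TestRendering:
    def test_single_detection_unit_integral_and_peak(self):
        locs = pd.DataFrame({"x_nm": [100.0], "y_nm": [80.0]})
        img = render_superres(locs, sigma_render=10.0, pixel_out=5.0)
        assert img.data.sum() == pytest.approx(1.0, abs=0.01)
        r, c = np.unravel_index(img.data.argmax(), img.data.shape)
        assert abs(c * img.pixel_nm + img.origin_nm[0] - 100.0) <= img.pixel_nm
        assert abs(r * img.pixel_nm + img.origin_nm[1] - 80.0) <= img.pixel_nm

    def test_rendered_spot_fwhm_is_gaussian_identity(self):
        # sigma = 10 nm -> FWHM = 2 sqrt(2 ln 2) * 10 ~ 23.5 nm
        from spineneck import NeckAxisROI, extract_transverse_profile, fwhm_of_profile
        locs = pd.DataFrame({"x_nm": [0.0], "y_nm": [0.0]})
        img = render_superres(locs, 10.0, 2.0,
                              extent=(-80.0, 80.0, -80.0, 80.0))
        roi = NeckAxisROI((-50.0, 0.0), (50.0, 0.0), band_width=2.0)
        pos, vals = extract_transverse_profile(img, roi, transverse_extent=60.0,
                                               step_nm=2.0)
        res = fwhm_of_profile(pos, vals)
        assert res.fwhm_nm == pytest.approx(2 * np.sqrt(2 * np.log(2)) * 10.0,
                                            abs=0.8)

    def test_two_detections_match_closed_form(self):
        sigma, px = 10.0, 4.0
        locs = pd.DataFrame({"x_nm": [75.0, 125.0], "y_nm": [100.0, 100.0]})
        extent = (0.0, 200.0, 0.0, 200.0)
        img = render_superres(locs, sigma, px, extent=extent)
        row = int(round((100.0 - img.origin_nm[1]) / px))
        xs = img.origin_nm[0] + np.arange(img.data.shape[1]) * px
        profile = img.data[row]
        # analytic: per-pixel integral of the two Gaussians at y-row scale
        from scipy.special import erf
        def gauss_px(x0):
            gx = 0.5 * (erf((xs + px / 2 - x0) / (sigma * np.sqrt(2)))
                        - erf((xs - px / 2 - x0) / (sigma * np.sqrt(2))))
            gy = 0.5 * (erf((row * px + px / 2 - 100.0) / (sigma * np.sqrt(2)))
                        - erf((row * px - px / 2 - 100.0) / (sigma * np.sqrt(2))))
            return gx * gy
        analytic = gauss_px(75.0) + gauss_px(125.0)
        assert np.allclose(profile, analytic, atol=1e-9)

    def test_rendering_is_linear(self, rng):
        a = pd.DataFrame({"x_nm": rng.uniform(0, 100, 20),
                          "y_nm": rng.uniform(0, 100, 20)})
        b = pd.DataFrame({"x_nm": rng.uniform(0, 100, 15),
                          "y_nm": rng.uniform(0, 100, 15)})
        extent = (-60.0, 160.0, -60.0, 160.0)
        img_a = render_superres(a, 10.0, 5.0, extent=extent)
        img_b = render_superres(b, 10.0, 5.0, extent=extent)
        img_ab = render_superres(pd.concat([a, b]), 10.0, 5.0, extent=extent)
        assert np.allclose(img_ab.data, img_a.data + img_b.data, atol=1e-12)

    def test_empty_table_zero_image(self):
        img = render_superres(pd.DataFrame({"x_nm": [], "y_nm": []}), 10.0, 5.0)
        assert np.all(img.data == 0.0)

    def test_pixel_larger_than_sigma_rejected(self):
        with pytest.raises(ValueError):
            render_superres(pd.DataFrame({"x_nm": [0.0], "y_nm": [0.0]}),
                            sigma_render=5.0, pixel_out=10.0)
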