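"""Thermal-video tracker: oracle equivalences and recovery guarantees."""

import numpy as np
import pytest

from nirsmoco import simulate
from nirsmoco.containers import RoiSpec, TrackResult
from nirsmoco.tracking import (
    gaussian_pyramid,
    ncc_fft,
    otsu_segment,
    resultant_motion,
    track,
)


def otsu_bruteforce(frame: np.ndarray, nbins: int = 256):
    """Exhaustive scan of inter-class variance over every histogram split.

    Returns (threshold, max_variance, variance_at(threshold) callable) so
    callers can check that another implementation attains the same maximum
    (the argmax can sit on a plateau of equal-variance empty bins, where any
    plateau member is equally correct).
    """
    counts, edges = np.histogram(frame.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    total = counts.sum()
    variances = np.full(nbins - 1, -np.inf)
    for k in range(1, nbins):
        w0 = counts[:k].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (counts[:k] * centers[:k]).sum() / w0
        m1 = (counts[k:] * centers[k:]).sum() / w1
        variances[k - 1] = w0 * w1 * (m0 - m1) ** 2
    best = int(np.argmax(variances))
    def variance_of_threshold(thr: float) -> float:
        k = int(np.clip(np.searchsorted(centers, thr, side="right"), 1, nbins - 1))
        return variances[k - 1]
    return centers[best], variances[best], variance_of_threshold


def ncc_bruteforce(template: np.ndarray, image: np.ndarray) -> np.ndarray:
    """Direct spatial-domain normalized cross-correlation (the slow oracle)."""
    th, tw = template.shape
    t0 = template - template.mean()
    tn = np.sqrt((t0**2).sum())
    out = np.empty((image.shape[0] - th + 1, image.shape[1] - tw + 1))
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            win = image[i : i + th, j : j + tw]
            w0 = win - win.mean()
            wn = np.sqrt((w0**2).sum())
            out[i, j] = (w0 * t0).sum() / (wn * tn) if wn > 0 else 0.0
    return out


class TestOtsu:
    def test_two_class_separation(self):
        frame = np.full((10, 10), 23.0)
        frame[:, 5:] = 34.0
        thr, mask = otsu_segment(frame)
        assert 23.0 < thr < 34.0
        np.testing.assert_array_equal(mask, frame == 34.0)

    def test_constant_frame_rejected(self):
        with pytest.raises(ValueError):
            otsu_segment(np.full((8, 8), 30.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        frame = np.where(
            rng.uniform(size=(16, 16)) < 0.5,
            rng.normal(23, 1, (16, 16)),
            rng.normal(34, 1, (16, 16)),
        )
        thr, mask = otsu_segment(frame)
        _, vmax, variance_of = otsu_bruteforce(frame)
        # the returned bin attains the exhaustive maximum (exact up to
        # equal-variance plateau ties in the empty inter-mode gap)
        assert variance_of(thr) == pytest.approx(vmax, rel=1e-9)

    def test_exact_bin_on_dense_overlapping_modes(self):
        # overlapping modes leave no empty-bin plateau: argmax is unique
        rng = np.random.default_rng(11)
        frame = np.concatenate(
            [rng.normal(25, 2.0, 3000), rng.normal(31, 2.0, 3000)]
        ).reshape(60, 100)
        thr, _ = otsu_segment(frame)
        thr_bf, _, _ = otsu_bruteforce(frame)
        assert thr == pytest.approx(thr_bf, abs=1e-12)


class TestGaussianPyramid:
    def test_level1_halves_240x320_to_120x160(self):
        out = gaussian_pyramid(np.zeros((240, 320)), level=1)
        assert out.shape == (120, 160)

    def test_level0_identity(self):
        img = np.random.default_rng(0).normal(size=(31, 17))
        np.testing.assert_array_equal(gaussian_pyramid(img, 0), img)

    def test_constant_image_value_preserved(self):
        out = gaussian_pyramid(np.full((64, 64), 29.5), level=1)
        assert out.shape == (32, 32)
        np.testing.assert_allclose(out, 29.5, atol=1e-9)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            gaussian_pyramid(np.zeros((1, 1)), level=1)


class TestNcc:
    def test_self_match_peak(self):
        rng = np.random.default_rng(1)
        image = rng.normal(size=(32, 32))
        template = image[10:18, 5:13]
        surf = ncc_fft(template, image)
        assert surf.max() == pytest.approx(1.0, abs=1e-9)
        assert np.unravel_index(np.argmax(surf), surf.shape) == (10, 5)

    def test_mean_offset_invariance(self):
        rng = np.random.default_rng(2)
        template = rng.normal(size=(8, 8))
        surf = ncc_fft(template, np.pad(template, 4) + 7.3)
        assert surf.max() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_spatial_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        image = rng.normal(28, 3, size=(32, 32))
        template = rng.normal(28, 3, size=(8, 8))
        np.testing.assert_allclose(
            ncc_fft(template, image), ncc_bruteforce(template, image), atol=1e-8
        )

    def test_matches_skimage_match_template(self):
        # independent cross-check against the established implementation
        from skimage.feature import match_template

        rng = np.random.default_rng(9)
        image = rng.normal(size=(40, 30))
        template = rng.normal(size=(7, 9))
        np.testing.assert_allclose(
            ncc_fft(template, image), match_template(image, template), atol=1e-7
        )

    def test_zero_variance_template_rejected(self):
        with pytest.raises(ValueError):
            ncc_fft(np.ones((4, 4)), np.random.default_rng(0).normal(size=(16, 16)))

    def test_valid_mask_excludes_placements(self):
        rng = np.random.default_rng(3)
        image = rng.normal(size=(16, 16))
        template = image[4:8, 4:8]
        mask = np.zeros((16, 16), dtype=bool)
        mask[12:, 12:] = True  # true location not admissible
        surf = ncc_fft(template, image, valid_mask=mask)
        assert np.isneginf(surf[4, 4])
        assert np.isfinite(surf).any()


class TestTrack:
    def test_static_video_constant_centers(self):
        video, gt = simulate.synth_thermal_video(n_frames=5, noise_sd=0.0)
        det = gt.extras["face_center0"] + np.asarray(gt.extras["layout"]["detectors"][0])
        roi = RoiSpec(mroi_center=(float(det[0]), float(det[1])), mroi_height=80, mroi_width=80)
        res = track(video, roi)
        assert np.all(res.gamma > 0.999)
        np.testing.assert_allclose(
            res.mroi_centers - res.mroi_centers[0], 0.0, atol=1e-9
        )

    def test_known_trajectory_recovered(self, tracked_video):
        video, gt, roi, occl = tracked_video
        res = track(video, roi)
        expected = np.asarray(roi.mroi_center) + gt.true_trajectory
        err = np.abs(res.mroi_centers - expected)
        assert np.nanmax(err) <= 2.0  # +/- 2**level px contract

    def test_occluded_frames_and_only_those_are_nan(self, tracked_video):
        video, gt, roi, occl = tracked_video
        res = track(video, roi)
        assert set(np.flatnonzero(~res.retained)) == set(occl)
        # tracking resumes once correlation recovers above gamma_th
        assert res.retained[max(occl) + 1]

    def test_sroi_rigid_offsets(self, tracked_video):
        video, gt, roi, _ = tracked_video
        res = track(video, roi)
        for k in np.flatnonzero(res.retained):
            for s, (dr, dc, *_rest) in enumerate(roi.srois):
                np.testing.assert_array_equal(
                    res.sroi_centers[k, s] - res.mroi_centers[k], (dr, dc)
                )

    def test_translation_equivariance(self):
        base = make_shifted_pair(shift=(4, -6))
        video0, video1, roi = base
        c0 = track(video0, roi).mroi_centers[1]
        c1 = track(video1, roi).mroi_centers[1]
        np.testing.assert_allclose(c1 - c0, (4, -6), atol=2.0)

    def test_noise_never_raises_gamma(self):
        # degradation monotonicity, in expectation over seeds
        gammas = {sd: [] for sd in (0.0, 0.5)}
        for seed in range(3):
            for sd in gammas:
                video, gt = simulate.synth_thermal_video(
                    n_frames=2, noise_sd=sd, seed=seed
                )
                det = gt.extras["face_center0"] + np.asarray(
                    gt.extras["layout"]["detectors"][0]
                )
                roi = RoiSpec(
                    mroi_center=(float(det[0]), float(det[1])),
                    mroi_height=80, mroi_width=80, gamma_th=0.5,
                )
                gammas[sd].append(track(video, roi).gamma[1])
        assert np.mean(gammas[0.5]) < np.mean(gammas[0.0])


def make_shifted_pair(shift):
    """Two single-frame-pair videos differing by a rigid shift of frame 1."""
    traj0 = np.zeros((2, 2))
    traj1 = np.zeros((2, 2))
    traj1[1] = shift
    video0, gt = simulate.synth_thermal_video(n_frames=2, trajectory=traj0, seed=2)
    video1, _ = simulate.synth_thermal_video(n_frames=2, trajectory=traj1, seed=2)
    det = gt.extras["face_center0"] + np.asarray(gt.extras["layout"]["detectors"][0])
    roi = RoiSpec(mroi_center=(float(det[0]), float(det[1])), mroi_height=80, mroi_width=80)
    # compare frame-1 centers across the two videos
    return _second_frame_video(video0), _second_frame_video(video1), roi


def _second_frame_video(video):
    from nirsmoco.containers import ThermalVideo

    return ThermalVideo(frames=np.stack([video.frames[0], video.frames[1]]), fs=video.fs)


class TestResultantMotion:
    def _result(self, centers, fs=10.0):
        centers = np.asarray(centers, dtype=float)
        n = len(centers)
        roi = RoiSpec(mroi_center=(50.0, 50.0), mroi_height=10, mroi_width=10)
        return TrackResult(
            mroi_centers=centers,
            gamma=np.ones(n),
            sroi_centers=np.zeros((n, 0, 2)),
            fs=fs,
            roi=roi,
        )

    def test_three_four_five(self):
        res = self._result([[0, 0], [3, 4]])
        trace = resultant_motion(res)
        np.testing.assert_allclose(trace.values, [0.0, 5.0])

    def test_static_all_zero(self):
        res = self._result([[7, 7]] * 4)
        assert not resultant_motion(res).values.any()

    def test_nan_gap_linear_interpolation(self):
        res = self._result([[0, 0], [2, 0], [np.nan, np.nan], [4, 0]])
        trace = resultant_motion(res)
        assert trace.values[2] == pytest.approx(3.0)
        np.testing.assert_array_equal(trace.interpolated_mask, [0, 0, 1, 0])

    def test_all_nan_rejected(self):
        res = self._result([[np.nan, np.nan]] * 3)
        with pytest.raises(ValueError):
            resultant_motion(res)

    def test_resampling_to_target_fs(self):
        res = self._result([[0, 0], [1, 0], [2, 0], [3, 0]], fs=2.0)
        trace = resultant_motion(res, target_fs=4.0)
        assert trace.fs == 4.0
        np.testing.assert_allclose(trace.values[:4], [0.0, 0.5, 1.0, 1.5])
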