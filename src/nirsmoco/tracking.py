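"""Contactless optode tracking in thermal video.

Pipeline per frame: Otsu skin segmentation -> Gaussian-pyramid decimation ->
frequency-domain normalized cross-correlation (NCC) of a fixed template
captured on the initialization frame -> correlation gating at ``gamma_th``.
Frames whose best correlation gamma falls at or below the threshold are
discarded (NaN centers); slave ROIs translate rigidly with the master ROI.

The template is the frame-0 crop and is never updated: re-finding the same
target template each frame avoids drift accumulation.  Matching runs at the
decimated resolution (that is the point of the pyramid step), so recovered
centers carry an accuracy contract of +/- 2**pyramid_level full-resolution
pixels and no sub-pixel refinement is attempted.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve
from skimage.filters import threshold_otsu
from skimage.transform import pyramid_reduce

from .containers import MotionTrace, RoiSpec, ThermalVideo, TrackResult

__all__ = [
    "otsu_segment",
    "gaussian_pyramid",
    "ncc_fft",
    "track",
    "resultant_motion",
]


def otsu_segment(frame: np.ndarray) -> tuple[float, np.ndarray]:
    """Split a temperature frame into skin (warm) and background.

    The threshold maximizes inter-class variance over a 256-bin histogram of
    the frame's range; the skin mask is everything above it.
    """
    frame = np.asarray(frame, dtype=float)
    if np.ptp(frame) == 0:
        raise ValueError("constant frame: no foreground/background separation possible")
    thr = float(threshold_otsu(frame, nbins=256))
    return thr, frame > thr


def gaussian_pyramid(image: np.ndarray, level: int) -> np.ndarray:
    """``level`` rounds of Gaussian low-pass + factor-2 downsampling.

    Output dimensions are ``ceil(input / 2**level)`` (240x320 at level 1
    -> 120x160).  ``level=0`` is the identity.
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    out = np.asarray(image, dtype=float)
    for _ in range(level):
        if min(out.shape) < 2:
            raise ValueError("image too small to decimate further")
        out = pyramid_reduce(out, downscale=2, preserve_range=True)
    return out


def ncc_fft(
    template: np.ndarray,
    image: np.ndarray,
    valid_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Normalized cross-correlation surface over all valid template placements.

    The cross term is computed by FFT convolution and the local image
    mean/variance by running (integral-image) sums, so cost is independent of
    template size.  The returned surface has shape
    ``(H - h + 1, W - w + 1)``; entry ``(i, j)`` is the correlation
    coefficient of the template with the window whose top-left corner is
    ``(i, j)``.  Placements whose window *center* falls outside
    ``valid_mask`` (a boolean image-shaped array) are set to ``-inf`` so they
    can never win the maximum search.
    """
    template = np.asarray(template, dtype=float)
    image = np.asarray(image, dtype=float)
    th, tw = template.shape
    if th > image.shape[0] or tw > image.shape[1]:
        raise ValueError("template must be smaller than the image")
    t0 = template - template.mean()
    t_ss = float((t0 ** 2).sum())
    if t_ss == 0:
        raise ValueError("template has zero variance")

    cross = fftconvolve(image, t0[::-1, ::-1], mode="valid")

    # running window sums via padded cumulative sums
    def _window_sums(img: np.ndarray) -> np.ndarray:
        c = np.cumsum(np.cumsum(img, axis=0), axis=1)
        c = np.pad(c, ((1, 0), (1, 0)))
        return (
            c[th:, tw:] - c[:-th, tw:] - c[th:, :-tw] + c[:-th, :-tw]
        )

    n = th * tw
    win_sum = _window_sums(image)
    win_sum2 = _window_sums(image ** 2)
    win_var_ss = np.maximum(win_sum2 - win_sum ** 2 / n, 0.0)

    denom = np.sqrt(win_var_ss * t_ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        surface = np.where(denom > 1e-12 * t_ss, cross / denom, 0.0)
    np.clip(surface, -1.0, 1.0, out=surface)

    if valid_mask is not None:
        centers = valid_mask[th // 2 : th // 2 + surface.shape[0],
                             tw // 2 : tw // 2 + surface.shape[1]]
        surface = np.where(centers, surface, -np.inf)
    return surface


def _mroi_bounds(roi: RoiSpec, shape: tuple[int, int]) -> tuple[int, int, int, int]:
    r0 = int(round(roi.mroi_center[0] - roi.mroi_height / 2))
    c0 = int(round(roi.mroi_center[1] - roi.mroi_width / 2))
    r1, c1 = r0 + roi.mroi_height, c0 + roi.mroi_width
    if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
        raise ValueError("mROI exceeds frame boundaries")
    return r0, c0, r1, c1


def track(video: ThermalVideo, roi: RoiSpec) -> TrackResult:
    """Follow the master ROI across a thermal video.

    The template is cropped from the *decimated* initialization frame (so
    template and search image share one smoothing history), matching is
    restricted to placements centered on Otsu-segmented skin, and frames
    where the best correlation gamma <= ``roi.gamma_th`` — or where the skin
    mask leaves no admissible placement — are discarded with NaN centers.
    """
    level = roi.pyramid_level
    scale = 2 ** level
    r0, c0, r1, c1 = _mroi_bounds(roi, video.frame_shape)

    init_dec = gaussian_pyramid(video.frames[0], level)
    template = init_dec[r0 // scale : max(r0 // scale + 1, r1 // scale),
                        c0 // scale : max(c0 // scale + 1, c1 // scale)]
    th, tw = template.shape
    # decimated-grid coordinates of the template center on frame 0
    tpl_center0 = np.array([r0 // scale + th // 2, c0 // scale + tw // 2])

    n_frames = video.n_frames
    centers = np.full((n_frames, 2), np.nan)
    gammas = np.full(n_frames, np.nan)
    offsets = np.array([(s[0], s[1]) for s in roi.srois], dtype=float).reshape(-1, 2)
    sroi_centers = np.full((n_frames, len(roi.srois), 2), np.nan)

    for k in range(n_frames):
        frame_dec = video.frames[k] if level == 0 else gaussian_pyramid(video.frames[k], level)
        try:
            _, skin = otsu_segment(frame_dec)
        except ValueError:
            continue  # constant frame -> discarded
        if not skin.any():
            continue
        surface = ncc_fft(template, frame_dec, valid_mask=skin)
        best = np.unravel_index(np.argmax(surface), surface.shape)
        gamma = surface[best]
        if not np.isfinite(gamma):
            continue  # skin mask admitted no placement
        gammas[k] = gamma
        if gamma <= roi.gamma_th:
            continue  # tracking failure: NaN output, resume when gamma recovers
        center_dec = np.array([best[0] + th // 2, best[1] + tw // 2])
        center_full = (
            np.asarray(roi.mroi_center, dtype=float)
            + (center_dec - tpl_center0) * scale
        )
        centers[k] = center_full
        if len(roi.srois):
            sroi_centers[k] = center_full[None, :] + offsets

    return TrackResult(
        mroi_centers=centers,
        gamma=gammas,
        sroi_centers=sroi_centers,
        fs=video.fs,
        roi=roi,
    )


def resultant_motion(result: TrackResult, target_fs: float | None = None) -> MotionTrace:
    """Reduce tracked centers to a 1-D resultant displacement trace.

    Displacement per frame is the Euclidean norm of ``center - center_ref``
    where the reference is the first retained frame; NaN gaps (discarded
    frames) are filled by linear interpolation and flagged, and the trace is
    resampled (linearly) to ``target_fs`` when that differs from the video
    frame rate.
    """
    retained = result.retained
    if retained.sum() < 2:
        raise ValueError("fewer than 2 retained frames: no motion trace possible")
    ref = result.mroi_centers[np.argmax(retained)]
    disp = np.linalg.norm(result.mroi_centers - ref[None, :], axis=1)
    nan = np.isnan(disp)
    idx = np.arange(len(disp))
    filled = disp.copy()
    filled[nan] = np.interp(idx[nan], idx[~nan], disp[~nan])
    trace = MotionTrace(values=filled, fs=result.fs, interpolated_mask=nan)
    if target_fs is not None and abs(target_fs - result.fs) > 1e-9:
        t_old = np.arange(len(filled)) / result.fs
        t_new = np.arange(int(round(t_old[-1] * target_fs)) + 1) / target_fs
        values = np.interp(t_new, t_old, filled)
        mask = np.interp(t_new, t_old, nan.astype(float)) > 0
        trace = MotionTrace(values=values, fs=target_fs, interpolated_mask=mask)
    return trace
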