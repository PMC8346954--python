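"""Reference motion-correction methods used for benchmarking.

Four standard fNIRS artifact-correction families, each re-implemented from
its originating publication at a conventional parameterization:

* discrete-wavelet outlier filtering (Molavi & Dumont style): detail
  coefficients outside an interquartile-range band are zeroed;
* PCA filtering (Zhang/Wilcox style): the top-variance spatial components
  across channels are subtracted;
* spline subtraction (MARA style): a smoothing spline fitted inside each
  flagged artifact segment is removed and the record re-leveled;
* correlation-based signal improvement (CBSI, Cui style): oxy- and
  deoxy-hemoglobin are forced to perfect anticorrelation, cancelling
  common-mode artifacts.

All are pure, seedless functions preserving length and sampling rate.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.interpolate import UnivariateSpline

from .containers import FnirsRecording

__all__ = [
    "wavelet_iqr_correct",
    "pca_correct",
    "spline_mara_correct",
    "cbsi_correct",
    "segments_from_motion",
]


def wavelet_iqr_correct(
    signal: np.ndarray,
    iqr_factor: float = 1.5,
    wavelet: str = "db5",
    level: int | None = None,
) -> np.ndarray:
    """Zero outlying discrete-wavelet detail coefficients and reconstruct.

    Per decomposition level, coefficients outside
    ``[q1 - f*IQR, q3 + f*IQR]`` of that level's coefficient distribution
    are set to zero; approximation coefficients pass through.  An infinite
    ``iqr_factor`` reduces to the identity (within reconstruction
    round-off).
    """
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    wav = pywt.Wavelet(wavelet)
    max_level = pywt.dwt_max_level(n, wav.dec_len)
    level = max_level if level is None else min(level, max_level)
    coeffs = pywt.wavedec(signal, wav, level=level, mode="symmetric")
    cleaned = [coeffs[0]]
    for d in coeffs[1:]:
        if np.isfinite(iqr_factor):
            q1, q3 = np.percentile(d, [25, 75])
            iqr = q3 - q1
            lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
            d = np.where((d < lo) | (d > hi), 0.0, d)
        cleaned.append(d)
    return pywt.waverec(cleaned, wav, mode="symmetric")[:n]


def pca_correct(
    recording: FnirsRecording,
    n_components: int = 1,
) -> tuple[FnirsRecording, float]:
    """Remove the top-variance spatial principal components across channels.

    The channels x time matrix is temporally mean-centered per channel, its
    spatial covariance eigendecomposed, and the projection onto the top
    ``n_components`` eigenvectors subtracted.  Returns the corrected
    recording and the fraction of variance removed (sum of the top
    eigenvalues over the total).
    """
    n_ch = recording.n_channels
    if n_ch < 2:
        raise ValueError("PCA correction needs >= 2 channels")
    if n_components >= n_ch:
        raise ValueError("n_components must be < n_channels")
    out = recording.copy()
    if n_components == 0:
        return out, 0.0
    X = recording.data
    means = X.mean(axis=1, keepdims=True)
    Xc = X - means
    cov = Xc @ Xc.T / Xc.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    V = evecs[:, :n_components]
    out.data = Xc - V @ (V.T @ Xc) + means
    removed = float(evals[:n_components].sum() / evals.sum())
    return out, removed


def spline_mara_correct(
    signal: np.ndarray,
    artifact_segments: list[tuple[int, int]],
    smoothing: float = 0.001,
) -> np.ndarray:
    """Subtract a smoothing spline inside each flagged segment and re-level.

    ``artifact_segments`` are half-open sample ranges ``(i0, i1)``, flagged
    externally (e.g. where the motion trace exceeds a quantile, or from
    ground truth).  Within a segment the spline models the artifact; the
    residual is offset for continuity with the sample preceding the segment,
    and everything after the segment is shifted so no artificial step is
    introduced at its end.  ``smoothing`` scales the spline's permitted
    residual (0 = interpolating spline).
    """
    signal = np.asarray(signal, dtype=float)
    n = len(signal)
    segs = sorted((int(a), int(b)) for a, b in artifact_segments)
    for (a0, a1), (b0, b1) in zip(segs, segs[1:]):
        if b0 < a1:
            raise ValueError("artifact segments overlap")
    out = signal.copy()
    for i0, i1 in segs:
        if not (0 <= i0 < i1 <= n):
            raise ValueError("segment outside signal bounds")
        seg = out[i0:i1].copy()
        x = np.arange(i1 - i0, dtype=float)
        if len(seg) >= 4:
            s = smoothing * len(seg) * seg.var()
            spline = UnivariateSpline(x, seg, k=3, s=s)(x)
        else:
            spline = np.full_like(seg, seg.mean())
        resid = seg - spline
        base = out[i0 - 1] if i0 > 0 else seg[0]
        corrected_seg = resid - resid[0] + base
        shift_after = corrected_seg[-1] - seg[-1]
        out[i0:i1] = corrected_seg
        out[i1:] += shift_after
    return out


def segments_from_motion(
    motion_values: np.ndarray,
    quantile: float = 0.95,
    pad: int = 5,
) -> list[tuple[int, int]]:
    """Flag artifact segments where a motion trace exceeds its quantile."""
    v = np.asarray(motion_values, dtype=float)
    thr = np.quantile(v, quantile)
    above = v > thr
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    segs: list[tuple[int, int]] = []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            segs.append((max(0, run_start - pad), min(len(v), prev + 1 + pad)))
            run_start = i
        prev = i
    segs.append((max(0, run_start - pad), min(len(v), prev + 1 + pad)))
    # merge overlaps introduced by padding
    merged = [segs[0]]
    for a, b in segs[1:]:
        if a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(b, merged[-1][1]))
        else:
            merged.append((a, b))
    return merged


def cbsi_correct(hbo: np.ndarray, hhb: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Correlation-based signal improvement for an O2Hb/HHb channel pair.

    With zero-mean signals and ``alpha = sd(hbo)/sd(hhb)``:

        hbo0 = (hbo - alpha * hhb) / 2,    hhb0 = -hbo0 / alpha

    The corrected pair is perfectly anticorrelated by construction
    (common-mode artifacts cancel; anticorrelated hemodynamics survive).
    Channel means are restored after correction.  Returns
    ``(hbo_corrected, hhb_corrected, alpha)``.
    """
    hbo = np.asarray(hbo, dtype=float)
    hhb = np.asarray(hhb, dtype=float)
    if hbo.shape != hhb.shape:
        raise ValueError("inputs must have equal length")
    sx, sy = hbo.std(), hhb.std()
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance input")
    mx, my = hbo.mean(), hhb.mean()
    x, y = hbo - mx, hhb - my
    alpha = sx / sy
    x0 = (x - alpha * y) / 2.0
    y0 = -x0 / alpha
    return x0 + mx, y0 + my, float(alpha)
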