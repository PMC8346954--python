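"""Motion-artifact correction by time–frequency exclusion masking.

For each fNIRS channel the procedure computes (i) the Morse CWT of the
channel, (ii) the Morse CWT of its detector's resultant motion trace, and
(iii) the Morlet wavelet coherence between channel and motion, all on one
shared frequency grid.  Time–frequency cells where the (globally
max-normalized) motion magnitude and the coherence both exceed a threshold
are flagged as motion-related, and the channel is reconstructed by the
inverse CWT with those cells excluded.
"""

from __future__ import annotations

import numpy as np

from .containers import (
    CoherenceMap,
    CorrectionConfig,
    CorrectionResult,
    FnirsRecording,
    MotionTrace,
    Scalogram,
    WaveletParams,
)
from .wavelets import cwt_morse, frequency_grid, icwt, wcoh_morlet

__all__ = ["build_mask", "correct_channel", "correct_recording", "prepare_motion"]


def build_mask(
    motion_scalogram: Scalogram,
    coherence: CoherenceMap,
    config: CorrectionConfig | None = None,
) -> np.ndarray:
    """Boolean exclusion mask over the shared time–frequency grid.

    The motion magnitude is normalized by its global maximum so the same
    threshold grid applies to it and to the (already [0,1]) coherence.
    Under the default ``intersection`` rule a cell must both carry motion
    energy and cohere with the signal; ``union`` masks either exceedance.
    An all-zero motion scalogram yields an empty mask (nothing to exclude).
    """
    if config is None:
        config = CorrectionConfig()
    mag = motion_scalogram.magnitude
    if mag.shape != coherence.values.shape:
        raise ValueError("motion scalogram and coherence grids are not congruent")
    peak = mag.max()
    norm = mag / peak if peak > 0 else np.zeros_like(mag)
    exceed_motion = norm > config.t_motion
    exceed_coh = coherence.values > config.t_coherence
    if config.combine_rule == "union":
        return exceed_motion | exceed_coh
    return exceed_motion & exceed_coh


def _reconstruct_excluding(signal: np.ndarray, sig_sg: Scalogram, mask: np.ndarray) -> np.ndarray:
    """Signal with the masked time-frequency content excised.

    Implemented as ``signal - icwt(masked cells only)``: the motion-related
    component is reconstructed from the flagged coefficients and subtracted.
    This is equivalent to reconstructing from the retained coefficients up
    to the wavelet round-trip error, but it leaves content the scale grid
    cannot represent (the mean, drift slower than two cycles per record)
    untouched instead of discarding it.
    """
    if not mask.any():
        return signal.copy()
    return signal - icwt(sig_sg, mask=~mask)


def prepare_motion(motion: MotionTrace, fs: float, n_samples: int) -> np.ndarray:
    """Gap-fill and length-check a motion trace for use against a signal."""
    v = np.asarray(motion.values, dtype=float)
    if abs(motion.fs - fs) > 1e-9:
        t_old = np.arange(len(v)) / motion.fs
        t_new = np.arange(n_samples) / fs
        v = np.interp(t_new, t_old, v)
    if len(v) != n_samples:
        raise ValueError(
            f"motion trace length {len(v)} does not match signal length {n_samples}"
        )
    nan = ~np.isfinite(v)
    if nan.all():
        raise ValueError("motion trace is entirely NaN")
    if nan.any():
        idx = np.arange(len(v))
        v = v.copy()
        v[nan] = np.interp(idx[nan], idx[~nan], v[~nan])
    return v


def correct_channel(
    signal: np.ndarray,
    motion: MotionTrace,
    config: CorrectionConfig | None = None,
    params: WaveletParams | None = None,
    return_diagnostics: bool = False,
):
    """Correct one channel against its detector's motion trace.

    Returns the corrected signal, or ``(corrected, diagnostics)`` when
    ``return_diagnostics`` is set; diagnostics carry the mask, its occupancy
    (fraction of excluded cells), and the grids, for audit and plotting.
    """
    if config is None:
        config = CorrectionConfig()
    if params is None:
        params = WaveletParams()
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1:
        raise ValueError("signal must be 1-D; use correct_recording for multichannel data")
    return _correct_channel_impl(signal, motion, config, params, return_diagnostics)


def _correct_channel_impl(signal, motion, config, params, return_diagnostics):
    fs = motion.fs
    mvals = prepare_motion(motion, fs, len(signal))
    freqs = frequency_grid(len(signal), fs, params.voices_per_octave)
    sig_sg = cwt_morse(signal, fs, params, frequencies=freqs)
    mot_sg = cwt_morse(mvals - mvals.mean(), fs, params, frequencies=freqs)
    if np.ptp(mvals) == 0:
        mask = np.zeros(sig_sg.coefficients.shape, dtype=bool)
    else:
        coh = wcoh_morlet(signal, mvals, fs, params, frequencies=freqs)
        mask = build_mask(mot_sg, coh, config)
    corrected = _reconstruct_excluding(signal, sig_sg, mask)
    if not return_diagnostics:
        return corrected
    diagnostics = {
        "mask": mask,
        "mask_occupancy": float(mask.mean()),
        "frequencies": freqs,
        "motion_interpolated": np.asarray(motion.interpolated_mask).copy(),
    }
    return corrected, diagnostics


def correct_recording(
    recording: FnirsRecording,
    traces: dict[int, MotionTrace],
    config: CorrectionConfig | None = None,
    params: WaveletParams | None = None,
    keep_masks: bool = False,
) -> CorrectionResult:
    """Correct every channel of a recording.

    ``traces`` maps detector id -> motion trace; channels sharing a detector
    share the motion input (and its scalogram) but each channel gets its own
    coherence map, hence its own mask.
    """
    if config is None:
        config = CorrectionConfig()
    if params is None:
        params = WaveletParams()
    n_ch, n = recording.data.shape
    fs = recording.fs
    freqs = frequency_grid(n, fs, params.voices_per_octave)

    # one motion scalogram per detector, reused across its channels
    motion_vals: dict[int, np.ndarray] = {}
    motion_sg: dict[int, Scalogram] = {}
    for ch in range(n_ch):
        det = recording.channel_to_detector.get(ch)
        if det is None or det not in traces:
            raise ValueError(f"channel {recording.channel_labels[ch]} has no motion trace")
        if det not in motion_sg:
            v = prepare_motion(traces[det], fs, n)
            motion_vals[det] = v
            motion_sg[det] = cwt_morse(v - v.mean(), fs, params, frequencies=freqs)

    corrected = np.empty_like(recording.data)
    occupancy = np.empty(n_ch)
    masks = [] if keep_masks else None
    used = {}
    for ch in range(n_ch):
        det = recording.channel_to_detector[ch]
        used[ch] = det
        v = motion_vals[det]
        sig_sg = cwt_morse(recording.data[ch], fs, params, frequencies=freqs)
        if np.ptp(v) == 0:
            mask = np.zeros(sig_sg.coefficients.shape, dtype=bool)
        else:
            coh = wcoh_morlet(recording.data[ch], v, fs, params, frequencies=freqs)
            mask = build_mask(motion_sg[det], coh, config)
        corrected[ch] = _reconstruct_excluding(recording.data[ch], sig_sg, mask)
        occupancy[ch] = mask.mean()
        if keep_masks:
            masks.append(mask)
    return CorrectionResult(
        corrected=corrected,
        mask_occupancy=occupancy,
        masks=masks,
        motion_trace_used=used,
    )
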