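"""Synthetic inputs with ground truth: resting fNIRS, motion, thermal video.

Every generator here is a pure function of its parameters and seed, and
returns the matching :class:`~nirsmoco.containers.GroundTruth` so downstream
modules can be validated without any external recording.

Defaults emulate the study conditions the pipeline targets: 10 Hz sampling
for both modalities, 5-minute records, 8 channels fed by 2 detectors,
20 s task / 20 s rest blocks, and a 240x320 thermal frame with a warm face
and cooler optode discs.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as gamma_dist

from .containers import (
    FnirsRecording,
    GroundTruth,
    MotionEventSet,
    MotionTrace,
    Paradigm,
    ThermalVideo,
)

__all__ = [
    "default_paradigm",
    "make_boxcar",
    "canonical_hrf",
    "synth_resting_fnirs",
    "random_motion_events",
    "synth_motion_trace",
    "inject_motion_artifacts",
    "synth_thermal_video",
    "default_optode_layout",
    "add_activation",
]

#: physiological band centers (Hz) and default amplitudes (signal units)
DEFAULT_COMPONENTS = {
    "cardiac": (1.1, 0.010),
    "respiratory": (0.25, 0.020),
    "mayer": (0.10, 0.030),
}
DEFAULT_DRIFT_AMPLITUDE = 0.02
DEFAULT_NOISE_SD = 0.005


def default_paradigm(total_duration: float = 300.0, amplitude: float = 1.0) -> Paradigm:
    """20 s task / 20 s rest blocks over a 5-minute record."""
    onsets = tuple(np.arange(20.0, total_duration - 20.0 + 1e-9, 40.0))
    return Paradigm(
        block_onsets=onsets,
        block_duration=20.0,
        total_duration=total_duration,
        amplitude=amplitude,
    )


def make_boxcar(paradigm: Paradigm, fs: float) -> np.ndarray:
    """Sample the block paradigm as a boxcar in {0, amplitude}.

    Block membership uses half-open intervals [onset, onset + duration), so a
    block of 20 s at 10 Hz contributes exactly 200 samples.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    n = int(round(paradigm.total_duration * fs))
    box = np.zeros(n)
    for onset in paradigm.block_onsets:
        i0 = int(round(onset * fs))
        i1 = int(round((onset + paradigm.block_duration) * fs))
        box[i0:min(i1, n)] = paradigm.amplitude
    return box


def canonical_hrf(
    fs: float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    undershoot_ratio: float = 6.0,
    length: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response function, peak-normalized.

    The kernel is the difference of two gamma densities (positive main lobe
    peaking ~5-6 s post-onset, smaller undershoot ~16 s), divided by its own
    maximum so the peak is exactly 1.0.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    t = np.arange(int(round(length * fs))) / fs
    main = gamma_dist.pdf(t, peak_delay / peak_dispersion, scale=peak_dispersion)
    under = gamma_dist.pdf(t, undershoot_delay / undershoot_dispersion, scale=undershoot_dispersion)
    h = main - under / undershoot_ratio
    return h / h.max()


def synth_resting_fnirs(
    fs: float = 10.0,
    duration: float = 300.0,
    n_channels: int = 8,
    component_amplitudes: dict | None = None,
    drift_amplitude: float = DEFAULT_DRIFT_AMPLITUDE,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_detectors: int = 2,
    seed: int = 0,
) -> tuple[FnirsRecording, GroundTruth]:
    """Resting-state physiology: cardiac + respiratory + Mayer sinusoids,
    slow drift, and white noise, with per-channel random phases.

    ``component_amplitudes`` maps band name -> (center_hz, amplitude);
    defaults are :data:`DEFAULT_COMPONENTS`.  Channels are assigned to
    detectors round-robin (8 channels / 2 detectors -> 4 each).
    """
    if duration < 60:
        raise ValueError("duration must be >= 60 s to resolve spectral structure")
    if fs < 2.5:
        raise ValueError("fs must be >= 2.5 Hz to represent the cardiac band")
    comps = DEFAULT_COMPONENTS if component_amplitudes is None else component_amplitudes
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    data = np.zeros((n_channels, n))
    for ch in range(n_channels):
        for f0, amp in comps.values():
            phase = rng.uniform(0, 2 * np.pi)
            data[ch] += amp * np.sin(2 * np.pi * f0 * t + phase)
        # slow drift: one very-low-frequency sinusoid per channel
        data[ch] += drift_amplitude * np.sin(2 * np.pi * 0.005 * t + rng.uniform(0, 2 * np.pi))
        data[ch] += noise_sd * rng.standard_normal(n)
    det = {ch: ch % n_detectors for ch in range(n_channels)}
    rec = FnirsRecording(data=data, fs=fs, channel_to_detector=det)
    gt = GroundTruth(clean_signal=data.copy())
    return rec, gt


def random_motion_events(
    n_events: int = 8,
    duration: float = 300.0,
    spike_fraction: float = 0.75,
    displacement_px: tuple[float, float] = (4.0, 14.0),
    coupling_per_px: tuple[float, float] = (0.008, 0.015),
    seed: int = 0,
    margin: float = 15.0,
) -> MotionEventSet:
    """Draw a random set of spike/shift events within ``[margin, duration-margin]``.

    The artifact magnitude of each event is its displacement times a random
    coupling constant (signal units per pixel), so larger head movements
    produce proportionally larger signal deflections.
    """
    rng = np.random.default_rng(seed)
    times = np.sort(rng.uniform(margin, duration - margin, n_events))
    # enforce minimal spacing so events stay distinguishable
    for i in range(1, n_events):
        times[i] = max(times[i], times[i - 1] + 5.0)
    kinds = tuple(
        "spike" if rng.uniform() < spike_fraction else "shift" for _ in range(n_events)
    )
    px = rng.uniform(*displacement_px, n_events)
    sig = px * rng.uniform(*coupling_per_px, n_events)
    return MotionEventSet(tuple(times), kinds, tuple(px), tuple(sig))


def _event_pulse(t: np.ndarray, t0: float, width: float) -> np.ndarray:
    """Unit-peak Gaussian pulse centered at ``t0`` (seconds)."""
    return np.exp(-0.5 * ((t - t0) / width) ** 2)


def synth_motion_trace(
    event_set: MotionEventSet,
    fs: float = 10.0,
    duration: float = 300.0,
    pulse_width: float = 1.0,
) -> MotionTrace:
    """Resultant optode displacement implied by the events.

    A ``spike`` is a transient: the head moves and settles back, so the
    displacement is a pulse.  A ``shift`` is a permanent displacement of the
    optode — the trace steps at the event and stays there — which is what
    couples a lasting baseline shift into the optical signal.
    """
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    values = np.zeros(n)
    for t0, kind, mag in zip(event_set.event_times, event_set.kinds, event_set.magnitudes_px):
        if not (0 <= t0 <= duration):
            raise ValueError("event time outside recording duration")
        values += mag * _event_pulse(t, t0, pulse_width)
        if kind == "shift":
            values += mag * (t >= t0)
    return MotionTrace(values=values, fs=fs)


def inject_motion_artifacts(
    recording: FnirsRecording,
    motion_trace: MotionTrace,
    event_set: MotionEventSet,
    channel_gains: np.ndarray | None = None,
    pulse_width: float = 1.0,
    seed: int = 0,
    channel_hit_prob: float = 0.75,
) -> tuple[FnirsRecording, GroundTruth]:
    """Add motion-coupled artifacts to every channel.

    Spike events add a transient deflection shaped like the displacement
    pulse; shift events add the pulse plus a persistent step from the event
    time onward.  Amplitudes are ``gain[ch, ev] * magnitudes_signal[ev]``,
    so different movements may corrupt different channel subsets.

    ``channel_gains`` is ``(n_channels, n_events)``; when omitted, gains are
    drawn as Bernoulli(``channel_hit_prob``) x Uniform(0.5, 1.5) from
    ``seed`` (a movement misses some channels entirely).
    """
    n_ch, n = recording.data.shape
    if len(motion_trace.values) != n:
        raise ValueError("motion trace not sample-aligned with recording")
    if abs(motion_trace.fs - recording.fs) > 1e-9:
        raise ValueError("motion trace and recording sampling rates differ")
    n_ev = len(event_set)
    if channel_gains is None:
        rng = np.random.default_rng(seed)
        hit = rng.uniform(size=(n_ch, n_ev)) < channel_hit_prob
        channel_gains = hit * rng.uniform(0.5, 1.5, size=(n_ch, n_ev))
    channel_gains = np.asarray(channel_gains, dtype=float)
    if channel_gains.shape != (n_ch, n_ev):
        raise ValueError("channel_gains must be (n_channels, n_events)")

    t = recording.times
    artifact = np.zeros_like(recording.data)
    for ev in range(n_ev):
        t0 = event_set.event_times[ev]
        amp = event_set.magnitudes_signal[ev]
        pulse = _event_pulse(t, t0, pulse_width)
        for ch in range(n_ch):
            g = channel_gains[ch, ev] * amp
            if g == 0:
                continue
            artifact[ch] += g * pulse
            if event_set.kinds[ev] == "shift":
                artifact[ch] += g * (t >= t0)
    out = recording.copy()
    out.data = out.data + artifact
    gt = GroundTruth(clean_signal=recording.data.copy(), artifact=artifact)
    return out, gt


def default_optode_layout() -> dict:
    """Optode positions (full-resolution px offsets from the face center).

    Two detector discs (radius 6) with deliberately different source
    neighborhoods, and eight smaller source discs (radius 4), mimicking a
    prefrontal 8-channel / 2-detector montage.
    """
    return {
        "detectors": [(-30.0, -45.0), (-30.0, 45.0)],
        "detector_radius": 6.0,
        "sources": [
            (-45.0, -70.0), (-45.0, -25.0), (-12.0, -60.0), (-5.0, -30.0),
            (-50.0, 30.0), (-42.0, 68.0), (-15.0, 25.0), (-8.0, 62.0),
        ],
        "source_radius": 4.0,
    }


def synth_thermal_video(
    n_frames: int = 300,
    frame_size: tuple[int, int] = (240, 320),
    trajectory: np.ndarray | None = None,
    face_temp: float = 34.0,
    background_temp: float = 23.0,
    optode_temp: float = 30.0,
    optode_layout: dict | None = None,
    noise_sd: float = 0.05,
    fs: float = 10.0,
    seed: int = 0,
    occlusion_frames: tuple[int, ...] = (),
) -> tuple[ThermalVideo, GroundTruth]:
    """A rigidly translating warm face with cooler optode discs.

    The face is an ellipse of ``face_temp`` on a ``background_temp``
    background; optode positions carry small cooler discs.  ``trajectory``
    is ``(n_frames, 2)`` per-frame ``(drow, dcol)`` offsets of the whole
    scene from its frame-0 position (default: static).  Pixel noise is
    i.i.d. Gaussian with ``noise_sd`` (default 0.05 degC, the order of a
    research thermal camera's noise-equivalent temperature difference).
    ``occlusion_frames`` overwrite a patch around the first detector with
    background temperature, destroying the template pattern there.
    """
    rows, cols = frame_size
    if trajectory is None:
        trajectory = np.zeros((n_frames, 2))
    trajectory = np.asarray(trajectory, dtype=float)
    if trajectory.shape != (n_frames, 2):
        raise ValueError("trajectory must be (n_frames, 2)")
    layout = default_optode_layout() if optode_layout is None else optode_layout
    center0 = np.array([rows * 0.5, cols * 0.5])
    semi = np.array([rows * 0.36, cols * 0.30])  # face semi-axes

    # reject trajectories that push the face out of the frame
    cmin = trajectory.min(axis=0) + center0 - semi
    cmax = trajectory.max(axis=0) + center0 + semi
    if cmin[0] < 0 or cmin[1] < 0 or cmax[0] > rows or cmax[1] > cols:
        raise ValueError("trajectory moves the face outside the frame")

    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    frames = np.empty((n_frames, rows, cols))
    det0 = np.asarray(layout["detectors"][0])
    occl = set(int(i) for i in occlusion_frames)
    for k in range(n_frames):
        c = center0 + trajectory[k]
        frame = np.full((rows, cols), background_temp)
        inside = ((rr - c[0]) / semi[0]) ** 2 + ((cc - c[1]) / semi[1]) ** 2 <= 1.0
        frame[inside] = face_temp
        # lateral temperature gradient across the face (faces are not isothermal)
        frame[inside] += 0.004 * (cc[inside] - c[1])
        for (dr, dc) in layout["detectors"]:
            disc = (rr - (c[0] + dr)) ** 2 + (cc - (c[1] + dc)) ** 2 <= layout["detector_radius"] ** 2
            frame[disc] = optode_temp
        for (dr, dc) in layout["sources"]:
            disc = (rr - (c[0] + dr)) ** 2 + (cc - (c[1] + dc)) ** 2 <= layout["source_radius"] ** 2
            frame[disc] = optode_temp
        if k in occl:
            pc = c + det0
            half = 3.0 * layout["detector_radius"]
            patch = (np.abs(rr - pc[0]) <= half) & (np.abs(cc - pc[1]) <= half)
            frame[patch] = background_temp
        if noise_sd > 0:
            frame = frame + noise_sd * rng.standard_normal((rows, cols))
        frames[k] = frame

    video = ThermalVideo(frames=frames, fs=fs)
    gt = GroundTruth(
        true_trajectory=trajectory.copy(),
        extras={
            "face_center0": center0,
            "face_semi_axes": semi,
            "layout": layout,
            "occlusion_frames": sorted(occl),
            "face_temp": face_temp,
            "background_temp": background_temp,
        },
    )
    return video, gt


def add_activation(
    recording: FnirsRecording,
    paradigm: Paradigm,
    hrf_kernel: np.ndarray | None = None,
    amplitude: float = 1.0,
) -> tuple[FnirsRecording, GroundTruth]:
    """Add ``amplitude * (boxcar (*) HRF)`` to every channel (causal).

    Returns the activated recording plus ground truth carrying the injected
    activation time series and the rest mask (samples where the boxcar is 0).
    """
    if hrf_kernel is None:
        hrf_kernel = canonical_hrf(recording.fs)
    box = make_boxcar(paradigm, recording.fs)
    if len(box) != recording.n_samples:
        raise ValueError("paradigm duration does not match the recording length")
    activation = amplitude * np.convolve(box, hrf_kernel)[: recording.n_samples]
    out = recording.copy()
    out.data = out.data + activation[None, :]
    gt = GroundTruth(
        clean_signal=recording.data.copy(),
        injected_activation=activation,
        rest_mask=box == 0,
    )
    return out, gt
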