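"""Shared data containers for the tracking / correction / evaluation pipeline.

Conventions used throughout the package:

* images and video frames are ``(rows, cols)`` arrays, 0-based ``(row, col)``
  coordinates, temperatures in degrees Celsius;
* time series are sampled uniformly at ``fs`` Hz, time in seconds;
* fNIRS data is a ``(n_channels, n_samples)`` array in signal units
  (delta-OD or delta-hemoglobin — the pipeline is unit-agnostic).

Four unrelated Greek symbols from the source literature collide (tracker
correlation gamma, Morse symmetry gamma, Morse order beta, GLM beta); each
lives in its own container here so they can never be confused.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Paradigm",
    "MotionEventSet",
    "GroundTruth",
    "ThermalVideo",
    "RoiSpec",
    "TrackResult",
    "MotionTrace",
    "FnirsRecording",
    "WaveletParams",
    "Scalogram",
    "CoherenceMap",
    "CorrectionConfig",
    "CorrectionResult",
    "GlmResult",
]


@dataclass(frozen=True)
class Paradigm:
    """A block experimental paradigm: task blocks on a resting baseline.

    Parameters
    ----------
    block_onsets : sequence of float
        Block start times in seconds, strictly increasing.
    block_duration : float
        Duration of each task block, seconds.
    total_duration : float
        Total length of the record, seconds.
    amplitude : float
        Boxcar height in signal units (>= 0).
    """

    block_onsets: tuple[float, ...]
    block_duration: float
    total_duration: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        onsets = tuple(float(t) for t in self.block_onsets)
        object.__setattr__(self, "block_onsets", onsets)
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("block onsets must be strictly increasing")
        if any(t + self.block_duration > self.total_duration + 1e-9 for t in onsets):
            raise ValueError("block extends past total_duration")
        if any(b < a + self.block_duration for a, b in zip(onsets, onsets[1:])):
            raise ValueError("blocks overlap")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.block_duration < 0 or self.total_duration <= 0:
            raise ValueError("durations must be positive")


@dataclass(frozen=True)
class MotionEventSet:
    """Discrete head-motion events (abstracting yawns, tilts, frowns...).

    ``kinds[i]`` is ``"spike"`` (transient deflection) or ``"shift"``
    (persistent baseline step).  ``magnitudes_px`` is the peak optode
    displacement in full-resolution pixels; ``magnitudes_signal`` the artifact
    gain in signal units per event.
    """

    event_times: tuple[float, ...]
    kinds: tuple[str, ...]
    magnitudes_px: tuple[float, ...]
    magnitudes_signal: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.event_times)
        if not (len(self.kinds) == len(self.magnitudes_px) == len(self.magnitudes_signal) == n):
            raise ValueError("event fields must have equal length")
        if any(k not in ("spike", "shift") for k in self.kinds):
            raise ValueError("event kind must be 'spike' or 'shift'")
        if not all(np.isfinite(self.magnitudes_px)) or not all(np.isfinite(self.magnitudes_signal)):
            raise ValueError("magnitudes must be finite")

    def __len__(self) -> int:
        return len(self.event_times)


@dataclass
class GroundTruth:
    """Known truth shipped alongside every synthetic dataset."""

    clean_signal: np.ndarray | None = None  # channels x time
    true_trajectory: np.ndarray | None = None  # frames x 2, (row, col) offsets
    injected_activation: np.ndarray | None = None  # time series
    rest_mask: np.ndarray | None = None  # bool per sample, True where boxcar == 0
    artifact: np.ndarray | None = None  # channels x time, corrupted - clean
    extras: dict = field(default_factory=dict)


@dataclass
class ThermalVideo:
    """A stack of per-pixel temperature frames at a fixed frame rate."""

    frames: np.ndarray  # (n_frames, rows, cols), degC
    fs: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, rows, cols)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("temperatures must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs


@dataclass(frozen=True)
class RoiSpec:
    """Tracking regions: one rectangular master ROI plus elliptic slave ROIs.

    All coordinates are 0-based full-resolution pixels.  ``srois`` is a tuple
    of ``(drow, dcol, semi_row, semi_col)`` ellipses whose centers are offsets
    from the mROI center and translate rigidly with it.
    """

    mroi_center: tuple[float, float]
    mroi_height: int
    mroi_width: int
    srois: tuple[tuple[float, float, float, float], ...] = ()
    gamma_th: float = 0.995
    pyramid_level: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma_th <= 1.0):
            raise ValueError("gamma_th must be in (0, 1]")
        if self.pyramid_level < 0:
            raise ValueError("pyramid_level must be >= 0")
        if self.mroi_height <= 0 or self.mroi_width <= 0:
            raise ValueError("mROI dimensions must be positive")


@dataclass
class TrackResult:
    """Per-frame tracking output; NaN rows mark discarded frames."""

    mroi_centers: np.ndarray  # (n_frames, 2) full-resolution (row, col), NaN if discarded
    gamma: np.ndarray  # (n_frames,) max correlation coefficient
    sroi_centers: np.ndarray  # (n_frames, n_srois, 2)
    fs: float
    roi: RoiSpec

    @property
    def n_discarded(self) -> int:
        return int(np.isnan(self.mroi_centers[:, 0]).sum())

    @property
    def retained(self) -> np.ndarray:
        return ~np.isnan(self.mroi_centers[:, 0])


@dataclass
class MotionTrace:
    """1-D resultant optode displacement, pixels, uniformly sampled."""

    values: np.ndarray
    fs: float
    interpolated_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.interpolated_mask is None:
            self.interpolated_mask = np.zeros(self.values.shape, dtype=bool)


@dataclass
class FnirsRecording:
    """Multichannel fNIRS time series.

    ``channel_to_detector`` maps channel index -> detector id so channels
    sharing a detector share one motion trace.  ``chromophore`` labels are
    free-form ('O2Hb', 'HHb', 'OD').
    """

    data: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    channel_to_detector: dict[int, int] = field(default_factory=dict)
    chromophore: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i + 1}" for i in range(self.n_channels)]
        if not self.channel_to_detector:
            self.channel_to_detector = {i: 0 for i in range(self.n_channels)}
        if not self.chromophore:
            self.chromophore = ["OD"] * self.n_channels

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy(self) -> "FnirsRecording":
        return FnirsRecording(
            data=self.data.copy(),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            channel_to_detector=dict(self.channel_to_detector),
            chromophore=list(self.chromophore),
        )


@dataclass(frozen=True)
class WaveletParams:
    """Parameters of the time–frequency engine.

    ``morse_symmetry`` is the Morse gamma exponent and
    ``morse_time_bandwidth`` the product P^2 = beta*gamma, so the Morse order
    is ``time_bandwidth / symmetry`` (defaults 3 and 60 give order 20).
    ``morlet_omega0`` is the Morlet center frequency used for coherence.
    """

    morse_symmetry: float = 3.0
    morse_time_bandwidth: float = 60.0
    voices_per_octave: int = 12
    morlet_omega0: float = 6.0

    def __post_init__(self) -> None:
        if self.morse_symmetry <= 0:
            raise ValueError("morse_symmetry must be > 0")
        if self.morse_time_bandwidth < self.morse_symmetry:
            raise ValueError("time-bandwidth product must be >= symmetry")
        if self.voices_per_octave < 4:
            raise ValueError("voices_per_octave must be >= 4")

    @property
    def morse_order(self) -> float:
        """Morse beta exponent (decay order)."""
        return self.morse_time_bandwidth / self.morse_symmetry


@dataclass
class Scalogram:
    """Complex CWT coefficients on a logarithmic frequency grid."""

    coefficients: np.ndarray  # complex, (n_scales, n_samples)
    frequencies: np.ndarray  # Hz, strictly decreasing with scale index
    scales: np.ndarray  # samples
    fs: float
    coi: np.ndarray  # Hz per sample: lowest edge-free frequency
    params: WaveletParams

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.coefficients)


@dataclass
class CoherenceMap:
    """Wavelet coherence (squared, in [0, 1]) on a Scalogram-congruent grid."""

    values: np.ndarray  # (n_scales, n_samples) in [0, 1]
    frequencies: np.ndarray
    fs: float


@dataclass(frozen=True)
class CorrectionConfig:
    """Settings for the time–frequency exclusion mask.

    ``threshold`` applies to both the globally max-normalized motion
    scalogram magnitude and the coherence map; a cell is excluded when both
    exceed it (``combine_rule='intersection'``, default) or when either does
    (``'union'``).  Separate per-map thresholds may be given via
    ``motion_threshold`` / ``coherence_threshold`` (default: both equal
    ``threshold``).
    """

    threshold: float = 0.6
    combine_rule: str = "intersection"
    motion_threshold: float | None = None
    coherence_threshold: float | None = None
    tested_thresholds: tuple[float, ...] = (0.4, 0.5, 0.6, 0.7, 0.8)

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold):
            raise ValueError("threshold must be positive")
        if self.combine_rule not in ("intersection", "union"):
            raise ValueError("combine_rule must be 'intersection' or 'union'")

    @property
    def t_motion(self) -> float:
        return self.threshold if self.motion_threshold is None else self.motion_threshold

    @property
    def t_coherence(self) -> float:
        return self.threshold if self.coherence_threshold is None else self.coherence_threshold


@dataclass
class CorrectionResult:
    """Output of correcting a whole recording."""

    corrected: np.ndarray  # channels x time
    mask_occupancy: np.ndarray  # fraction of masked time-frequency cells per channel
    masks: list | None = None
    motion_trace_used: dict[int, int] | None = None  # channel -> detector id


@dataclass
class GlmResult:
    """Ordinary-least-squares fit of a signal on [regressor, intercept]."""

    beta: float
    beta_se: float
    t_stat: float
    residual_sd: float
    sigma_rest: float | None = None
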