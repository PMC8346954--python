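# Methods

`nirsmoco` removes motion artifacts from functional near-infrared
spectroscopy (fNIRS) recordings using a contactless estimate of optode
motion obtained from thermal-infrared video, and validates the procedure on
fully synthetic data with known ground truth. This note documents the
models, the parameters that matter, the numerical choices, and what the
synthetic benchmark does and does not demonstrate.

## The correction model

Head movement decouples optodes from the scalp and injects two kinds of
error into the optical signal: transient high-frequency deflections
("spikes") and, when the optode settles in a new position, persistent
baseline steps ("shifts"). Both overlap spectrally with the hemodynamic
response, so plain band-pass filtering cannot separate them. The approach
here uses the *measured motion of each detector* as a reference that is
sensitive to movement but blind to brain activity:

1. **Tracking.** Each detector is tracked through the thermal video by
   normalized cross-correlation (NCC) of a fixed template selected on the
   first frame. Frames are first segmented by Otsu's method so the search
   runs only over skin, and decimated one level of a Gaussian pyramid
   (240×320 → 120×160) for speed. The per-frame maximum correlation γ is a
   quality index: frames with γ ≤ γ_th (default 0.995) are discarded as
   NaN, and tracking resumes when γ recovers. The per-frame (row, col)
   centers reduce to a 1-D *resultant motion* trace (Euclidean displacement
   from the first retained frame), with NaN gaps filled by linear
   interpolation and flagged.

2. **Time–frequency masking.** For each channel the package computes the
   continuous wavelet transform (CWT) of the signal and of its detector's
   motion trace with an analytic generalized Morse wavelet (symmetry
   γ_m = 3, time–bandwidth product β_m·γ_m = 60, i.e. order β_m = 20), and
   the wavelet coherence (WCOH) between signal and motion with an analytic
   Morlet wavelet (ω₀ = 6), all on one shared logarithmic frequency grid.
   A time–frequency cell is flagged as motion-related when the motion
   magnitude, normalized by its global maximum, and the coherence both
   exceed a threshold T (default 0.6; the intersection rule — a `union`
   rule is available, and separate per-map thresholds can be configured).

3. **Reconstruction.** The corrected channel is the signal with the flagged
   content excised: the masked coefficients are reconstructed by the
   inverse CWT and subtracted from the signal. This is equivalent to
   reconstructing from the retained coefficients (up to the ~1% round-trip
   error of the transform) but leaves content the scale grid cannot
   represent — the mean and drift slower than two cycles per record —
   untouched, which matters because a block activation has a nonzero mean.
   An empty mask therefore returns the input exactly.

Channels sharing a detector share one motion scalogram; coherence, and
hence the mask, is channel-specific. Motion of a *source* that its
detector does not share is invisible to this scheme by construction.

## Wavelet engine

The CWT is evaluated diagonally in the frequency domain,
`W(s,·) = ifft(fft(x) · Ψ(s ω))`, with the Morse window
`Ψ(ω) ∝ ω^β exp(−ω^γ)` normalized to peak value 2 at
`ω_p = (β/γ)^{1/γ}` ("L1"/amplitude normalization: a real sinusoid of
amplitude A attains coefficient magnitude ≈ A; verified to 1%). Scales are
log-spaced at 12 voices per octave (configurable, ≥ 4) spanning
[2/duration, fs/2] Hz. Signals are padded by symmetric reflection to the
next power of two: reflection rather than zero padding keeps the hard
boundary edges out of the long low-frequency atoms and holds the interior
round-trip error near 1% (the contract is < 2% excluding 10 s at each end).
A conservative cone of influence (time spread taken as √(βγ)/ω_p scale
units) is recorded per sample; masked cells inside and outside the cone are
treated identically.

Inversion uses the single-integral formula: the real coefficient sum over
scales divided by a constant. Because the transform is diagonal in
frequency, "transform then sum" has the transfer function
`T(ω) = ½ Σ_j Ψ(s_j ω)`, which is flat across the covered band at ≥ 4
voices/octave; the constant is the mid-band median of T, computed
analytically from the scale grid at call time (deterministic — no empirical
calibration per call).

Wavelet coherence follows the standard smoothing convention: cross- and
auto-spectra weighted by 1/scale, smoothed by a Gaussian in time with
standard deviation equal to the scale (in samples; implemented by FFT so
cost is independent of scale) and a ~0.6-octave boxcar across scales.
Self-coherence is identically 1; values are clipped to [0, 1];
`wcoh(x, y) == wcoh(y, x)` bitwise (the cross-spectrum is formed from
explicit real/imaginary products because complex FFT arithmetic is not
bit-symmetric under conjugation).

## Tracker numerics

The template is cropped from the *decimated* first frame, so template and
search image share one smoothing history and a static video scores γ = 1
exactly. Matching uses the fast NCC algorithm (FFT cross term plus
integral-image running sums for the local mean/variance); placements whose
window center falls off the Otsu skin mask are excluded, and a frame whose
skin mask admits no placement is discarded like a low-γ frame. Centers are
reported at full resolution by rescaling the decimated argmax; no sub-pixel
refinement is attempted, so the accuracy contract is ±2^level px per axis.
A consequence of matching at decimated resolution with the strict default
γ_th = 0.995: displacements that are not multiples of 2^level px blur the
decimated image by a half pixel and can push γ to ~0.97–0.98, below the
gate. The synthetic validation trajectories therefore move in even-pixel
steps; with a real camera γ_th should be re-tuned to the hardware, and the
threshold is exposed as a CLI flag for exactly that reason.

## Synthetic data: what it emulates

All validation inputs are generated by `nirsmoco.simulate`:

* **Resting physiology** — per channel, sinusoids at the cardiac (1.1 Hz),
  respiratory (0.25 Hz) and Mayer-wave (0.10 Hz) bands with random phases
  (amplitudes 0.01/0.02/0.03 signal units), a slow 0.005 Hz drift (0.02),
  and white noise (sd 0.005). Band centers are recoverable from a 300 s
  periodogram to ±0.05 Hz.
* **Activation** — a block paradigm (20 s task / 20 s rest over 5 min)
  convolved with a peak-normalized double-gamma HRF (peak ~5 s, undershoot
  ~16 s, |h| < 0.01 beyond 32 s). In the benchmark the evoked-response
  *peak* is the amplitude parameter (default 0.02 signal units, i.e. a
  response on the order of the resting fluctuations; there is no single
  canonical value, so it is exposed rather than fixed).
* **Motion events** — 8 events per 5-min record, 75% spikes / 25% shifts,
  displacements 4–14 px. A spike is a 1 s Gaussian displacement pulse; a
  shift is a pulse plus a *persistent* displacement step (a lasting signal
  shift physically corresponds to a permanent optode displacement, so the
  motion reference must step too). Artifact amplitude per event is
  displacement × a random coupling of 0.008–0.015 signal units/px, with
  per-channel gain 0.5–1.5; by default every channel of a moving detector
  is corrupted, and a hit-probability parameter can emulate movements that
  corrupt only a subset. Events are assigned round-robin to detectors, so
  the two detectors' motions differ.
* **Thermal scene** — a warm face ellipse (34 °C, with a mild lateral
  temperature gradient) on a 23 °C background with cooler (30 °C) optode
  discs (2 detector discs of radius 6 px with distinct source
  neighborhoods, 8 source discs of radius 4 px), translated rigidly;
  pixel noise sd 0.05 °C, the order of a research camera's noise-equivalent
  temperature difference. Occluded frames overwrite the template region
  with background temperature. Out-of-plane rotation is not modeled;
  occlusion serves as the γ-degrading event instead.

Everything is a pure function of its parameters and seed; injected
artifacts and activations are strictly additive, so `corrupted − clean`
recovers the injected series exactly.

What passing these tests does **not** show about real recordings: real
physiology is nonstationary and broadband, real artifact coupling is
nonlinear in displacement, real optics add chromophore-specific effects,
and real faces rotate and deform. The benchmark demonstrates the internal
consistency and the qualitative behavior of the method under its own
assumptions, not clinical performance.

## Validation design

Each synthetic "subject" (replicate; default 16, a typical fNIRS
validation cohort size — tests and the acceptance script use 5–7
replicates, keeping runs in the seconds-to-minutes range) yields 8
channels on 2 detectors. Channels are scored by an ordinary-least-squares
GLM on `[regressor, intercept]` where the regressor is the known
(unit-peak) activation shape; no drift regressors. Metrics:

* β and t = β/SE(β) (residual dof n − 2);
* SNR = β/σ_rest with σ_rest the SD of the scored series over rest samples
  (boxcar = 0);
* MSE against the known clean series, over the whole record.

Method comparisons average each channel's metric over replicates, then run
a two-sided paired t-test *across channels* (df = n_channels − 1 = 7); no
multiple-testing correction. The threshold sweep evaluates
T ∈ {0.4, 0.5, 0.6, 0.7, 0.8} on the same seeded replicates; on the default
conditions the sweep's best-SNR threshold lands on 0.6 (seed-dependent:
0.5 at some seeds), consistent with the default.

Baselines are re-implemented from their originating schemes at standard
settings (parameterizations vary across toolboxes, so cross-method
comparisons are directional, not numeric): discrete-wavelet
IQR filtering (db5, full depth, factor 1.5), spatial PCA (1 component),
MARA-style spline subtraction (smoothing spline inside externally flagged
segments — from motion-trace quantile exceedance or ground truth — with
boundary re-leveling), and CBSI (enforced O2Hb/HHb anticorrelation; the
benchmark synthesizes the HHb companion from the CBSI generative model).

## Known limitations

* Shifts are corrected only partially: masking removes the step's
  *transition* content, not the far-field offset (out of band); the
  residual is a near-constant offset that the GLM intercept absorbs but
  the whole-record MSE still sees.
* A channel whose detector moved but whose own coupling was zero can be
  perturbed slightly by spurious coherence exceedances inside
  motion-energetic cells (the intersection rule bounds, but does not
  eliminate, this).
* Source-only motion is uncorrectable by design (the source rides with its
  detector's mask only).
* The tracker handles rigid translation only, at integer decimated-pixel
  resolution, one master ROI per run.
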