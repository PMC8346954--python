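# nirsmoco

Motion-artifact correction for functional near-infrared spectroscopy
(fNIRS) signals, driven by a contactless estimate of optode motion from
thermal-infrared video.

fNIRS measures cortical oxy-/deoxy-hemoglobin changes through scalp
optodes. Head movement decouples optodes from the scalp and corrupts the
optical signal with transient spikes and persistent baseline shifts that
overlap spectrally with the hemodynamic response, so they cannot be
filtered out by frequency alone. `nirsmoco` implements a reference-signal
approach in which the reference — the motion of each detector — is measured
without touching the participant, by template tracking in a thermal video
of the face:

1. **Track** each detector through the thermal video: Otsu skin
   segmentation, level-1 Gaussian-pyramid decimation, FFT-based normalized
   cross-correlation against a fixed first-frame template, and a
   correlation gate γ_th = 0.995 that discards unreliable frames (NaN).
   The tracked centers reduce to a resultant displacement trace per
   detector.
2. **Mask** motion-related time–frequency content: compute the CWT of the
   signal and of the motion trace (analytic generalized Morse wavelet,
   symmetry 3, time–bandwidth product 60) and their wavelet coherence
   (analytic Morlet); flag cells where the max-normalized motion magnitude
   **and** the coherence exceed a threshold T (default 0.6, swept over
   {0.4, …, 0.8} by the validation harness).
3. **Reconstruct** the channel by the inverse CWT with the flagged cells
   excised.

A simulation harness validates the procedure the way reference-signal
methods are validated: synthetic block activations (boxcar ⊗ double-gamma
HRF) are added to resting-state physiology, motion-coupled spike/shift
artifacts are injected, and every channel is scored by a GLM —
β, t = β/SE(β), SNR = β/σ_rest, and MSE against the known clean signal —
against four standard baselines (wavelet-IQR, PCA, MARA-style spline,
CBSI). See `docs/methods.md` for the full model description.

## Worked example

Score the proposed correction against the uncorrected signal on 40
synthetic channels (5 replicate "subjects" × 8 channels, 5-minute 10 Hz
records, 20 s on/off blocks, 8 motion events each):

```python
from nirsmoco import evaluation
from nirsmoco.evaluation import BenchmarkConfig

cfg = BenchmarkConfig(n_replicates=5, base_seed=1)
table = evaluation.run_benchmark(cfg, methods=("uncorrected", "proposed"))
print(table.groupby("method")[["snr", "mse", "beta"]].mean().round(4))

unc = table[table.method == "uncorrected"].sort_values(["replicate", "channel"])
pro = table[table.method == "proposed"].sort_values(["replicate", "channel"])
frac = (pro["mse"].to_numpy() < unc["mse"].to_numpy()).mean()
print(f"channels improved: {frac:.0%} of {len(unc)}")
```

prints

```
                snr     mse    beta
method
proposed     0.4783  0.0026  0.0197
uncorrected  0.4478  0.0029  0.0194
channels improved: 100% of 40
```

Reading the numbers: the injected evoked response peaks at 0.02 signal
units, so the GLM β of ~0.02 recovers the truth for both series; the
correction raises the mean SNR (β over the resting-period SD) from 0.45 to
0.48 and lowers the mean squared error against the known clean signal on
every one of the 40 corrupted channels. `evaluation.threshold_sweep(cfg)`
reproduces the 5-point threshold analysis, and
`evaluation.compare_methods(cfg)` adds the four baselines plus the paired
t-tests across the 8 channel means (df = 7).

## Command line

The same pipeline is scriptable end to end; `simulate` writes inputs that
`track` and `correct` consume unmodified:

```sh
nirsmoco simulate --out-dir demo --seed 1
nirsmoco track   --video demo/thermal.tiff --roi demo/roi.json --out demo/motion.csv
nirsmoco correct --fnirs demo/fnirs.csv \
                 --motion demo/motion_det0.csv,demo/motion_det1.csv \
                 --threshold 0.6 --out demo/corrected.csv
nirsmoco evaluate --seed 0 --replicates 5 --sweep --out demo/sweep.csv
```

Formats: multipage 32-bit float TIFF (°C) for thermal video; CSV for time
series (`time,ch1..chN` and `time,displacement_px,gamma,interpolated`);
JSON for ROI specs, ground truth and per-run provenance records; optional
SNIRF (HDF5) import.

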