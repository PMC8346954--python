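"""Exclusion-mask construction and end-to-end channel correction."""

import numpy as np
import pytest

from nirsmoco import simulate
from nirsmoco.containers import (
    CoherenceMap,
    CorrectionConfig,
    FnirsRecording,
    MotionEventSet,
    MotionTrace,
    Scalogram,
    WaveletParams,
)
from nirsmoco.correction import build_mask, correct_channel, correct_recording

FS = 10.0


def _toy_maps(motion_mag, coh_vals):
    motion_mag = np.asarray(motion_mag, dtype=float)
    coh_vals = np.asarray(coh_vals, dtype=float)
    freqs = np.geomspace(1.0, 0.1, motion_mag.shape[0])
    sg = Scalogram(
        coefficients=motion_mag.astype(complex),
        frequencies=freqs,
        scales=1.0 / freqs,
        fs=FS,
        coi=np.full(motion_mag.shape[1], 5.0),
        params=WaveletParams(),
    )
    cm = CoherenceMap(values=coh_vals, frequencies=freqs, fs=FS)
    return sg, cm


class TestBuildMask:
    def test_hand_enumerated_intersection_and_union(self):
        motion = [[1.0, 0.2, 0.8, 0.1],
                  [0.7, 0.9, 0.1, 0.0],
                  [0.3, 0.65, 0.0, 1.0],
                  [0.0, 0.0, 0.61, 0.5]]
        coh = [[0.9, 0.9, 0.1, 0.9],
               [0.1, 0.7, 0.9, 0.9],
               [0.9, 0.5, 0.9, 0.61],
               [0.9, 0.9, 0.62, 0.0]]
        sg, cm = _toy_maps(motion, coh)
        inter = build_mask(sg, cm, CorrectionConfig(threshold=0.6))
        # hand enumeration: motion>0.6 AND coh>0.6
        expect_inter = np.array(
            [[1, 0, 0, 0],
             [0, 1, 0, 0],
             [0, 0, 0, 1],
             [0, 0, 1, 0]], dtype=bool)
        np.testing.assert_array_equal(inter, expect_inter)
        union = build_mask(sg, cm, CorrectionConfig(threshold=0.6, combine_rule="union"))
        expect_union = np.array(
            [[1, 1, 1, 1],
             [1, 1, 1, 1],
             [1, 1, 1, 1],
             [1, 1, 1, 0]], dtype=bool)
        np.testing.assert_array_equal(union, expect_union)

    def test_threshold_above_one_empty(self):
        sg, cm = _toy_maps(np.random.default_rng(0).uniform(size=(4, 4)), np.ones((4, 4)))
        assert not build_mask(sg, cm, CorrectionConfig(threshold=1.01)).any()

    def test_all_zero_motion_empty_mask(self):
        sg, cm = _toy_maps(np.zeros((4, 4)), np.ones((4, 4)))
        assert not build_mask(sg, cm, CorrectionConfig(threshold=0.5)).any()

    @pytest.mark.parametrize("rule", ["intersection", "union"])
    def test_monotone_shrinking_in_threshold(self, rule):
        rng = np.random.default_rng(4)
        sg, cm = _toy_maps(rng.uniform(size=(12, 40)), rng.uniform(size=(12, 40)))
        prev = None
        for thr in (0.4, 0.5, 0.6, 0.7, 0.8):
            mask = build_mask(sg, cm, CorrectionConfig(threshold=thr, combine_rule=rule))
            if prev is not None:
                assert np.all(prev | ~mask)  # mask is a subset of the previous
            prev = mask

    def test_incongruent_grids_rejected(self):
        sg, _ = _toy_maps(np.zeros((4, 4)), np.zeros((4, 4)))
        _, cm = _toy_maps(np.zeros((5, 4)), np.zeros((5, 4)))
        with pytest.raises(ValueError):
            build_mask(sg, cm)


def _artifact_channel(kind="spike", seed=0):
    """Physiology + HRF blocks + one motion-coupled artifact, with truth."""
    dur = 300.0
    rec, _ = simulate.synth_resting_fnirs(fs=FS, duration=dur, n_channels=1, seed=seed)
    paradigm = simulate.default_paradigm(dur)
    hrf = simulate.canonical_hrf(FS)
    box = simulate.make_boxcar(paradigm, FS)
    peak = np.convolve(box, hrf)[: len(box)].max()
    rec, gt = simulate.add_activation(rec, paradigm, hrf, 0.02 / peak)
    ev = MotionEventSet((150.0,), (kind,), (10.0,), (0.12,))
    trace = simulate.synth_motion_trace(ev, FS, dur)
    corrupted, art_gt = simulate.inject_motion_artifacts(
        rec, trace, ev, channel_gains=np.ones((1, 1))
    )
    return corrupted.data[0], art_gt.clean_signal[0], trace


class TestCorrectChannel:
    def test_zero_motion_returns_input_unchanged(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(size=600)
        trace = MotionTrace(values=np.zeros(600), fs=FS)
        out = correct_channel(sig, trace)
        np.testing.assert_allclose(out, sig, atol=1e-12)

    def test_spike_artifact_mse_reduced(self):
        corrupted, clean, trace = _artifact_channel("spike")
        corrected = correct_channel(corrupted, trace)
        assert np.mean((corrected - clean) ** 2) < np.mean((corrupted - clean) ** 2)

    def test_step_contrast_reduced(self):
        corrupted, clean, trace = _artifact_channel("shift")
        corrected = correct_channel(corrupted, trace)
        t = np.arange(len(corrupted)) / FS
        def contrast(x):
            return abs(x[t > 160].mean() - x[t < 140].mean())
        assert contrast(corrected - clean) < contrast(corrupted - clean)

    def test_length_mismatch_rejected(self):
        trace = MotionTrace(values=np.zeros(100), fs=FS)
        with pytest.raises(ValueError):
            correct_channel(np.zeros(200), trace)

    def test_motion_nan_gaps_filled(self):
        corrupted, clean, trace = _artifact_channel("spike", seed=2)
        vals = trace.values.copy()
        vals[700:705] = np.nan
        gappy = MotionTrace(values=vals, fs=FS)
        out, diag = correct_channel(corrupted, gappy, return_diagnostics=True)
        assert np.all(np.isfinite(out))

    def test_diagnostics_report_occupancy(self):
        corrupted, _, trace = _artifact_channel("spike", seed=3)
        _, diag = correct_channel(corrupted, trace, return_diagnostics=True)
        assert 0.0 < diag["mask_occupancy"] < 0.5


class TestCorrectRecording:
    def _recording(self, n_channels=4, n_detectors=2, seed=0):
        dur = 300.0
        rec, _ = simulate.synth_resting_fnirs(
            fs=FS, duration=dur, n_channels=n_channels, n_detectors=n_detectors, seed=seed
        )
        ev = simulate.random_motion_events(n_events=4, duration=dur, seed=seed)
        traces = {
            d: simulate.synth_motion_trace(ev, FS, dur) for d in range(n_detectors)
        }
        return rec, traces

    def test_scalogram_sharing_per_detector(self, monkeypatch):
        # 4 channels on 2 detectors: 2 motion scalograms, 4 signal scalograms
        import nirsmoco.correction as corr_mod

        calls = {"cwt": 0, "wcoh": 0}
        real_cwt, real_wcoh = corr_mod.cwt_morse, corr_mod.wcoh_morlet

        def counting_cwt(*a, **k):
            calls["cwt"] += 1
            return real_cwt(*a, **k)

        def counting_wcoh(*a, **k):
            calls["wcoh"] += 1
            return real_wcoh(*a, **k)

        monkeypatch.setattr(corr_mod, "cwt_morse", counting_cwt)
        monkeypatch.setattr(corr_mod, "wcoh_morlet", counting_wcoh)
        rec, traces = self._recording()
        correct_recording(rec, traces)
        assert calls["cwt"] == 2 + 4  # per-detector motion + per-channel signal
        assert calls["wcoh"] == 4  # coherence is channel-specific

    def test_identical_channels_identical_outputs(self):
        rec, traces = self._recording(n_channels=2, n_detectors=1)
        rec.data[1] = rec.data[0]
        result = correct_recording(rec, traces)
        np.testing.assert_array_equal(result.corrected[0], result.corrected[1])

    def test_zero_traces_identity(self):
        rec, traces = self._recording()
        for tr in traces.values():
            tr.values[:] = 0.0
        result = correct_recording(rec, traces)
        np.testing.assert_allclose(result.corrected, rec.data, atol=1e-12)
        assert not result.mask_occupancy.any()

    def test_missing_trace_names_channel(self):
        rec, traces = self._recording()
        del traces[1]
        with pytest.raises(ValueError, match="ch2"):
            correct_recording(rec, traces)


class TestPipelineInvariants:
    def test_idempotence_no_runaway_erosion(self):
        corrupted, _, trace = _artifact_channel("spike", seed=5)
        once = correct_channel(corrupted, trace)
        twice = correct_channel(once, trace)
        extra = np.sqrt(np.mean((twice - once) ** 2)) / np.sqrt(np.mean(once**2))
        assert extra < 0.05

    def test_specificity_motion_free_beta_stable(self):
        from nirsmoco.evaluation import glm_fit

        dur = 300.0
        rec, _ = simulate.synth_resting_fnirs(fs=FS, duration=dur, n_channels=1, seed=6)
        paradigm = simulate.default_paradigm(dur)
        hrf = simulate.canonical_hrf(FS)
        box = simulate.make_boxcar(paradigm, FS)
        peak = np.convolve(box, hrf)[: len(box)].max()
        rec, gt = simulate.add_activation(rec, paradigm, hrf, 0.02 / peak)
        regressor = gt.injected_activation / 0.02
        trace = MotionTrace(values=np.zeros(rec.n_samples), fs=FS)
        corrected = correct_channel(rec.data[0], trace)
        b0 = glm_fit(rec.data[0], regressor).beta
        b1 = glm_fit(corrected, regressor).beta
        assert abs(b1 - b0) / abs(b0) < 0.05
        # signal energy essentially unchanged (interior)
        e0 = np.sum(rec.data[0, 100:-100] ** 2)
        e1 = np.sum(corrected[100:-100] ** 2)
        assert abs(e1 - e0) / e0 < 0.05
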