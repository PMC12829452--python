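"""Preprocessing: filtering, cropping, ocular-component removal,
re-referencing, epoching and amplitude rejection."""

import numpy as np
import pytest

from eegdx.preprocess import (
    EpochSet,
    PreprocConfig,
    PreprocessingError,
    common_average_reference,
    crop_recording,
    filter_recording,
    n_epochs_expected,
    preprocess_subject,
    reject_epochs,
    remove_ocular_components,
    segment_epochs,
    subject_exclusion_report,
)
from eegdx.simulate import SimConfig, generate_cohort, inject_blinks, inject_noise_bursts

from conftest import make_recording


def tone(freq, sr=256.0, seconds=10.0, amp=10.0):
    t = np.arange(int(sr * seconds)) / sr
    return amp * np.sin(2 * np.pi * freq * t)


class TestFilter:
    # steady-state response is measured on the central region: zero-phase
    # FIR filtering of a full-duration tone rings at the signal edges
    _core = slice(512, -512)

    def test_notch_attenuates_line_frequency(self):
        rec = make_recording(np.tile(tone(60.0), (2, 1)))
        out = filter_recording(rec, PreprocConfig())
        in_rms = np.sqrt((rec.eeg[0, self._core] ** 2).mean())
        out_rms = np.sqrt((out.eeg[0, self._core] ** 2).mean())
        assert out_rms < 0.10 * in_rms
        assert out.eeg.shape == rec.eeg.shape

    def test_passband_tone_preserved(self):
        rec = make_recording(np.tile(tone(10.0), (2, 1)))
        out = filter_recording(rec, PreprocConfig())
        in_rms = np.sqrt((rec.eeg[0, self._core] ** 2).mean())
        out_rms = np.sqrt((out.eeg[0, self._core] ** 2).mean())
        assert abs(out_rms - in_rms) < 0.10 * in_rms

    def test_zero_signal_stays_zero(self):
        rec = make_recording(np.zeros((2, 2560)))
        out = filter_recording(rec, PreprocConfig())
        assert np.allclose(out.eeg, 0.0)

    def test_cutoff_above_nyquist_rejected(self):
        rec = make_recording(np.zeros((2, 2560)), sample_rate=64.0)
        with pytest.raises(PreprocessingError):
            filter_recording(rec, PreprocConfig(bandpass_high=50.0))


class TestCrop:
    def test_crop_sample_arithmetic(self):
        rec = make_recording(np.random.default_rng(0).normal(size=(2, 300 * 64)), sample_rate=64.0)
        out = crop_recording(rec, 240.0)
        assert out.eeg.shape[1] == 240 * 64

    def test_crop_to_own_length_is_identity(self):
        rec = make_recording(np.random.default_rng(0).normal(size=(2, 240 * 64)), sample_rate=64.0)
        out = crop_recording(rec, 240.0)
        assert np.array_equal(out.eeg, rec.eeg)

    def test_short_recording_error_names_subject(self):
        rec = make_recording(np.zeros((2, 200 * 64)), sample_rate=64.0, subject_id="sub-07")
        with pytest.raises(PreprocessingError, match="sub-07"):
            crop_recording(rec, 240.0)


class TestCommonAverageReference:
    def test_constant_offset_removed(self):
        rec = make_recording(np.full((4, 256), 7.5))
        out = common_average_reference(rec)
        assert np.allclose(out.eeg, 0.0)

    def test_per_sample_channel_mean_is_zero(self, tiny_recording):
        out = common_average_reference(tiny_recording)
        assert np.abs(out.eeg.mean(axis=0)).max() < 1e-9

    def test_idempotent(self, tiny_recording):
        once = common_average_reference(tiny_recording)
        twice = common_average_reference(once)
        assert np.allclose(once.eeg, twice.eeg)

    def test_single_channel_rejected(self):
        rec = make_recording(np.zeros((1, 256)))
        with pytest.raises(PreprocessingError):
            common_average_reference(rec)


class TestSegmentation:
    def test_full_duration_epoch_count(self):
        # 240 s, 4-s windows, 2-s step -> 119 fully contained epochs
        assert n_epochs_expected(240.0, 4.0, 2.0) == 119

    def test_counting_examples(self):
        rec = make_recording(np.random.default_rng(1).normal(size=(2, 10 * 64)), sample_rate=64.0)
        eps = segment_epochs(rec, PreprocConfig())
        assert eps.n_epochs == 4
        assert np.allclose(eps.onsets, [0, 2, 4, 6])
        rec4 = make_recording(np.zeros((2, 4 * 64)), sample_rate=64.0)
        assert segment_epochs(rec4, PreprocConfig()).n_epochs == 1

    def test_count_formula_matches_brute_force_enumerator(self):
        """Window-placement counting oracle over 200 random (T, L, S)."""
        rng = np.random.default_rng(12)
        for _ in range(200):
            length = rng.uniform(0.5, 10.0)
            step = rng.uniform(0.1, length)
            duration = rng.uniform(length, 60.0)
            brute = 0
            onset = 0.0
            while onset + length <= duration + 1e-9:
                brute += 1
                onset += step
            assert n_epochs_expected(duration, length, step) == brute

    def test_overlap_not_smaller_than_length_rejected(self):
        with pytest.raises(PreprocessingError):
            PreprocConfig(epoch_length=4.0, epoch_overlap=4.0)

    def test_segmentation_commutes_with_referencing(self, tiny_recording):
        cfg = PreprocConfig()
        a = segment_epochs(common_average_reference(tiny_recording), cfg)
        b = segment_epochs(tiny_recording, cfg)
        b_ref = b.epochs - b.epochs.mean(axis=1, keepdims=True)
        assert np.allclose(a.epochs, b_ref, atol=1e-9)


class TestRejection:
    def _epoch_set(self, epochs):
        n = epochs.shape[0]
        return EpochSet(
            subject_id="s",
            group=0,
            sample_rate=64.0,
            epochs=epochs,
            onsets=np.arange(n) * 2.0,
            kept_mask=np.ones(n, bool),
        )

    def test_peak_to_peak_boundary(self):
        quiet = np.zeros((2, 256))
        loud = np.zeros((2, 256))
        loud[0, 10], loud[0, 20] = 145.0, -160.0  # p2p 305
        ok = np.zeros((2, 256))
        ok[0, 10], ok[0, 20] = 149.0, -149.0  # p2p 298
        eps = self._epoch_set(np.stack([quiet, loud, ok]))
        out = reject_epochs(eps, PreprocConfig())
        assert out.kept_mask.tolist() == [True, False, True]
        assert out.n_epochs == 2

    def test_idempotent_on_kept_epochs(self, tiny_recording):
        eps = segment_epochs(tiny_recording, PreprocConfig())
        once = reject_epochs(eps, PreprocConfig())
        twice = reject_epochs(once, PreprocConfig())
        assert np.array_equal(once.epochs, twice.epochs)
        assert twice.kept_mask.all()

    def test_rejection_matches_generator_ground_truth(self):
        """Epochs overlapping injected noise-burst spans — and only
        those — are dropped."""
        cfg = SimConfig.test_scale(1, seed=23, blink_rate=0.0, noise_burst_prob=0.4)
        recs, _ = generate_cohort(cfg)
        rec = recs[0]
        spans = rec.annotations["noise_spans_s"]
        assert spans, "fixture must contain bursts"
        pcfg = PreprocConfig(crop_seconds=60.0)
        x = common_average_reference(crop_recording(filter_recording(rec, pcfg), 60.0))
        eps = segment_epochs(x, pcfg)
        out = reject_epochs(eps, pcfg)
        expected_drop = np.array(
            [
                any(onset < end and start < onset + 4.0 for start, end in spans)
                for onset in eps.onsets
            ]
        )
        assert np.array_equal(out.kept_mask, ~expected_drop)


class TestOcularRemoval:
    def test_blink_free_recording_removes_nothing(self, tiny_recording):
        cfg = PreprocConfig(n_ica_components=6)
        _, report = remove_ocular_components(tiny_recording, cfg)
        assert report.removed == []
        assert len(report.scores) <= cfg.n_ica_components

    def test_blink_component_removed_and_correlation_drops(self):
        cfg = SimConfig.test_scale(1, seed=31, duration=60.0, blink_rate=0.0, noise_burst_prob=0.0)
        recs, _ = generate_cohort(cfg)
        rec = inject_blinks(recs[0], rate=20.0, seed=5)
        pcfg = PreprocConfig(n_ica_components=6, eog_match_threshold=2.0)

        def eog_frontal_corr(r):
            return max(
                abs(np.corrcoef(r.eog[i], r.eeg[0])[0, 1]) for i in range(2)
            )

        cleaned, report = remove_ocular_components(rec, pcfg)
        assert len(report.removed) >= 1
        assert len(report.removed) <= pcfg.n_ica_components
        assert eog_frontal_corr(cleaned) < eog_frontal_corr(rec)

    def test_requires_eog_channel(self, tiny_recording):
        rec = tiny_recording.copy()
        rec.eog = np.empty((0, rec.n_samples))
        rec.channel_names = rec.channel_names[:8]
        with pytest.raises(PreprocessingError):
            remove_ocular_components(rec, PreprocConfig(n_ica_components=6))

    def test_component_count_bounded_by_channels(self, tiny_recording):
        with pytest.raises(PreprocessingError):
            remove_ocular_components(tiny_recording, PreprocConfig(n_ica_components=15))


class TestPipeline:
    def test_audit_log_records_fixed_stage_order(self, tiny_recording):
        cfg = PreprocConfig(crop_seconds=20.0, n_ica_components=6)
        _, audit = preprocess_subject(tiny_recording, cfg)
        steps = [s["step"] for s in audit["steps"]]
        assert steps == [
            "filter",
            "crop",
            "ica_removal",
            "common_average_reference",
            "segment",
            "reject",
        ]

    def test_subject_exclusion_report_flags_noisy_subject(self):
        cfg = SimConfig.test_scale(1, seed=41, duration=20.0, blink_rate=0.0, noise_burst_prob=0.0)
        recs, _ = generate_cohort(cfg)
        noisy = inject_noise_bursts(recs[0], prob=1.0, amplitude=400.0, seed=1)
        eps = segment_epochs(noisy, PreprocConfig())
        rep = subject_exclusion_report(eps, threshold_uv=250.0)
        assert rep["exclude"]
        clean_eps = segment_epochs(recs[0], PreprocConfig())
        assert not subject_exclusion_report(clean_eps, threshold_uv=250.0)["exclude"]


def test_epoch_set_disk_round_trip(tmp_path, tiny_recording):
    from eegdx.preprocess import load_epochs, save_epochs

    eps = segment_epochs(tiny_recording, PreprocConfig())
    save_epochs(eps, tmp_path / "e")
    back = load_epochs(tmp_path / "e")
    assert np.array_equal(back.epochs, eps.epochs)
    assert np.array_equal(back.onsets, eps.onsets)
    assert back.subject_id == eps.subject_id
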