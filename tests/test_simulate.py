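"""Synthetic cohort generator: determinism, spectral shape, group
effects, artifact injection and covariate distributions."""

import numpy as np
import pytest
from scipy import signal, stats

import eegdx
from eegdx.simulate import (
    CANONICAL_BANDS,
    COVARIATE_DISTRIBUTIONS,
    SCORE_RANGES,
    SimConfig,
    SimulationError,
    band_power_target_channels,
    burst_chirp_statistic,
    generate_cohort,
    generate_covariates,
    inject_blinks,
    inject_noise_bursts,
)


def welch_band_power(x, sr, lo, hi):
    """Independent Welch-PSD oracle for mean band power of a 1-D signal."""
    freqs, psd = signal.welch(x, fs=sr, nperseg=int(2 * sr))
    mask = (freqs >= lo) & (freqs < hi)
    return psd[mask].mean()


def quiet_config(**kw):
    kw.setdefault("blink_rate", 0.0)
    kw.setdefault("noise_burst_prob", 0.0)
    return SimConfig.test_scale(**kw)


class TestCohortBasics:
    def test_balanced_groups_and_shapes(self):
        cfg = quiet_config(n_per_group=3, seed=1, duration=20.0)
        recs, cov = generate_cohort(cfg)
        assert len(recs) == 6
        assert sum(r.group for r in recs) == 3
        for r in recs:
            assert r.eeg.shape == (8, int(20 * 256))
            assert r.eog.shape == (2, int(20 * 256))
            assert len(set(r.channel_names)) == 10
        assert len(cov) == 6
        assert set(cov.subject_id) == {r.subject_id for r in recs}

    def test_bitwise_determinism_from_seed(self):
        cfg = SimConfig.test_scale(2, seed=9, duration=20.0, effect_kind="band_power")
        a_recs, a_cov = generate_cohort(cfg)
        b_recs, b_cov = generate_cohort(cfg)
        for a, b in zip(a_recs, b_recs):
            assert np.array_equal(a.eeg, b.eeg)
            assert np.array_equal(a.eog, b.eog)
        assert a_cov.equals(b_cov)

    @pytest.mark.parametrize("bad", [
        dict(n_per_group=0),
        dict(n_per_group=1, noise_burst_prob=1.5),
        dict(n_per_group=1, effect_size=-1.0),
        dict(n_per_group=1, effect_kind="weird"),
        dict(n_per_group=1, one_over_f_exponent=3.0),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(SimulationError):
            SimConfig.test_scale(**bad)


class TestBackgroundSpectrum:
    @pytest.mark.parametrize("beta", [0.8, 1.6])
    def test_one_over_f_slope_by_loglog_regression(self, beta):
        """Log-log PSD regression on an alpha-free channel recovers the
        configured spectral exponent."""
        cfg = quiet_config(
            n_per_group=1, seed=21, duration=60.0,
            alpha_amplitude_uv=0.0, one_over_f_exponent=beta,
        )
        recs, _ = generate_cohort(cfg)
        x = recs[0].eeg[0]
        freqs, psd = signal.welch(x, fs=256.0, nperseg=int(4 * 256))
        mask = (freqs >= 2) & (freqs <= 40)
        slope = np.polyfit(np.log(freqs[mask]), np.log(psd[mask]), 1)[0]
        assert slope == pytest.approx(-beta, abs=0.3)

    def test_alpha_rhythm_occipital_dominant(self):
        cfg = quiet_config(n_per_group=1, seed=2, duration=40.0)
        recs, _ = generate_cohort(cfg)
        r = recs[0]
        alpha_occ = welch_band_power(r.eeg[-1], r.sample_rate, 8, 13)
        alpha_front = welch_band_power(r.eeg[0], r.sample_rate, 8, 13)
        assert alpha_occ > 2 * alpha_front


class TestGroupEffects:
    def test_no_effect_means_no_band_power_separation(self):
        cfg = quiet_config(n_per_group=10, seed=7, duration=30.0, effect_kind="none")
        recs, _ = generate_cohort(cfg)
        n_nonsig = 0
        for lo, hi in CANONICAL_BANDS.values():
            p0 = [np.mean([welch_band_power(ch, r.sample_rate, lo, hi) for ch in r.eeg])
                  for r in recs if r.group == 0]
            p1 = [np.mean([welch_band_power(ch, r.sample_rate, lo, hi) for ch in r.eeg])
                  for r in recs if r.group == 1]
            if stats.ttest_ind(p0, p1).pvalue > 0.05:
                n_nonsig += 1
        assert n_nonsig >= 4

    def test_band_power_effect_elevates_theta_on_targets(self):
        cfg = quiet_config(
            n_per_group=4, seed=5, duration=30.0,
            effect_kind="band_power", effect_size=1.0,
        )
        recs, _ = generate_cohort(cfg)
        targets = band_power_target_channels(8)
        lo, hi = CANONICAL_BANDS["theta"]
        theta = {0: [], 1: []}
        for r in recs:
            theta[r.group].append(
                np.mean([welch_band_power(r.eeg[ch], r.sample_rate, lo, hi) for ch in targets])
            )
        assert np.mean(theta[1]) > np.mean(theta[0])

    def test_spectrotemporal_band_power_matched_within_two_percent(self):
        cfg = quiet_config(
            n_per_group=5, seed=13, duration=30.0,
            effect_kind="spectrotemporal", effect_size=1.0,
        )
        recs, _ = generate_cohort(cfg)  # would raise if matching failed
        for lo, hi in CANONICAL_BANDS.values():
            for ch in range(8):
                p0 = np.mean([welch_band_power(r.eeg[ch], r.sample_rate, lo, hi)
                              for r in recs if r.group == 0])
                p1 = np.mean([welch_band_power(r.eeg[ch], r.sample_rate, lo, hi)
                              for r in recs if r.group == 1])
                assert 0.98 <= p1 / p0 <= 1.02

    def test_spectrotemporal_band_power_features_carry_no_group_signal(self):
        """Epoch-level band-power features from the chirp cohort show no
        usable per-feature group separation (mean absolute standardized
        difference well below 0.25)."""
        from eegdx.bandpower import band_power_features
        from eegdx.preprocess import PreprocConfig, segment_epochs

        cfg = quiet_config(
            n_per_group=5, seed=13, duration=60.0,
            effect_kind="spectrotemporal", effect_size=1.0,
        )
        recs, _ = generate_cohort(cfg)
        feats, groups = [], []
        for r in recs:
            f = band_power_features(segment_epochs(r, PreprocConfig()))
            feats.append(f)
            groups.append(np.full(f.shape[0], r.group))
        x = np.concatenate(feats)
        y = np.concatenate(groups)
        sd = np.sqrt(0.5 * (x[y == 1].var(0) + x[y == 0].var(0)))
        d = np.abs((x[y == 1].mean(0) - x[y == 0].mean(0)) / sd)
        assert d.max() < 0.25

    def test_chirp_direction_statistic_separates_groups(self):
        """The measured sub-band arrival-lag statistic flips sign with
        the injected chirp direction and differs between groups by a
        standardized difference far above 1."""
        cfg = quiet_config(
            n_per_group=5, seed=13, duration=30.0,
            effect_kind="spectrotemporal", effect_size=1.0,
        )
        recs, _ = generate_cohort(cfg)
        s0 = [burst_chirp_statistic(r) for r in recs if r.group == 0]
        s1 = [burst_chirp_statistic(r) for r in recs if r.group == 1]
        assert max(s0) < 0 < min(s1)  # downward vs upward sweeps
        pooled_sd = np.sqrt(0.5 * (np.var(s0) + np.var(s1))) + 1e-12
        assert abs(np.mean(s0) - np.mean(s1)) / pooled_sd > 1.0


class TestBlinkInjection:
    def test_zero_rate_is_identity(self, tiny_recording):
        out = inject_blinks(tiny_recording, rate=0.0, seed=1)
        assert np.array_equal(out.eeg, tiny_recording.eeg)
        assert np.array_equal(out.eog, tiny_recording.eog)

    def test_blinks_raise_eog_frontal_correlation(self, tiny_recording):
        def max_corr(rec):
            return max(
                abs(np.corrcoef(rec.eog[i], rec.eeg[0])[0, 1])
                for i in range(rec.eog.shape[0])
            )

        before = max_corr(tiny_recording)
        blinked = inject_blinks(tiny_recording, rate=20.0, seed=4)
        assert max_corr(blinked) > before

    def test_deterministic_given_seed(self, tiny_recording):
        a = inject_blinks(tiny_recording, rate=20.0, seed=6)
        b = inject_blinks(tiny_recording, rate=20.0, seed=6)
        assert np.array_equal(a.eeg, b.eeg)
        assert a.annotations["blink_times_s"] == b.annotations["blink_times_s"]

    def test_negative_rate_rejected(self, tiny_recording):
        with pytest.raises(SimulationError):
            inject_blinks(tiny_recording, rate=-1.0, seed=0)


class TestNoiseBurstInjection:
    def test_zero_probability_is_identity(self, tiny_recording):
        out = inject_noise_bursts(tiny_recording, prob=0.0, amplitude=400.0, seed=2)
        assert np.array_equal(out.eeg, tiny_recording.eeg)

    def test_prob_one_marks_every_span_above_amplitude(self, tiny_recording):
        out = inject_noise_bursts(tiny_recording, prob=1.0, amplitude=400.0, seed=2)
        spans = out.annotations["noise_spans_s"]
        assert len(spans) == int(tiny_recording.duration // 4)
        sr = out.sample_rate
        for start, end in spans:
            seg = out.eeg[:, int(start * sr) : int(end * sr)]
            p2p = (seg.max(axis=1) - seg.min(axis=1)).max()
            assert p2p > 400.0

    def test_marked_spans_reproducible(self, tiny_recording):
        a = inject_noise_bursts(tiny_recording, prob=0.5, amplitude=400.0, seed=8)
        b = inject_noise_bursts(tiny_recording, prob=0.5, amplitude=400.0, seed=8)
        assert a.annotations["noise_spans_s"] == b.annotations["noise_spans_s"]
        assert np.array_equal(a.eeg, b.eeg)

    def test_invalid_probability_rejected(self, tiny_recording):
        with pytest.raises(SimulationError):
            inject_noise_bursts(tiny_recording, prob=1.5, amplitude=400.0, seed=0)


class TestCovariates:
    def test_ranges_and_missingness(self):
        cfg = quiet_config(n_per_group=10, seed=3, duration=4.0)
        _, cov = generate_cohort(cfg)
        for name, (lo, hi) in SCORE_RANGES.items():
            vals = cov[name].dropna()
            assert vals.between(lo, hi).all()
        assert cov["age"].isna().sum() == 1
        assert cov["mis_score"].isna().sum() == 2

    def test_sample_means_converge_to_clipped_normal_expectation(self):
        """Law-of-large-numbers check at n = 2000 against the scipy
        closed form for the mean of a normal clipped to the instrument
        range (tolerance 3 standard errors)."""
        n = 2000
        cfg = SimConfig.test_scale(n // 2, seed=17, n_missing_age=0, n_missing_mis=0)
        rng = np.random.default_rng(123)
        ids = [f"s{i}" for i in range(n)]
        groups = [i % 2 for i in range(n)]
        cov = generate_covariates(cfg, ids, groups, rng)
        for name, per_group in COVARIATE_DISTRIBUTIONS.items():
            if name == "age":
                lo, hi = 18.0, 90.0
            else:
                lo, hi = SCORE_RANGES[name]
            for g in (0, 1):
                m, sd = per_group[g]
                a, b = (lo - m) / sd, (hi - m) / sd
                # E[clip(X, lo, hi)] for X ~ N(m, sd)
                expected = (
                    lo * stats.norm.cdf(a)
                    + hi * stats.norm.sf(b)
                    + m * (stats.norm.cdf(b) - stats.norm.cdf(a))
                    - sd * (stats.norm.pdf(b) - stats.norm.pdf(a))
                )
                sample = cov.loc[cov.group == g, name]
                se = sample.std() / np.sqrt(len(sample))
                assert abs(sample.mean() - expected) < 3 * se

    def test_separation_zero_removes_group_difference(self):
        cfg = SimConfig.test_scale(
            500, seed=29, covariate_separation=0.0, n_missing_age=0, n_missing_mis=0
        )
        rng = np.random.default_rng(11)
        ids = [f"s{i}" for i in range(1000)]
        groups = [i % 2 for i in range(1000)]
        cov = generate_covariates(cfg, ids, groups, rng)
        m0 = cov.loc[cov.group == 0, "bdi_total"].mean()
        m1 = cov.loc[cov.group == 1, "bdi_total"].mean()
        assert abs(m0 - m1) < 2.0
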