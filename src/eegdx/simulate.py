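"""Seeded synthetic resting-state EEG cohorts with controllable group effects.

The generator stands in for an undeposited two-group resting EEG study
(cases vs healthy controls, balanced). Each subject is a multichannel
recording in microvolts: 1/f^beta background noise on every channel, an
occipital-dominant ~10 Hz alpha oscillation, plus optional artifacts
(frontal blink transients mirrored on EOG channels, sporadic
high-amplitude noise bursts) and one of two group effects:

``band_power``
    multiplicative theta-band (4-8 Hz) power elevation on a fixed
    fronto-central channel subset of the case group, scaled by
    ``effect_size`` — a classic spectral-power group difference that
    band-power features can see.

``spectrotemporal``
    transient cross-channel beta-band chirp bursts occur in *both*
    groups at the same rate, amplitude and latencies; only the chirp
    *direction* differs (upward sweeps in cases, downward in controls).
    Time reversal leaves the power spectrum unchanged, so every
    time-averaged band-power feature is distribution-matched between
    groups by symmetry; per-channel per-band long-run power is
    additionally rescaled post hoc to agree within 2% in all five
    canonical bands. The group signal lives purely in the orientation of
    the burst in the time-frequency plane — visible to a time-frequency
    model, invisible to band power.

Channels are ordered anterior -> posterior: low indices are frontal
(blink-dominant), high indices occipital (alpha-dominant).

Everything is reproducible bit-for-bit from ``SimConfig.seed``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "SimConfig",
    "RawRecording",
    "SimulationError",
    "generate_cohort",
    "generate_covariates",
    "inject_blinks",
    "inject_noise_bursts",
    "band_power_target_channels",
    "burst_chirp_statistic",
    "COVARIATE_DISTRIBUTIONS",
    "SCORE_RANGES",
]


class SimulationError(ValueError):
    """Raised when a simulation precondition or postcondition fails."""


EFFECT_KINDS = ("none", "band_power", "spectrotemporal")

#: canonical EEG frequency bands, Hz (half-open [low, high))
CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 45.0),
}

#: instrument score ranges (inclusive)
SCORE_RANGES = {
    "docs_total": (0.0, 80.0),
    "mis_score": (0.0, 30.0),
    "bai_total": (0.0, 63.0),
    "bdi_total": (0.0, 63.0),
}

#: per-group (mean, sd) defaults for the continuous covariates; keys are
#: group codes 1 = case (OCD), 0 = healthy control
COVARIATE_DISTRIBUTIONS: dict[str, dict[int, tuple[float, float]]] = {
    "docs_total": {1: (20.80, 17.99), 0: (13.20, 15.91)},
    "mis_score": {1: (5.90, 5.92), 0: (8.38, 6.97)},
    "bai_total": {1: (13.30, 11.87), 0: (13.80, 15.32)},
    "bdi_total": {1: (16.00, 14.50), 0: (7.00, 10.98)},
    "age": {1: (34.89, 14.41), 0: (35.90, 13.31)},
}

AGE_RANGE = (18.0, 90.0)

#: P(male) per group and education level probabilities per group
SEX_P_MALE = {1: 0.60, 0: 0.70}
EDUCATION_LEVELS = (
    "some_college",
    "bachelor",
    "masters",
    "doctoral",
    "other_professional",
)
EDUCATION_P = {
    1: (0.2, 0.2, 0.0, 0.4, 0.2),
    0: (0.0, 0.0, 0.1, 0.2, 0.7),
}

# spectrotemporal burst parameters (seconds / Hz / dimensionless)
_BURST_PERIOD_S = 2.0       # one burst per channel per 2-s segment, both groups
_BURST_FREQ_HZ = 20.0
_BURST_SIGMA_S = 0.10       # Gaussian envelope SD
_CHIRP_SPAN_HZ = 24.0       # total instantaneous-frequency sweep per burst
_BAND_MATCH_TOL = 0.02


@dataclass(frozen=True)
class SimConfig:
    """Cohort simulation parameters. Defaults mirror the full-scale study
    conditions (68 EEG + 2 EOG channels, 1024 Hz, 240 s eyes-open rest)."""

    n_per_group: int
    n_eeg_channels: int = 68
    n_eog_channels: int = 2
    sample_rate: float = 1024.0
    duration: float = 240.0
    effect_kind: str = "none"
    effect_size: float = 1.0
    blink_rate: float = 12.0          # events / minute
    noise_burst_prob: float = 0.05    # per non-overlapping 4-s span
    noise_burst_amplitude: float = 400.0  # µV threshold the burst must exceed
    seed: int = 0
    # background signal
    one_over_f_exponent: float = 1.0  # beta of the 1/f^beta background
    noise_std_uv: float = 10.0
    alpha_amplitude_uv: float = 8.0
    alpha_freq_hz: float = 10.0
    # covariates
    covariate_separation: float = 1.0
    n_missing_age: int = 1
    n_missing_mis: int = 2

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise SimulationError("n_per_group must be >= 1")
        if self.sample_rate <= 0 or self.duration <= 0:
            raise SimulationError("sample_rate and duration must be positive")
        if not 0.0 <= self.noise_burst_prob <= 1.0:
            raise SimulationError("noise_burst_prob must be in [0, 1]")
        if self.effect_size < 0:
            raise SimulationError("effect_size must be >= 0")
        if self.effect_kind not in EFFECT_KINDS:
            raise SimulationError(
                f"effect_kind must be one of {EFFECT_KINDS}, got {self.effect_kind!r}"
            )
        if not 0.5 <= self.one_over_f_exponent <= 2.0:
            raise SimulationError("one_over_f_exponent must lie in [0.5, 2]")

    @classmethod
    def test_scale(cls, n_per_group: int, **kw) -> "SimConfig":
        """Desk-scale preset: 8 EEG + 2 EOG channels, 256 Hz, 60 s."""
        kw.setdefault("n_eeg_channels", 8)
        kw.setdefault("n_eog_channels", 2)
        kw.setdefault("sample_rate", 256.0)
        kw.setdefault("duration", 60.0)
        return cls(n_per_group=n_per_group, **kw)


@dataclass
class RawRecording:
    """One subject's continuous EEG + EOG, amplitudes in µV.

    ``annotations`` carries generator ground truth (blink times, noise
    burst spans, effect metadata) used by downstream tests.
    """

    subject_id: str
    group: int
    sample_rate: float
    eeg: np.ndarray  # (n_eeg_channels, n_samples)
    eog: np.ndarray  # (n_eog_channels, n_samples)
    channel_names: list[str]
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=np.float64)
        self.eog = np.asarray(self.eog, dtype=np.float64)
        if self.eeg.ndim != 2 or self.eog.ndim != 2:
            raise SimulationError("eeg and eog must be 2-D (channels x samples)")
        if self.eeg.shape[1] != self.eog.shape[1]:
            raise SimulationError("eeg and eog must share the sample count")
        if not np.isfinite(self.eeg).all() or not np.isfinite(self.eog).all():
            raise SimulationError(
                f"non-finite samples in recording {self.subject_id}"
            )
        n_ch = self.eeg.shape[0] + self.eog.shape[0]
        if len(self.channel_names) != n_ch:
            raise SimulationError("channel_names length must equal channel count")
        if len(set(self.channel_names)) != n_ch:
            raise SimulationError("channel_names must be unique")
        if self.group not in (0, 1):
            raise SimulationError("group must be 0 or 1")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def eeg_channel_names(self) -> list[str]:
        return self.channel_names[: self.eeg.shape[0]]

    def copy(self) -> "RawRecording":
        return RawRecording(
            subject_id=self.subject_id,
            group=self.group,
            sample_rate=self.sample_rate,
            eeg=self.eeg.copy(),
            eog=self.eog.copy(),
            channel_names=list(self.channel_names),
            annotations=copy.deepcopy(self.annotations),
        )


def band_power_target_channels(n_eeg: int) -> np.ndarray:
    """Fixed fronto-central channel subset carrying the theta elevation."""
    start = n_eeg // 8
    count = max(1, n_eeg // 4)
    return np.arange(start, min(start + count, n_eeg))


# ---------------------------------------------------------------------------
# signal primitives


def _one_over_f_noise(
    rng: np.random.Generator, n_ch: int, n_samp: int, sr: float, beta: float, std: float
) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^beta.

    Channels are calibrated so that the standard deviation of their
    0.5-45 Hz content equals ``std``: for shallow-slope 1/f noise most
    variance sits below the analysis band, and calibrating on the raw
    signal would couple every measured band to sub-delta drift sampling
    noise.
    """
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / sr)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    spec = (
        rng.standard_normal((n_ch, freqs.size))
        + 1j * rng.standard_normal((n_ch, freqs.size))
    ) * amp
    x = np.fft.irfft(spec, n=n_samp, axis=1)
    band = (freqs >= 0.5) & (freqs <= 45.0)
    if band.any():
        x_band = np.fft.irfft(np.where(band, spec, 0.0), n=n_samp, axis=1)
        sd = x_band.std(axis=1, keepdims=True)
    else:
        sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd * std


def _band_limited_noise(
    rng: np.random.Generator, n_samp: int, sr: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-variance Gaussian noise confined to [lo, hi) Hz."""
    freqs = np.fft.rfftfreq(n_samp, d=1.0 / sr)
    mask = (freqs >= lo) & (freqs < hi)
    spec = np.zeros(freqs.size, dtype=complex)
    spec[mask] = rng.standard_normal(mask.sum()) + 1j * rng.standard_normal(mask.sum())
    x = np.fft.irfft(spec, n=n_samp)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_power(x: np.ndarray, sr: float, lo: float, hi: float) -> float:
    """Mean periodogram power of a 1-D signal within [lo, hi) Hz."""
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sr)
    p = np.abs(np.fft.rfft(x)) ** 2 / x.size
    mask = (freqs >= lo) & (freqs < hi)
    return float(p[mask].mean()) if mask.any() else 0.0


def _alpha_oscillation(
    rng: np.random.Generator, cfg: SimConfig, n_samp: int
) -> np.ndarray:
    """Occipital-weighted, slowly amplitude-modulated alpha rhythm."""
    n_eeg = cfg.n_eeg_channels
    t = np.arange(n_samp) / cfg.sample_rate
    # slow positive envelope (waxing/waning alpha)
    env = 1.0 + 0.5 * _band_limited_noise(rng, n_samp, cfg.sample_rate, 0.05, 0.5)
    env = np.clip(env, 0.0, None)
    carrier = np.sin(2 * np.pi * cfg.alpha_freq_hz * t + rng.uniform(0, 2 * np.pi))
    idx = np.arange(n_eeg)
    occ_weight = np.exp(-(n_eeg - 1 - idx) / max(n_eeg / 6.0, 1.0))
    return cfg.alpha_amplitude_uv * occ_weight[:, None] * (env * carrier)[None, :]


def _spectrotemporal_bursts(
    rng: np.random.Generator, cfg: SimConfig, n_samp: int, group: int
) -> tuple[np.ndarray, np.ndarray]:
    """Beta-band chirp bursts, one cross-channel event per 2-s segment
    in *both* groups; the group difference is the chirp *direction*.

    Every event sweeps 8 -> 32 Hz over ~0.6 s — upward
    (low-to-high frequency) in cases, downward in controls. A downward
    chirp is the time reversal of an upward one, so its power spectrum —
    and hence every Welch band-power feature, including cross-channel
    covariance structure — is identical by symmetry: only the
    orientation of the blob in the time-frequency plane distinguishes
    the groups, which is exactly the local spectro-temporal pattern a
    2-D convolution kernel can resolve and a time-averaged band-power
    feature cannot.

    Events are coherent across channels (shared latency and phase per
    segment) with an alternating +1/-1 spatial pattern, zero-sum across
    channels so common-average referencing is exactly neutral. With an
    odd channel count the last channel stays burst-free.

    Returns the burst signal and the vector of burst center times.
    """
    n_eeg = cfg.n_eeg_channels
    sr = cfg.sample_rate
    x = np.zeros((n_eeg, n_samp))
    n_paired = 2 * (n_eeg // 2)
    signs = np.where(np.arange(n_eeg) % 2 == 0, 1.0, -1.0)
    amp = 3.0 * cfg.noise_std_uv * cfg.effect_size
    direction = 1.0 if group == 1 else -1.0
    n_segments = int(np.floor(n_samp / sr / _BURST_PERIOD_S))
    half = 3.0 * _BURST_SIGMA_S
    lat_lo, lat_hi = half + 0.05, _BURST_PERIOD_S - half - 0.05
    sweep_rate = direction * _CHIRP_SPAN_HZ / (2 * half)  # Hz per second
    times = np.empty(n_segments)
    for k in range(n_segments):
        lat = rng.uniform(lat_lo, lat_hi)
        phase = rng.uniform(0, 2 * np.pi)
        c = k * _BURST_PERIOD_S + lat
        times[k] = c
        i0 = max(0, int((c - half) * sr))
        i1 = min(n_samp, int((c + half) * sr) + 1)
        t = np.arange(i0, i1) / sr - c
        envelope = np.exp(-0.5 * (t / _BURST_SIGMA_S) ** 2)
        # instantaneous frequency: center + sweep_rate * t
        wave = envelope * np.cos(
            2 * np.pi * (_BURST_FREQ_HZ * t + 0.5 * sweep_rate * t**2) + phase
        )
        x[:n_paired, i0:i1] += amp * signs[:n_paired, None] * wave[None, :]
    return x, times


def burst_chirp_statistic(rec: RawRecording) -> float:
    """Measured chirp-direction statistic: mean lag (s) between the
    energy-weighted arrival times of the upper and lower beta sub-bands
    around each burst. Positive for upward chirps (cases), negative for
    downward (controls)."""
    times = np.asarray(rec.annotations.get("burst_times_s", []), dtype=float)
    if times.size == 0:
        raise SimulationError(f"recording {rec.subject_id} carries no bursts")
    sr = rec.sample_rate
    ch = 0  # carries the burst with spatial weight +1
    span = _CHIRP_SPAN_HZ / 2
    lo_env = _band_envelope(rec.eeg[ch], sr, _BURST_FREQ_HZ - span, _BURST_FREQ_HZ - 1)
    hi_env = _band_envelope(rec.eeg[ch], sr, _BURST_FREQ_HZ + 1, _BURST_FREQ_HZ + span)
    half = 3.0 * _BURST_SIGMA_S
    lags = []
    t_axis = np.arange(rec.n_samples) / sr
    for c in times:
        i0, i1 = int((c - half) * sr), int((c + half) * sr)
        if i0 < 0 or i1 > rec.n_samples:
            continue
        seg_t = t_axis[i0:i1]
        lo = lo_env[i0:i1] ** 2
        hi = hi_env[i0:i1] ** 2
        if lo.sum() == 0 or hi.sum() == 0:
            continue
        lags.append(np.average(seg_t, weights=hi) - np.average(seg_t, weights=lo))
    return float(np.mean(lags))


def _band_envelope(x: np.ndarray, sr: float, lo: float, hi: float) -> np.ndarray:
    """Amplitude envelope of the [lo, hi) Hz component (analytic signal
    via one-sided FFT masking)."""
    freqs = np.fft.rfftfreq(x.size, d=1.0 / sr)
    spec = np.fft.rfft(x)
    spec[(freqs < lo) | (freqs >= hi)] = 0.0
    full = np.zeros(x.size, dtype=complex)
    full[: spec.size] = 2 * spec
    analytic = np.fft.ifft(full)
    return np.abs(analytic)


# ---------------------------------------------------------------------------
# subject-level generation


def _channel_names(cfg: SimConfig) -> list[str]:
    eeg = [f"EEG{i + 1:03d}" for i in range(cfg.n_eeg_channels)]
    eog = [f"EOG{i + 1:03d}" for i in range(cfg.n_eog_channels)]
    return eeg + eog


def _simulate_subject(
    cfg: SimConfig, subject_id: str, group: int, rng: np.random.Generator
) -> RawRecording:
    n_samp = int(round(cfg.duration * cfg.sample_rate))
    beta = cfg.one_over_f_exponent
    eeg = _one_over_f_noise(
        rng, cfg.n_eeg_channels, n_samp, cfg.sample_rate, beta, cfg.noise_std_uv
    )
    eog = _one_over_f_noise(
        rng, cfg.n_eog_channels, n_samp, cfg.sample_rate, beta, cfg.noise_std_uv
    )
    if cfg.alpha_amplitude_uv > 0:
        eeg += _alpha_oscillation(rng, cfg, n_samp)
    annotations: dict = {"effect_kind": cfg.effect_kind}
    if cfg.effect_kind == "band_power" and group == 1 and cfg.effect_size > 0:
        targets = band_power_target_channels(cfg.n_eeg_channels)
        lo, hi = CANONICAL_BANDS["theta"]
        for ch in targets:
            base = eeg[ch].var() * _theta_fraction(cfg)
            extra = _band_limited_noise(rng, n_samp, cfg.sample_rate, lo, hi)
            eeg[ch] += np.sqrt(cfg.effect_size * base) * extra
        annotations["band_power_targets"] = targets.tolist()
    elif cfg.effect_kind == "spectrotemporal":
        bursts, times = _spectrotemporal_bursts(rng, cfg, n_samp, group)
        eeg += bursts
        annotations["burst_times_s"] = times
    return RawRecording(
        subject_id=subject_id,
        group=group,
        sample_rate=cfg.sample_rate,
        eeg=eeg,
        eog=eog,
        channel_names=_channel_names(cfg),
        annotations=annotations,
    )


def _theta_fraction(cfg: SimConfig) -> float:
    """Fraction of 1/f^beta background variance lying in the theta band
    (analytic, up to Nyquist), used to size the injected theta power."""
    f = np.linspace(1.0 / cfg.duration, cfg.sample_rate / 2, 4096)
    psd = f ** (-cfg.one_over_f_exponent)
    lo, hi = CANONICAL_BANDS["theta"]
    mask = (f >= lo) & (f < hi)
    return float(np.trapezoid(psd[mask], f[mask]) / np.trapezoid(psd, f))


# ---------------------------------------------------------------------------
# artifact injection


def inject_blinks(rec: RawRecording, rate: float, seed: int) -> RawRecording:
    """Add randomly timed blink transients (300-500 ms half-period
    raised-cosine pulses) with frontal-dominant EEG topography and
    amplified copies on the EOG channels. ``rate`` is events per minute;
    rate 0 returns the input unchanged."""
    if rate < 0:
        raise SimulationError("blink rate must be >= 0")
    if rate == 0:
        return rec
    rng = np.random.default_rng(seed)
    out = rec.copy()
    sr = rec.sample_rate
    n_samp = rec.n_samples
    n_eeg = rec.eeg.shape[0]
    idx = np.arange(n_eeg)
    frontal = np.exp(-idx / max(n_eeg / 6.0, 1.0))
    eog_gain = np.array([2.5, 1.2][: rec.eog.shape[0]] or [2.5])
    if eog_gain.size < rec.eog.shape[0]:
        eog_gain = np.resize(eog_gain, rec.eog.shape[0])
    n_events = rng.poisson(rate * rec.duration / 60.0)
    times: list[float] = []
    for _ in range(n_events):
        dur = rng.uniform(0.3, 0.5)
        onset = rng.uniform(0.0, max(rec.duration - dur, 0.0))
        amp = rng.uniform(80.0, 120.0)
        i0 = int(onset * sr)
        i1 = min(n_samp, i0 + int(dur * sr))
        u = np.arange(i1 - i0) / (dur * sr)
        pulse = amp * np.sin(np.pi * np.clip(u, 0, 1)) ** 2
        out.eeg[:, i0:i1] += frontal[:, None] * pulse[None, :]
        out.eog[:, i0:i1] += eog_gain[:, None] * pulse[None, :]
        times.append(onset + dur / 2.0)
    out.annotations["blink_times_s"] = sorted(times)
    return out


def inject_noise_bursts(
    rec: RawRecording, prob: float, amplitude: float, seed: int
) -> RawRecording:
    """With probability ``prob`` per non-overlapping 4-s span, add a
    high-amplitude 10 Hz burst (0.5 s, Hann envelope, centered in the
    span) on one random EEG channel, guaranteed to exceed ``amplitude``
    peak-to-peak. Burst supports are recorded as ground truth."""
    if not 0.0 <= prob <= 1.0:
        raise SimulationError("noise burst prob must be in [0, 1]")
    if amplitude <= 0:
        raise SimulationError("noise burst amplitude must be > 0")
    rng = np.random.default_rng(seed)
    if prob == 0:
        return rec
    out = rec.copy()
    sr = rec.sample_rate
    n_spans = int(np.floor(rec.duration / 4.0))
    spans: list[tuple[float, float]] = []
    burst_dur = 0.5
    for k in range(n_spans):
        if rng.uniform() >= prob:
            continue
        ch = int(rng.integers(0, out.eeg.shape[0]))
        center = 4.0 * k + 2.0
        i0 = int((center - burst_dur / 2) * sr)
        i1 = min(out.n_samples, i0 + int(burst_dur * sr))
        t = np.arange(i1 - i0) / sr
        envelope = np.sin(np.pi * t / burst_dur) ** 2
        peak = 0.75 * amplitude
        out.eeg[ch, i0:i1] += peak * envelope * np.cos(2 * np.pi * 10.0 * t)
        spans.append((i0 / sr, i1 / sr))
    out.annotations["noise_spans_s"] = spans
    return out


# ---------------------------------------------------------------------------
# band-power matching (spectrotemporal effect)


def _welch_band_powers(rec: RawRecording, bands=CANONICAL_BANDS) -> np.ndarray:
    """(n_eeg, n_bands) mean Welch power per canonical band."""
    nperseg = int(2 * rec.sample_rate)
    freqs, psd = signal.welch(rec.eeg, fs=rec.sample_rate, nperseg=nperseg, axis=1)
    out = np.empty((rec.eeg.shape[0], len(bands)))
    for j, (lo, hi) in enumerate(bands.values()):
        mask = (freqs >= lo) & (freqs < hi)
        out[:, j] = psd[:, mask].mean(axis=1)
    return out


def _scale_bands(rec: RawRecording, gains: np.ndarray) -> RawRecording:
    """Apply per-(channel, band) amplitude gains in the FFT domain."""
    r = rec.copy()
    spec = np.fft.rfft(r.eeg, axis=1)
    freqs = np.fft.rfftfreq(r.n_samples, d=1.0 / r.sample_rate)
    for j, (lo, hi) in enumerate(CANONICAL_BANDS.values()):
        mask = (freqs >= lo) & (freqs < hi)
        spec[:, mask] *= gains[:, j][:, None]
    r.eeg = np.fft.irfft(spec, n=r.n_samples, axis=1)
    return r


def _match_band_power(recs: list[RawRecording], max_iter: int = 6) -> list[RawRecording]:
    """Rescale the case group per channel and band until both groups'
    Welch mean band power agrees to within the 2% tolerance.

    Sharp band-edge FFT scaling and windowed-segment (Welch)
    re-measurement disagree through spectral leakage when gains are far
    from 1, so the Welch-measured residual is driven down iteratively.
    """
    controls = [r for r in recs if r.group == 0]
    cases = [r for r in recs if r.group == 1]
    p0 = np.mean([_welch_band_powers(r) for r in controls], axis=0)
    ratio = None
    for _ in range(max_iter):
        p1 = np.mean([_welch_band_powers(r) for r in cases], axis=0)
        ratio = p1 / p0
        if np.abs(ratio - 1.0).max() <= 0.5 * _BAND_MATCH_TOL:
            break
        gains = np.sqrt(1.0 / ratio)
        cases = [_scale_bands(r, gains) for r in cases]
    # postcondition: per-channel per-band group mean-power ratio within 2%
    p1 = np.mean([_welch_band_powers(r) for r in cases], axis=0)
    ratio = p1 / p0
    if np.any(np.abs(ratio - 1.0) > _BAND_MATCH_TOL):
        worst = float(np.abs(ratio - 1.0).max())
        raise SimulationError(
            f"band-power matching violated: worst deviation {worst:.4f} > "
            f"{_BAND_MATCH_TOL}"
        )
    by_id = {r.subject_id: r for r in controls + cases}
    return [by_id[r.subject_id] for r in recs]


# ---------------------------------------------------------------------------
# covariates


def _clip_round(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip(np.round(x), lo, hi)


def generate_covariates(
    cfg: SimConfig,
    subject_ids: list[str],
    groups: list[int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-subject covariate table with group-dependent distributions.

    ``cfg.covariate_separation`` scales each continuous covariate's
    between-group mean difference about the two-group midpoint (1.0
    reproduces the default descriptive statistics; 0 removes the group
    difference). Missingness defaults: age absent for ``n_missing_age``
    subjects, the magical-ideation score for ``n_missing_mis``.
    """
    n = len(subject_ids)
    groups_arr = np.asarray(groups)
    cols: dict[str, np.ndarray] = {}
    s = cfg.covariate_separation
    for name, per_group in COVARIATE_DISTRIBUTIONS.items():
        (m1, sd1), (m0, sd0) = per_group[1], per_group[0]
        mid = 0.5 * (m1 + m0)
        means = np.where(groups_arr == 1, mid + s * (m1 - mid), mid + s * (m0 - mid))
        sds = np.where(groups_arr == 1, sd1, sd0)
        draws = rng.normal(means, sds)
        if name == "age":
            cols[name] = np.clip(draws, *AGE_RANGE)
        else:
            cols[name] = _clip_round(draws, *SCORE_RANGES[name])
    sex = np.where(
        rng.uniform(size=n) < np.where(groups_arr == 1, SEX_P_MALE[1], SEX_P_MALE[0]),
        "M",
        "F",
    )
    edu = np.empty(n, dtype=object)
    for g in (0, 1):
        mask = groups_arr == g
        edu[mask] = rng.choice(EDUCATION_LEVELS, size=mask.sum(), p=EDUCATION_P[g])
    df = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": groups_arr,
            "docs_total": cols["docs_total"],
            "mis_score": cols["mis_score"],
            "bai_total": cols["bai_total"],
            "bdi_total": cols["bdi_total"],
            "age": cols["age"],
            "sex": sex,
            "education": edu,
        }
    )
    if 0 < cfg.n_missing_age <= n:
        df.loc[rng.choice(n, cfg.n_missing_age, replace=False), "age"] = np.nan
    if 0 < cfg.n_missing_mis <= n:
        df.loc[rng.choice(n, cfg.n_missing_mis, replace=False), "mis_score"] = np.nan
    return df


def validate_covariates(df: pd.DataFrame) -> None:
    """Invariant checks for a covariate table."""
    if df["subject_id"].duplicated().any():
        raise SimulationError("duplicate subject_ids in covariate table")
    for name, (lo, hi) in SCORE_RANGES.items():
        vals = df[name].dropna()
        if ((vals < lo) | (vals > hi)).any():
            raise SimulationError(f"{name} outside its instrument range [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(cfg: SimConfig) -> tuple[list[RawRecording], pd.DataFrame]:
    """Generate a balanced two-group cohort plus its covariate table.

    Returns ``2 * cfg.n_per_group`` recordings (groups interleaved by
    subject index) and one covariate row per subject. Fully reproducible
    from ``cfg.seed``.
    """
    n_total = 2 * cfg.n_per_group
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(n_total + 1)
    recs: list[RawRecording] = []
    artifact_seeds: list[tuple[int, int]] = []
    subject_ids, groups = [], []
    for i in range(n_total):
        rng = np.random.default_rng(children[i])
        subject_id = f"sub-{i + 1:02d}"
        group = i % 2
        recs.append(_simulate_subject(cfg, subject_id, group, rng))
        artifact_seeds.append(
            (int(rng.integers(2**31)), int(rng.integers(2**31)))
        )
        subject_ids.append(subject_id)
        groups.append(group)
    # band-power matching acts on the stationary neural signal, before
    # artifact injection: blinks and noise bursts are group-balanced
    # nuisance processes whose Poisson sampling noise would otherwise
    # dominate the per-band group means
    if cfg.effect_kind == "spectrotemporal":
        recs = _match_band_power(recs)
    recs = [
        inject_noise_bursts(
            inject_blinks(rec, cfg.blink_rate, seed=s_blink),
            cfg.noise_burst_prob,
            cfg.noise_burst_amplitude,
            seed=s_burst,
        )
        for rec, (s_blink, s_burst) in zip(recs, artifact_seeds)
    ]
    for rec in recs:  # simulation-bug guard
        if not (np.isfinite(rec.eeg).all() and np.isfinite(rec.eog).all()):
            raise SimulationError(f"non-finite output for {rec.subject_id}")
    cov_rng = np.random.default_rng(children[-1])
    covariates = generate_covariates(cfg, subject_ids, groups, cov_rng)
    validate_covariates(covariates)
    return recs, covariates
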