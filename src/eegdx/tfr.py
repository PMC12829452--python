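"""Morlet time-frequency log-power tensors for the CNN.

Each clean epoch becomes a (frequencies x time points x channels)
log-power image: complex Morlet transform per channel at logarithmically
spaced frequencies with frequency-proportional cycle counts, temporal
decimation by plain subsampling, then 10*log10(power + 1e-10). No
baseline correction is applied.

Caveat: with n_cycles = f / 2 the lowest frequencies use wavelets shorter
than one cycle, so low-frequency resolution is poor and the cone of
influence at epoch edges is wide; values there are kept as computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from mne.time_frequency import tfr_array_morlet

from .preprocess import EpochSet

__all__ = [
    "TFRConfig",
    "TFRTensor",
    "TFRError",
    "log_spaced_freqs",
    "morlet_power",
    "log_power",
    "to_channels_last",
    "epochs_to_tensor",
    "save_tensor",
    "load_tensor",
]


class TFRError(ValueError):
    pass


@dataclass(frozen=True)
class TFRConfig:
    """Time-frequency transform parameters."""

    f_min: float = 1.0
    f_max: float = 45.0
    n_freqs: int = 40
    cycles_divisor: float = 2.0  # n_cycles = freq / cycles_divisor
    decim: int = 16
    log_floor: float = 1e-10
    log_scale: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.f_min < self.f_max:
            raise TFRError("need 0 < f_min < f_max")
        if self.n_freqs < 2:
            raise TFRError("n_freqs must be >= 2")
        if self.decim < 1:
            raise TFRError("decim must be >= 1")
        if self.log_floor <= 0:
            raise TFRError("log_floor must be > 0")


@dataclass
class TFRTensor:
    """Per-epoch time-frequency array for one subject.

    ``layout`` is either ``"channels_first"`` (epochs, channels, freqs,
    times — the transform's native order) or ``"channels_last"`` (epochs,
    freqs, times, channels — the CNN input order). ``is_log`` records
    whether ``data`` holds raw power or 10*log10 power.
    """

    subject_id: str
    group: int
    data: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    layout: str = "channels_first"
    is_log: bool = False

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise TFRError("TFR data must be 4-D")
        if self.layout not in ("channels_first", "channels_last"):
            raise TFRError(f"unknown layout {self.layout!r}")
        if np.any(np.diff(self.freqs) <= 0):
            raise TFRError("freqs must be strictly ascending")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


def log_spaced_freqs(cfg: TFRConfig) -> np.ndarray:
    """Geometrically spaced analysis frequencies from f_min to f_max."""
    return np.geomspace(cfg.f_min, cfg.f_max, cfg.n_freqs)


def morlet_power(eps: EpochSet, cfg: TFRConfig) -> TFRTensor:
    """Squared-magnitude Morlet transform of every epoch and channel,
    decimated in time by keeping every ``cfg.decim``-th sample.

    Output layout is channels_first, pre-log power (all values >= 0).
    """
    sr = eps.sample_rate
    if cfg.f_max >= sr / 2:
        raise TFRError(f"f_max {cfg.f_max} Hz >= Nyquist ({sr / 2} Hz)")
    n_samples = eps.epochs.shape[2]
    if n_samples % cfg.decim != 0:
        raise TFRError(
            f"epoch length {n_samples} not divisible by decim {cfg.decim}"
        )
    freqs = log_spaced_freqs(cfg)
    n_cycles = freqs / cfg.cycles_divisor
    power = tfr_array_morlet(
        eps.epochs,
        sfreq=sr,
        freqs=freqs,
        n_cycles=n_cycles,
        output="power",
        decim=cfg.decim,
        zero_mean=False,
        verbose="ERROR",
    )
    times = np.arange(n_samples)[:: cfg.decim] / sr
    return TFRTensor(
        subject_id=eps.subject_id,
        group=eps.group,
        data=power,
        freqs=freqs,
        times=times,
        layout="channels_first",
        is_log=False,
    )


def log_power(tfr: TFRTensor, cfg: TFRConfig = TFRConfig()) -> TFRTensor:
    """Elementwise ``log_scale * log10(power + log_floor)`` (defaults:
    10*log10(p + 1e-10), a dB-like scale in arbitrary units)."""
    if tfr.is_log:
        raise TFRError("tensor is already log-transformed")
    if np.any(tfr.data < 0):
        raise TFRError("negative power values")
    data = cfg.log_scale * np.log10(tfr.data + cfg.log_floor)
    return TFRTensor(
        subject_id=tfr.subject_id,
        group=tfr.group,
        data=data,
        freqs=tfr.freqs,
        times=tfr.times,
        layout=tfr.layout,
        is_log=True,
    )


def to_channels_last(tfr: TFRTensor) -> TFRTensor:
    """Permute (epochs, channels, freqs, times) -> (epochs, freqs, times,
    channels); a pure transpose, values untouched."""
    if tfr.layout != "channels_first":
        raise TFRError("input must be channels_first")
    if tfr.data.shape[2] != tfr.freqs.size or tfr.data.shape[3] != tfr.times.size:
        raise TFRError("axis sizes do not match freqs/times vectors")
    return TFRTensor(
        subject_id=tfr.subject_id,
        group=tfr.group,
        data=np.transpose(tfr.data, (0, 2, 3, 1)),
        freqs=tfr.freqs,
        times=tfr.times,
        layout="channels_last",
        is_log=tfr.is_log,
    )


def epochs_to_tensor(eps: EpochSet, cfg: TFRConfig) -> TFRTensor:
    """Full default path: Morlet power -> log transform -> channels-last."""
    return to_channels_last(log_power(morlet_power(eps, cfg), cfg))


def save_tensor(tfr: TFRTensor, out_dir) -> None:
    """Persist a TFRTensor as ``tfr.npy`` plus a JSON sidecar with the
    frequency/time axes and layout metadata."""
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    np.save(out_dir / "tfr.npy", tfr.data)
    meta = {
        "subject_id": tfr.subject_id,
        "group": tfr.group,
        "freqs": tfr.freqs.tolist(),
        "times": tfr.times.tolist(),
        "layout": tfr.layout,
        "is_log": tfr.is_log,
    }
    (out_dir / "tfr.json").write_text(json.dumps(meta))


def load_tensor(out_dir) -> TFRTensor:
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    meta = json.loads((out_dir / "tfr.json").read_text())
    return TFRTensor(
        subject_id=meta["subject_id"],
        group=meta["group"],
        data=np.load(out_dir / "tfr.npy"),
        freqs=np.array(meta["freqs"]),
        times=np.array(meta["times"]),
        layout=meta["layout"],
        is_log=meta["is_log"],
    )
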