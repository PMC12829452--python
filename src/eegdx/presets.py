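"""Canonical analysis presets.

``full_scale_protocol`` mirrors the complete study conditions (68 EEG +
2 EOG channels, 1024 Hz, 240 s, 40 wavelet frequencies, 50 training
passes). ``scaled_protocol`` is the desk-scale counterpart used by the
test suite and the worked examples: 8 EEG + 2 EOG channels, 256 Hz,
60 s recordings, 16 wavelet frequencies and at most 30 training passes
with internal-validation early stopping — small enough for a laptop CPU
while preserving every pipeline stage and contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

from .bandpower import BandPowerSpec
from .cnn import CNNSpec
from .preprocess import PreprocConfig
from .simulate import SimConfig
from .tfr import TFRConfig

__all__ = ["Protocol", "full_scale_protocol", "scaled_protocol"]


@dataclass(frozen=True)
class Protocol:
    preproc: PreprocConfig
    tfr: TFRConfig
    cnn: CNNSpec
    bandpower: BandPowerSpec

    def sim_config(self, n_per_group: int, seed: int, **kw) -> SimConfig:
        raise NotImplementedError


@dataclass(frozen=True)
class _FullProtocol(Protocol):
    def sim_config(self, n_per_group: int, seed: int, **kw) -> SimConfig:
        return SimConfig(n_per_group=n_per_group, seed=seed, **kw)


@dataclass(frozen=True)
class _ScaledProtocol(Protocol):
    def sim_config(self, n_per_group: int, seed: int, **kw) -> SimConfig:
        return SimConfig.test_scale(n_per_group, seed=seed, **kw)


def full_scale_protocol() -> Protocol:
    return _FullProtocol(
        preproc=PreprocConfig(),
        tfr=TFRConfig(),
        cnn=CNNSpec(),
        bandpower=BandPowerSpec(),
    )


def scaled_protocol() -> Protocol:
    return _ScaledProtocol(
        preproc=PreprocConfig(crop_seconds=60.0, n_ica_components=6),
        tfr=TFRConfig(n_freqs=16),
        cnn=CNNSpec(max_train_epochs=30, patience=10),
        bandpower=BandPowerSpec(),
    )
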