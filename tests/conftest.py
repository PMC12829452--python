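"""Shared fixtures.

The scaled cohorts and their LOSO evaluations are expensive (minutes),
so they are session-scoped and computed lazily: the synthetic study
conditions are fixed here once (seeds included) and shared by every test
that needs them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import eegdx
from eegdx.loso import run_loso
from eegdx.pipeline import bandpower_dataset, preprocess_cohort, tensor_dataset
from eegdx.presets import scaled_protocol

warnings.filterwarnings("ignore", category=RuntimeWarning)

# fixed study conditions for the scaled synthetic cohorts
COHORT_SEED = 11
RUN_SEED = 5
N_PER_GROUP = 10


@pytest.fixture(scope="session")
def protocol():
    return scaled_protocol()


def _cohort_datasets(protocol, effect_kind):
    cfg = protocol.sim_config(
        N_PER_GROUP, seed=COHORT_SEED, effect_kind=effect_kind, effect_size=1.0
    )
    recs, cov = eegdx.generate_cohort(cfg)
    eps = preprocess_cohort(recs, protocol.preproc)
    return {
        "recordings": recs,
        "covariates": cov,
        "epochs": eps,
        "tensors": tensor_dataset(eps, protocol.tfr),
        "bandpower": bandpower_dataset(eps, protocol.bandpower),
    }


@pytest.fixture(scope="session")
def spectro_cohort(protocol):
    return _cohort_datasets(protocol, "spectrotemporal")


@pytest.fixture(scope="session")
def bandpower_cohort(protocol):
    return _cohort_datasets(protocol, "band_power")


@pytest.fixture(scope="session")
def spectro_loso(protocol, spectro_cohort):
    return {
        "cnn": run_loso(spectro_cohort["tensors"], "cnn", protocol.cnn, seed=RUN_SEED),
        "svm": run_loso(spectro_cohort["bandpower"], "svm", protocol.bandpower, seed=RUN_SEED),
    }


@pytest.fixture(scope="session")
def bandpower_loso(protocol, bandpower_cohort):
    return {
        "cnn": run_loso(bandpower_cohort["tensors"], "cnn", protocol.cnn, seed=RUN_SEED),
        "svm": run_loso(bandpower_cohort["bandpower"], "svm", protocol.bandpower, seed=RUN_SEED),
    }


@pytest.fixture()
def tiny_recording():
    """One cheap artifact-free recording (8 EEG + 2 EOG, 256 Hz, 20 s)."""
    cfg = eegdx.SimConfig.test_scale(
        1, seed=3, duration=20.0, blink_rate=0.0, noise_burst_prob=0.0
    )
    recs, _ = eegdx.generate_cohort(cfg)
    return recs[0]


def make_recording(eeg, sample_rate=256.0, n_eog=1, subject_id="sub-x", group=0):
    """Helper to wrap a raw EEG array (n_ch, n_samp) into a RawRecording."""
    eeg = np.asarray(eeg, dtype=float)
    n_samp = eeg.shape[1]
    return eegdx.RawRecording(
        subject_id=subject_id,
        group=group,
        sample_rate=sample_rate,
        eeg=eeg,
        eog=np.zeros((n_eog, n_samp)),
        channel_names=[f"EEG{i:03d}" for i in range(eeg.shape[0])]
        + [f"EOG{i:03d}" for i in range(n_eog)],
    )
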