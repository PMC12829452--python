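"""End-to-end conveniences: cohort -> clean epochs -> classifier inputs.

These helpers chain the per-subject preprocessing, the time-frequency
transform and the band-power features so that a LOSO comparison of the
two classifiers is a few lines; see examples/ for narrative usage.
"""

from __future__ import annotations

from .bandpower import BandPowerSpec, band_power_features
from .loso import SubjectData
from .preprocess import EpochSet, PreprocConfig, preprocess_subject
from .simulate import RawRecording
from .tfr import TFRConfig, epochs_to_tensor

__all__ = [
    "preprocess_cohort",
    "tensor_dataset",
    "bandpower_dataset",
]


def preprocess_cohort(
    recs: list[RawRecording], cfg: PreprocConfig, run_ica: bool = True
) -> list[EpochSet]:
    """Clean and epoch every recording (fixed pipeline order per subject)."""
    return [preprocess_subject(r, cfg, run_ica=run_ica)[0] for r in recs]


def tensor_dataset(epoch_sets: list[EpochSet], cfg: TFRConfig) -> list[SubjectData]:
    """Channels-last log-power TFR tensors per subject, for the CNN."""
    out = []
    for eps in epoch_sets:
        t = epochs_to_tensor(eps, cfg)
        out.append(SubjectData(subject_id=eps.subject_id, group=eps.group, x=t.data))
    return out


def bandpower_dataset(
    epoch_sets: list[EpochSet], spec: BandPowerSpec = BandPowerSpec()
) -> list[SubjectData]:
    """Welch band-power feature matrices per subject, for the SVM."""
    return [
        SubjectData(
            subject_id=eps.subject_id,
            group=eps.group,
            x=band_power_features(eps, spec),
        )
        for eps in epoch_sets
    ]
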