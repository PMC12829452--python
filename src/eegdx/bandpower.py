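"""Band-power features and the RBF-SVM epoch classifier baseline.

Features: per epoch and EEG channel, mean Welch spectral power within the
five canonical bands (delta 1-4, theta 4-8, alpha 8-13, beta 13-30,
gamma 30-45 Hz). Feature order is channel-major, band-minor and fixed:
column ``ch * 5 + b`` is band ``b`` of channel ``ch``.

Classifier: support vector machine with radial-basis kernel, C = 1,
gamma = 'scale', inverse-frequency class weights and Platt-scaled
probability outputs, trained on standardized features (standardization
happens upstream, per cross-validation fold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.svm import SVC

from .preprocess import EpochSet
from .simulate import CANONICAL_BANDS

__all__ = ["BandPowerSpec", "band_power_features", "fit_svm", "predict_svm_probabilities"]


@dataclass(frozen=True)
class BandPowerSpec:
    bands: tuple[tuple[str, float, float], ...] = tuple(
        (name, lo, hi) for name, (lo, hi) in CANONICAL_BANDS.items()
    )
    welch_segment: float = 2.0  # seconds, Hann window
    welch_overlap: float = 0.5  # fraction of segment
    svm_c: float = 1.0
    svm_gamma: str = "scale"

    def __post_init__(self) -> None:
        edges = [(lo, hi) for _, lo, hi in self.bands]
        for (lo, hi), (lo2, _) in zip(edges, edges[1:]):
            if hi > lo2:
                raise ValueError("bands must be ascending and non-overlapping")
        if not 0 <= self.welch_overlap < 1:
            raise ValueError("welch_overlap must be in [0, 1)")


def band_power_features(eps: EpochSet, spec: BandPowerSpec = BandPowerSpec()) -> np.ndarray:
    """(n_epochs, n_channels * n_bands) mean band-power feature matrix."""
    sr = eps.sample_rate
    n_samples = eps.epochs.shape[2]
    nperseg = int(round(spec.welch_segment * sr))
    if nperseg > n_samples:
        raise ValueError(
            f"welch_segment ({spec.welch_segment} s) longer than the epoch "
            f"({n_samples / sr} s)"
        )
    freqs, psd = signal.welch(
        eps.epochs,
        fs=sr,
        window="hann",
        nperseg=nperseg,
        noverlap=int(round(spec.welch_overlap * nperseg)),
        axis=2,
    )  # psd: (n_epochs, n_channels, n_freqs)
    n_epochs, n_ch = psd.shape[:2]
    n_bands = len(spec.bands)
    out = np.empty((n_epochs, n_ch * n_bands))
    for b, (_, lo, hi) in enumerate(spec.bands):
        mask = (freqs >= lo) & (freqs < hi)
        if not mask.any():
            raise ValueError(f"no Welch bins fall in band [{lo}, {hi}) Hz")
        out[:, b::n_bands] = psd[:, :, mask].mean(axis=2)
    return out


def fit_svm(
    features: np.ndarray, labels: np.ndarray, spec: BandPowerSpec = BandPowerSpec(), seed: int = 0
) -> SVC:
    """RBF-SVM with balanced class weights and probability outputs.
    ``features`` are expected standardized (fold-wise, upstream)."""
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("SVM training requires both classes present")
    clf = SVC(
        C=spec.svm_c,
        kernel="rbf",
        gamma=spec.svm_gamma,
        class_weight="balanced",
        probability=True,
        random_state=seed,
    )
    clf.fit(np.asarray(features), y)
    return clf


def predict_svm_probabilities(model: SVC, features: np.ndarray) -> np.ndarray:
    """Per-epoch class-1 probabilities in [0, 1]."""
    idx = int(np.where(model.classes_ == 1)[0][0])
    return model.predict_proba(np.asarray(features))[:, idx]
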