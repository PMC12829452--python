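"""Leave-one-subject-out orchestration.

Every subject serves as the held-out test set exactly once; all of their
epochs are scored by a classifier trained on the remaining subjects'
epochs. Feature standardization is fitted per fold on training epochs
only. A subject's epoch probabilities are averaged into one score and
thresholded (strictly greater than 0.5 -> case); per-fold records keep
the epoch-level probabilities so every downstream report — including the
late-fusion stage — is recomputable without retraining.

Per-fold seeds derive deterministically from the run seed (seed +
fold_id), so results do not depend on fold execution order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from sklearn.preprocessing import StandardScaler

from .bandpower import BandPowerSpec, fit_svm, predict_svm_probabilities
from .cnn import CNNModel, CNNSpec, build_cnn

__all__ = [
    "FoldPlan",
    "SubjectScore",
    "SubjectData",
    "EpochProbabilities",
    "LOSOResult",
    "LOSOError",
    "make_loso_folds",
    "fit_fold_scaler",
    "apply_scaler",
    "aggregate_subject",
    "run_loso",
    "CNNEpochClassifier",
    "SVMEpochClassifier",
]


class LOSOError(ValueError):
    pass


@dataclass(frozen=True)
class FoldPlan:
    fold_id: int
    train_subject_ids: tuple[str, ...]
    test_subject_id: str


@dataclass(frozen=True)
class SubjectScore:
    """LOSO-aggregated subject-level result: mean epoch probability,
    thresholded strictly above 0.5 (a tied 0.5 goes to the control
    class)."""

    subject_id: str
    score: float
    predicted: int
    truth: int


@dataclass
class SubjectData:
    """One subject's epoch-level feature array (epochs along axis 0)."""

    subject_id: str
    group: int
    x: np.ndarray


@dataclass
class EpochProbabilities:
    subject_id: str
    probs: np.ndarray
    model: str
    fold_id: int

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.size and (p.min() < 0 or p.max() > 1):
            raise LOSOError("epoch probabilities must lie in [0, 1]")
        self.probs = p


@dataclass
class LOSOResult:
    model: str
    subject_scores: list[SubjectScore]
    fold_records: list[dict]
    manifest: dict

    @property
    def scores(self) -> np.ndarray:
        return np.array([s.score for s in self.subject_scores])

    @property
    def truths(self) -> np.ndarray:
        return np.array([s.truth for s in self.subject_scores])

    @property
    def predictions(self) -> np.ndarray:
        return np.array([s.predicted for s in self.subject_scores])

    def fold_epoch_accuracy(self) -> tuple[float, float]:
        """Mean and SD across folds of epoch-level accuracy."""
        acc = np.array([r["epoch_accuracy"] for r in self.fold_records])
        return float(acc.mean()), float(acc.std())

    def pooled_epochs(self) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated held-out epoch probabilities and truths."""
        probs = np.concatenate([r["epoch_probs"] for r in self.fold_records])
        truth = np.concatenate(
            [np.full(len(r["epoch_probs"]), r["truth"]) for r in self.fold_records]
        )
        return probs, truth


def make_loso_folds(subject_ids) -> list[FoldPlan]:
    """One fold per subject, ordered by subject id; the test subject is
    excluded from its own training set."""
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise LOSOError("duplicate subject ids")
    if len(ids) < 2:
        raise LOSOError("leave-one-subject-out needs >= 2 subjects")
    ordered = sorted(ids)
    return [
        FoldPlan(
            fold_id=i,
            train_subject_ids=tuple(s for s in ordered if s != test),
            test_subject_id=test,
        )
        for i, test in enumerate(ordered)
    ]


def fit_fold_scaler(train_features: np.ndarray) -> StandardScaler:
    """Per-feature z-scaler fitted on training epochs only. Zero-variance
    features are centered but not divided (scale 1)."""
    x = np.asarray(train_features)
    return StandardScaler().fit(x.reshape(x.shape[0], -1))


def apply_scaler(scaler: StandardScaler, features: np.ndarray) -> np.ndarray:
    x = np.asarray(features)
    flat = scaler.transform(x.reshape(x.shape[0], -1))
    return flat.reshape(x.shape)


def aggregate_subject(probs: EpochProbabilities, truth: int) -> SubjectScore:
    """Mean epoch probability -> subject score; predicted case iff the
    score is strictly greater than 0.5."""
    if probs.probs.size == 0:
        raise LOSOError(f"subject {probs.subject_id} has no epoch probabilities")
    score = float(np.mean(probs.probs))
    return SubjectScore(
        subject_id=probs.subject_id,
        score=score,
        predicted=int(score > 0.5),
        truth=int(truth),
    )


# ---------------------------------------------------------------------------
# classifier adapters


class CNNEpochClassifier:
    """Adapter: TFR tensors (n_epochs, freqs, times, channels) -> CNN."""

    name = "cnn"

    def __init__(self, spec: CNNSpec = CNNSpec()):
        self.spec = spec
        self.model: CNNModel | None = None

    def fit(self, x, y, subject_ids, seed, monitor=None):
        spec = dataclasses.replace(self.spec, seed=seed)
        self.model = build_cnn(x.shape[1:], spec)
        self.model.fit(x, y, subject_ids=subject_ids, monitor=monitor)
        return self

    def predict_proba(self, x):
        return self.model.predict_proba(x)


class SVMEpochClassifier:
    """Adapter: band-power feature matrices -> RBF SVM."""

    name = "svm"

    def __init__(self, spec: BandPowerSpec = BandPowerSpec()):
        self.spec = spec
        self.model = None

    def fit(self, x, y, subject_ids, seed, monitor=None):
        self.model = fit_svm(x, y, self.spec, seed=seed)
        return self

    def predict_proba(self, x):
        return predict_svm_probabilities(self.model, x)


def _make_classifier(kind, spec):
    if kind == "cnn":
        return CNNEpochClassifier(spec or CNNSpec())
    if kind == "svm":
        return SVMEpochClassifier(spec or BandPowerSpec())
    raise LOSOError(f"unknown classifier kind {kind!r}")


def run_loso(
    dataset: list[SubjectData],
    classifier: str = "cnn",
    spec=None,
    seed: int = 0,
    keep_models: bool = False,
) -> LOSOResult:
    """Full LOSO evaluation of an epoch classifier.

    Per fold: fit the feature scaler on training epochs, train the
    classifier, score every held-out epoch, aggregate to a subject score.
    ``classifier`` is ``"cnn"`` (expects channels-last TFR tensors) or
    ``"svm"`` (expects band-power matrices); ``spec`` the matching
    classifier spec.
    """
    by_id = {d.subject_id: d for d in dataset}
    if len(by_id) != len(dataset):
        raise LOSOError("duplicate subject ids in dataset")
    for d in dataset:
        if d.x.shape[0] < 1:
            raise LOSOError(f"subject {d.subject_id} has no clean epochs")
    folds = make_loso_folds(list(by_id))
    subject_scores: list[SubjectScore] = []
    fold_records: list[dict] = []
    use_monitor = (
        classifier == "cnn"
        and getattr(spec, "early_stop", None) == "paper_faithful_test_monitor"
    )
    for fold in folds:
        fold_seed = seed + fold.fold_id
        train = [by_id[s] for s in fold.train_subject_ids]
        test = by_id[fold.test_subject_id]
        x_train = np.concatenate([d.x for d in train])
        y_train = np.concatenate([np.full(d.x.shape[0], d.group) for d in train])
        subj_train = np.concatenate(
            [np.full(d.x.shape[0], d.subject_id, dtype=object) for d in train]
        )
        scaler = fit_fold_scaler(x_train)
        x_train_s = apply_scaler(scaler, x_train)
        x_test_s = apply_scaler(scaler, test.x)
        clf = _make_classifier(classifier, spec)
        monitor = None
        if use_monitor:
            monitor = (x_test_s, np.full(test.x.shape[0], test.group, dtype=float))
        try:
            clf.fit(x_train_s, y_train, subj_train, fold_seed, monitor=monitor)
            probs = EpochProbabilities(
                subject_id=test.subject_id,
                probs=clf.predict_proba(x_test_s),
                model=classifier,
                fold_id=fold.fold_id,
            )
        except Exception as exc:
            raise LOSOError(
                f"fold {fold.fold_id} (test subject {fold.test_subject_id}) "
                f"failed: {exc}"
            ) from exc
        score = aggregate_subject(probs, truth=test.group)
        subject_scores.append(score)
        epoch_pred = (probs.probs > 0.5).astype(int)
        record = {
            "fold_id": fold.fold_id,
            "test_subject_id": test.subject_id,
            "truth": int(test.group),
            "epoch_probs": probs.probs,
            "epoch_accuracy": float((epoch_pred == test.group).mean()),
            "seed": fold_seed,
            "scaler_mean": scaler.mean_.copy(),
            "scaler_scale": scaler.scale_.copy(),
        }
        if keep_models:
            record["model"] = clf
        fold_records.append(record)
    manifest = {
        "classifier": classifier,
        "seed": seed,
        "n_subjects": len(folds),
        "fold_seeds": [seed + f.fold_id for f in folds],
    }
    return LOSOResult(
        model=classifier,
        subject_scores=subject_scores,
        fold_records=fold_records,
        manifest=manifest,
    )
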