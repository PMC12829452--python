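"""Late-fusion (stacking) of the subject-level EEG score with clinical
and demographic covariates.

A second-stage logistic regression is fitted on two inputs — the EEG
score from the first-stage LOSO evaluation plus one covariate at a time —
and evaluated under the identical leave-one-subject-out protocol:
numeric inputs are z-scored and categorical inputs one-hot encoded with
parameters fitted on the training rows of each fold only. Subjects with
a missing value for the tested covariate are dropped (listwise deletion;
the remaining N is reported). Each augmented model's pooled AUC is
labeled Improved / None / Worse against the EEG-only baseline at
two-decimal reporting precision.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import OneHotEncoder, StandardScaler

from .loso import SubjectScore, make_loso_folds
from .metrics import classification_metrics, confusion, roc_auc

__all__ = [
    "FusionError",
    "FusionResult",
    "FUSION_FEATURES",
    "CATEGORICAL_FEATURES",
    "assemble_fusion_table",
    "run_fusion_loso",
    "compare_to_baseline",
    "run_fusion_analysis",
]

#: covariates testable one at a time, in reporting order
FUSION_FEATURES = (
    "docs_total",
    "mis_score",
    "bai_total",
    "bdi_total",
    "age",
    "sex",
    "education",
)
CATEGORICAL_FEATURES = frozenset({"sex", "education"})


class FusionError(ValueError):
    pass


@dataclass
class FusionResult:
    feature: str | None  # None = EEG-score-only baseline
    n_used: int
    auc: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    skipped_folds: int = 0
    change_label: str | None = None  # Improved | None | Worse vs baseline


def assemble_fusion_table(
    scores: list[SubjectScore],
    covariates: pd.DataFrame,
    feature: str | None,
) -> pd.DataFrame:
    """One row per subject with a non-missing value of ``feature``
    (``None`` keeps all subjects: the EEG-only baseline table)."""
    if feature is not None and feature not in FUSION_FEATURES:
        raise FusionError(
            f"unknown feature {feature!r}; valid features: {list(FUSION_FEATURES)}"
        )
    cov = covariates.set_index("subject_id")
    missing_subjects = [s.subject_id for s in scores if s.subject_id not in cov.index]
    if missing_subjects:
        raise FusionError(f"subjects absent from covariate table: {missing_subjects}")
    rows = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in scores],
            "eeg_score": [s.score for s in scores],
            "truth": [s.truth for s in scores],
        }
    )
    if feature is not None:
        rows[feature] = cov.loc[rows["subject_id"], feature].to_numpy()
        rows = rows.dropna(subset=[feature]).reset_index(drop=True)
    return rows


def _design_matrices(
    train: pd.DataFrame, test: pd.DataFrame, feature: str | None
) -> tuple[np.ndarray, np.ndarray]:
    """Fold-wise preprocessing: z-score numerics on training rows,
    one-hot categoricals (categories unseen in training map to all
    zeros)."""
    num_cols = ["eeg_score"]
    cat_cols: list[str] = []
    if feature is not None:
        (cat_cols if feature in CATEGORICAL_FEATURES else num_cols).append(feature)
    scaler = StandardScaler().fit(train[num_cols])
    blocks_tr = [scaler.transform(train[num_cols])]
    blocks_te = [scaler.transform(test[num_cols])]
    if cat_cols:
        enc = OneHotEncoder(handle_unknown="ignore", sparse_output=False)
        enc.fit(train[cat_cols].astype(str))
        blocks_tr.append(enc.transform(train[cat_cols].astype(str)))
        blocks_te.append(enc.transform(test[cat_cols].astype(str)))
    return np.hstack(blocks_tr), np.hstack(blocks_te)


def run_fusion_loso(
    rows: pd.DataFrame, feature: str | None = None, seed: int = 0
) -> FusionResult:
    """LOSO evaluation of the second-stage logistic regression.

    Pooled held-out probabilities across folds yield AUC, accuracy and
    macro-averaged precision/recall/F1 (labels thresholded strictly above
    0.5). Folds whose training rows contain a single class are skipped
    and counted.
    """
    truth_counts = rows["truth"].value_counts()
    if len(truth_counts) < 2 or truth_counts.min() < 2:
        raise FusionError("need >= 2 subjects per class after missing-value drop")
    folds = make_loso_folds(rows["subject_id"].tolist())
    indexed = rows.set_index("subject_id")
    probs: dict[str, float] = {}
    skipped = 0
    for fold in folds:
        train = indexed.loc[list(fold.train_subject_ids)].reset_index()
        test = indexed.loc[[fold.test_subject_id]].reset_index()
        if train["truth"].nunique() < 2:
            skipped += 1
            continue
        x_tr, x_te = _design_matrices(train, test, feature)
        clf = LogisticRegression(C=1.0, max_iter=1000)  # ridge penalty at unit strength
        clf.fit(x_tr, train["truth"].to_numpy())
        idx = int(np.where(clf.classes_ == 1)[0][0])
        probs[fold.test_subject_id] = float(clf.predict_proba(x_te)[0, idx])
    scored = rows[rows["subject_id"].isin(probs)].copy()
    scored["prob"] = scored["subject_id"].map(probs)
    truth = scored["truth"].to_numpy()
    pred = (scored["prob"].to_numpy() > 0.5).astype(int)
    report = classification_metrics(confusion(truth, pred))
    return FusionResult(
        feature=feature,
        n_used=len(rows),
        auc=roc_auc(truth, scored["prob"].to_numpy()),
        accuracy=report.accuracy,
        precision=report.macro_avg[0],
        recall=report.macro_avg[1],
        f1=report.macro_avg[2],
        skipped_folds=skipped,
    )


def compare_to_baseline(
    results: list[FusionResult], baseline: FusionResult
) -> list[FusionResult]:
    """Label each augmented model against the baseline AUC at two-decimal
    precision and order rows canonically."""
    base = round(baseline.auc, 2)
    labeled = []
    for r in results:
        auc = round(r.auc, 2)
        label = "Improved" if auc > base else ("None" if auc == base else "Worse")
        labeled.append(replace(r, change_label=label))
    order = {f: i for i, f in enumerate(FUSION_FEATURES)}
    return sorted(labeled, key=lambda r: order.get(r.feature, -1))


def run_fusion_analysis(
    scores: list[SubjectScore],
    covariates: pd.DataFrame,
    seed: int = 0,
    features: tuple[str, ...] = FUSION_FEATURES,
) -> tuple[FusionResult, list[FusionResult]]:
    """Baseline (EEG score only) plus every one-covariate augmentation."""
    baseline = run_fusion_loso(assemble_fusion_table(scores, covariates, None), None, seed)
    results = [
        run_fusion_loso(assemble_fusion_table(scores, covariates, f), f, seed)
        for f in features
    ]
    return baseline, compare_to_baseline(results, baseline)
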