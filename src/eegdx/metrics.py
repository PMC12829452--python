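"""Classification metrics for subject-level evaluation.

Confusion counts, per-class precision/recall/F1, accuracy, macro and
support-weighted averages, and ROC AUC with the Mann-Whitney tie
convention (ties between a positive and a negative score count 1/2).
Internal values are kept at full precision; report rendering rounds
half-even to two decimals to match conventional printed tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "classification_metrics",
    "roc_auc",
    "render_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts for binary labels (0 = control, 1 = case)."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        for name in ("tn", "fp", "fn", "tp"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


@dataclass
class MetricsReport:
    """Per-class and aggregate metrics; ``flags`` names any metric whose
    denominator was zero (reported as 0.0 by convention)."""

    precision: dict[int, float]
    recall: dict[int, float]
    f1: dict[int, float]
    support: dict[int, int]
    accuracy: float
    macro_avg: tuple[float, float, float]
    weighted_avg: tuple[float, float, float]
    auc: float | None = None
    flags: list[str] = field(default_factory=list)


def _check_binary(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a)
    if not np.isin(a, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return a.astype(int)


def confusion(truth, predicted) -> ConfusionCounts:
    """Count the four outcomes of binary prediction against truth."""
    t = _check_binary(truth, "truth")
    p = _check_binary(predicted, "predicted")
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: truth {t.shape} vs predicted {p.shape}")
    return ConfusionCounts(
        tn=int(((t == 0) & (p == 0)).sum()),
        fp=int(((t == 0) & (p == 1)).sum()),
        fn=int(((t == 1) & (p == 0)).sum()),
        tp=int(((t == 1) & (p == 1)).sum()),
    )


def _ratio(num: int, den: int, label: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(label)
        return 0.0
    return num / den


def classification_metrics(c: ConfusionCounts) -> MetricsReport:
    """Full classification report from confusion counts (AUC not included;
    it needs continuous scores, see :func:`roc_auc`)."""
    if c.n == 0:
        raise ValueError("empty confusion matrix")
    flags: list[str] = []
    prec = {
        0: _ratio(c.tn, c.tn + c.fn, "precision_0", flags),
        1: _ratio(c.tp, c.tp + c.fp, "precision_1", flags),
    }
    rec = {
        0: _ratio(c.tn, c.tn + c.fp, "recall_0", flags),
        1: _ratio(c.tp, c.tp + c.fn, "recall_1", flags),
    }
    f1 = {}
    for k in (0, 1):
        s = prec[k] + rec[k]
        f1[k] = _ratio_f(2 * prec[k] * rec[k], s, f"f1_{k}", flags)
    support = {0: c.tn + c.fp, 1: c.tp + c.fn}
    accuracy = (c.tp + c.tn) / c.n
    macro = tuple(np.mean([d[0], d[1]]) for d in (prec, rec, f1))
    w = np.array([support[0], support[1]], dtype=float) / c.n
    weighted = tuple(w[0] * d[0] + w[1] * d[1] for d in (prec, rec, f1))
    return MetricsReport(
        precision=prec,
        recall=rec,
        f1=f1,
        support=support,
        accuracy=accuracy,
        macro_avg=macro,
        weighted_avg=weighted,
        flags=flags,
    )


def _ratio_f(num: float, den: float, label: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(label)
        return 0.0
    return num / den


def roc_auc(truth, scores) -> float:
    """Area under the ROC curve as the pairwise concordance probability.

    Equals the probability that a random positive scores above a random
    negative, counting ties 1/2 (Mann-Whitney U / n_pos / n_neg).
    """
    t = _check_binary(truth, "truth")
    s = np.asarray(scores, dtype=float)
    if t.shape != s.shape:
        raise ValueError("truth and scores must have equal length")
    n_pos = int(t.sum())
    n_neg = int(t.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present in truth")
    ranks = rankdata(s)  # average ranks implement the 1/2-tie convention
    u = ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


_CLASS_NAMES = {0: "HC (0)", 1: "OCD (1)"}


def _r2(x: float) -> str:
    # round-half-even at 2 decimals, matching printed-table precision
    return f"{round(float(x), 2):.2f}"


def render_report(metrics: MetricsReport, style: str = "text") -> str:
    """Render a classification report as text or CSV.

    Layout: one row per class (precision, recall, F1, support), then
    accuracy, macro-average and weighted-average rows.
    """
    if metrics.support[0] == 0 or metrics.support[1] == 0:
        raise ValueError("cannot render report with an empty class")
    rows: list[tuple[str, str, str, str, str]] = []
    for k in (0, 1):
        rows.append(
            (
                _CLASS_NAMES[k],
                _r2(metrics.precision[k]),
                _r2(metrics.recall[k]),
                _r2(metrics.f1[k]),
                str(metrics.support[k]),
            )
        )
    n = metrics.support[0] + metrics.support[1]
    rows.append(("Accuracy", "-", "-", _r2(metrics.accuracy), str(n)))
    rows.append(("Macro Avg", *map(_r2, metrics.macro_avg), str(n)))
    rows.append(("Wtd Avg", *map(_r2, metrics.weighted_avg), str(n)))
    if style == "csv":
        header = "class,precision,recall,f1,support"
        return "\n".join([header] + [",".join(r) for r in rows])
    if style == "text":
        return "\n".join(" ".join(r) for r in rows)
    raise ValueError(f"unknown style {style!r}")
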