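"""Classification report for a 20-subject confusion matrix.

Reproduces, as a worked example, the subject-level report implied by a
confusion matrix with 8 true negatives, 2 false positives, 1 false
negative and 9 true positives.
"""

from eegdx.metrics import ConfusionCounts, classification_metrics, render_report, roc_auc

counts = ConfusionCounts(tn=8, fp=2, fn=1, tp=9)
report = classification_metrics(counts)
print(render_report(report))
print(f"\naccuracy {report.accuracy:.2%} of {counts.n} subjects")

# AUC needs continuous scores, not counts: illustrate on a score vector
truth = [0] * 10 + [1] * 10
scores = [0.2, 0.1, 0.4, 0.3, 0.6, 0.2, 0.3, 0.7, 0.1, 0.4,
          0.8, 0.9, 0.6, 0.7, 0.4, 0.9, 0.8, 0.6, 0.7, 0.9]
print(f"pairwise-concordance AUC of the example scores: {roc_auc(truth, scores):.2f}")
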