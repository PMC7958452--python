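"""Classification metrics and multi-run confidence intervals.

Sensitivity-specificity and precision-recall AUCs, threshold metrics
including the Matthews correlation coefficient, and t-based 95% confidence
intervals across repeated training runs.
"""

import numpy as np

from fieldgan import classification_report, multi_run_ci, paired_difference_ci

rng = np.random.default_rng(0)
labels = np.r_[np.ones(30, int), np.zeros(30, int)]
scores = np.where(labels == 1, rng.normal(0.7, 0.15, 60), rng.normal(0.35, 0.15, 60))

rep = classification_report(scores, labels)
print(f"SS-AUC {rep.auc_ss:.3f}  PR-AUC {rep.auc_pr:.3f}")
print(f"acc {rep.accuracy:.2f}  sens {rep.sensitivity:.2f}  "
      f"spec {rep.specificity:.2f}  F1 {rep.f1:.2f}  MCC {rep.mcc:.2f}")

# 95% CI across repeated runs, and a paired difference of two model variants
auc_runs_a = [0.93, 0.91, 0.94, 0.92, 0.95]
auc_runs_b = [0.90, 0.89, 0.92, 0.90, 0.91]
lo, hi, mean = multi_run_ci(auc_runs_a)
print(f"variant A AUC mean {mean:.3f}, 95% CI [{lo:.3f}, {hi:.3f}]")
lo, hi, mean = paired_difference_ci(auc_runs_a, auc_runs_b)
print(f"A - B difference   {mean:.3f}, 95% CI [{lo:.3f}, {hi:.3f}]")
# an interval excluding 0 indicates a consistent advantage of A over B
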