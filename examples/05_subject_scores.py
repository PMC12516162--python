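"""Threshold-invariant subject-level biomarker scores and ROC/Youden.

Subject scores avoid hard counts: the lesion score sums candidate lesion
probabilities; PRL% / CVS% are lesion-probability-weighted means x100.  The
ROC utility then selects an operating threshold at Youden's J.
"""

import numpy as np

import rimvein as rv
from rimvein.network import CandidatePrediction

# one subject's candidate predictions (as produced by classify_all_candidates)
preds = [CandidatePrediction(0.95, 0.82, 0.10),
         CandidatePrediction(0.90, 0.05, 0.75),
         CandidatePrediction(0.60, 0.10, 0.15),
         CandidatePrediction(0.08, 0.50, 0.50)]   # likely false positive

s = rv.subject_scores(preds)
print(f"lesion score = {s.lesion_score:.2f} (sum of lesion probabilities;"
      " the false positive contributes little)")
print(f"PRL% = {s.prl_pct:.1f}, CVS% = {s.cvs_pct:.1f} (lesion-weighted"
      " percentages, insensitive to any threshold choice)")

# candidate-level ROC with a seeded synthetic validation set
rng = np.random.default_rng(0)
labels = rng.integers(0, 2, 400)
scores = np.clip(labels * 0.35 + rng.normal(0.35, 0.18, 400), 0, 1)
roc = rv.roc_and_youden(scores, labels)
print(f"\nAUROC = {roc.auroc:.3f}; Youden threshold = {roc.youden_threshold:.3f}"
      f" (J = {roc.youden_j:.3f}) — the operating point that maximizes"
      " sensitivity + specificity - 1.")
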