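"""Sensitivity, specificity, accuracy and the ROC curve.

Temperate is the positive class: sensitivity is the recall of temperate
phages, specificity the recall of virulent phages. AUCROC is computed by
the trapezoidal rule and equals the Mann-Whitney rank statistic.
"""

import numpy as np

from phalife.evaluate import confusion, metrics, roc_auc

rng = np.random.default_rng(0)
n = 400
truth = rng.choice(["temperate", "virulent"], size=n)
# a noisy scorer: temperate phages tend to score higher
scores = np.where(truth == "temperate", 0.72, 0.30) + rng.normal(0, 0.2, n)
calls = np.where(scores >= 0.5, "temperate", "virulent")

counts = confusion(truth.tolist(), calls.tolist())
m = metrics(counts)
print(f"TP={counts.tp} FN={counts.fn} TN={counts.tn} FP={counts.fp}")
print(f"sensitivity={m['sensitivity']:.3f} "
      f"specificity={m['specificity']:.3f} accuracy={m['accuracy']:.3f}")

roc = roc_auc(scores, (truth == "temperate").astype(int))
print(f"AUCROC={roc.auc:.3f} over {len(roc.fpr)} ROC points")
# AUCROC is the probability a random temperate phage outscores a random
# virulent one; 0.5 is chance, 1.0 is perfect separation.
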