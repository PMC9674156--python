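"""Example-based multi-label metrics and the probability-0.5 baseline.

Multi-functional residues (those carrying at least two of the five
function labels) turn residue-level prediction into a multi-label task.
This script scores a random predictor that includes each label with
probability 0.5 — the reference point against which a trained predictor's
Hamming loss / accuracy / precision / recall / F1 are judged.
"""

import numpy as np

from pclm.metrics import multilabel_metrics, random_baseline

rng = np.random.default_rng(3)
n = 1352  # size of a typical multi-functional evaluation pool
sizes = rng.choice([2, 3, 4, 5], size=n, p=[0.7, 0.2, 0.07, 0.03])
truth = [set(rng.choice(5, size=s, replace=False) + 1) for s in sizes]

predicted = random_baseline(truth, q=5, prob=0.5, seed=11)
ev = multilabel_metrics(predicted, truth, q=5)

print(f"examples (p): {ev.p}   labels (q): {ev.q}")
print(f"Hamming loss : {ev.hamming_loss:.3f}   (expectation 0.5)")
print(f"Accuracy_exam: {ev.accuracy_exam:.3f}")
print(f"Precision    : {ev.precision_exam:.3f}")
print(f"Recall       : {ev.recall_exam:.3f}   (expectation 0.5)")
print(f"F1           : {ev.f1_exam:.3f}")
# A coin-flip predictor mislabels half of all label slots regardless of the
# truth distribution, hence Hamming loss and recall concentrate near 0.5.
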