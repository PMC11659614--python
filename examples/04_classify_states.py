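"""Decode behavioral states from whole-brain timescale features.

Builds a recording that alternates between rest and task states, estimates
tau per channel per 10-s window, and trains a nested-cross-validated
RBF-kernel SVM to predict the state of each window from the tau
topography.
"""

import numpy as np

from intflex.classification import build_feature_table, nested_cv_classify
from intflex.synthetic import gen_state_recording
from intflex.timescales import windowed_int

rng = np.random.default_rng(3)
n_ch = 20
tau_rest = 0.25 * np.exp(rng.normal(0.0, 0.2, n_ch))

schedule = [("rest", 50.0), ("task", 50.0)] * 10
rec = gen_state_recording(
    schedule, {"rest": tau_rest, "task": 1.8 * tau_rest},
    n_channels=n_ch, fs=20.0, seed=4,
)
X, y = build_feature_table(windowed_int(rec))
report = nested_cv_classify(X, y, model="svm", inner=5, outer=5,
                            n_iter=10, seed=5)

print(f"windows: {len(y)}, features (channels): {X.shape[1]}")
print(f"overall accuracy: {report.overall_accuracy:.0%}")
print("confusion matrix (rows = true state):")
print(report.confusion.to_string())
for state, roc in report.roc.items():
    print(f"one-vs-rest AUC [{state}]: {roc['auc']:.3f}")
print()
print("Accuracy far above the 50% chance level shows the timescale")
print("topography alone separates the two states; hyperparameters were")
print("tuned only on inner folds, so the estimate is leakage-free.")
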