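"""Tune an RBF-SVM's (C, gamma) with the fuzzy self-tuning swarm.

The swarm maximizes stratified 5-fold cross-validated accuracy over the
box [0, 30]^2; no inertia weights or learning factors are set by hand.
"""

from hybridsvm import encode_features, generate_imbalanced
from hybridsvm.svm import tune_svm

ds = encode_features(generate_imbalanced(70, 30, d=2, separation=2.5, seed=0))
result = tune_svm(ds, max_iter=30, seed=0)

print(f"best C       : {result.hyperparams.C:.4f}")
print(f"best gamma   : {result.hyperparams.gamma:.4f}")
print(f"cv accuracy  : {result.best_fitness:.4f}")
print(result.trace_frame().head(5).to_string(index=False))
# The trace's best-cv-accuracy column is monotone non-decreasing: the
# swarm never forgets its best (C, gamma).
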