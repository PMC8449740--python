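"""Run the full hybrid pipeline and compare it with an untuned SVM.

Filter noise -> balance with SMOTE -> split -> swarm-tune the SVM ->
score the held-out test set with imbalance-aware metrics.
"""

from hybridsvm import generate_imbalanced, inject_label_noise
from hybridsvm.pipeline import (GeneratorSpec, PipelineConfig, baseline_svm,
                                run_pipeline)

gen = GeneratorSpec(n_majority=400, n_minority=70, d=2,
                    separation=4.0, noise_rate=0.1)
cfg = PipelineConfig(generator=gen, seed=0, n_folds=5, max_iter=15)
res = run_pipeline(cfg)

raw = generate_imbalanced(gen.n_majority, gen.n_minority, gen.d,
                          gen.separation, seed=0)
noisy, _ = inject_label_noise(raw, gen.noise_rate, seed=1)
base, base_auc = baseline_svm(noisy, seed=0)

print(f"removed by filter : {res.manifest['removed']}")
print(f"synthetic samples : {res.manifest['synthetic']}")
print(f"best (C, gamma)   : ({res.hyperparams.C:.3f}, {res.hyperparams.gamma:.3f})")
print(f"pipeline  G-mean  : {res.metrics.gmean:.3f}   AUC {res.auc:.3f}")
print(f"raw SVM   G-mean  : {base.gmean:.3f}   AUC {base_auc:.3f}")
# The raw SVM leans toward the majority class (low G-mean); cleaning,
# balancing and tuning recover minority sensitivity without giving up
# specificity.  Note the default 'paper' stage order oversamples before
# splitting, which optimistically biases test metrics; pass
# mode='leak_safe' for an honest generalization estimate.
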