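"""End-to-end orchestration: filter -> oversample -> split -> tune -> test.

Two stage orders ship:

* ``paper`` (default) — the printed procedure: the *whole* dataset is
  noise-filtered and SMOTE-balanced, and only then split into train/test.
  Synthetic neighbours of eventual test points are visible during
  training, so metrics from this order are optimistically biased; a loud
  warning is logged.
* ``leak_safe`` — the split happens first and filtering, encoding and
  oversampling are fit on the training partition only; the test partition
  contains no synthetic samples.

Every stage writes its counts, seeds and chosen hyperparameters into a run
manifest so downstream checks read structured records, not stdout.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np

from .data import (Dataset, FeatureEncoder, generate_imbalanced,
                   inject_label_noise, read_table, stratified_split)
from .filtering import cvcf_filter
from .fpso import SearchSpace
from .metrics import (MetricSet, auc, compute_metrics,
                      confusion_from_predictions)
from .smote import SmoteConfig, smote_oversample
from .svm import DEFAULT_BOX, SVMHyperparams, train_svm, tune_svm

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "baseline_svm"]

log = logging.getLogger("hybridsvm")


@dataclass(frozen=True)
class GeneratorSpec:
    """Synthetic-source parameters for runs without an input file."""

    n_majority: int = 400
    n_minority: int = 70
    d: int = 2
    separation: float = 4.0
    noise_rate: float = 0.1
    n_nominal: int = 0


@dataclass(frozen=True)
class PipelineConfig:
    source: str | None = None            # CSV/ARFF path; None -> generator
    sidecar: str | None = None
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    n_folds: int = 10                    # CVCF committee size
    voting: str = "majority"
    smote_k: int = 5
    smote_target: int | str = "balanced"
    box: SearchSpace = DEFAULT_BOX
    max_iter: int = 30
    fitness_folds: int = 5
    test_fraction: float = 0.2
    mode: str = "paper"                  # or "leak_safe"
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("paper", "leak_safe"):
            raise ValueError("mode must be 'paper' or 'leak_safe'")

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(self, seed=seed)


@dataclass
class PipelineResult:
    metrics: MetricSet
    auc: float
    hyperparams: SVMHyperparams
    removed_indices: np.ndarray
    synthetic_count: int
    manifest: dict
    tune: object
    filter_result: object


def _load(cfg: PipelineConfig) -> Dataset:
    if cfg.source is not None:
        return read_table(cfg.source, sidecar=cfg.sidecar)
    g = cfg.generator
    ds = generate_imbalanced(g.n_majority, g.n_minority, g.d, g.separation,
                             seed=cfg.seed, n_nominal=g.n_nominal)
    if g.noise_rate > 0:
        ds, _rec = inject_label_noise(ds, g.noise_rate, seed=cfg.seed + 1)
    return ds


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the ten-step hybrid procedure and score the held-out test set."""
    manifest: dict = {"mode": cfg.mode, "seed": cfg.seed}

    def stage(name):
        def wrap(fn, *a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage {name!r} failed (config={cfg})") from exc
        return wrap

    ds = stage("load")(_load, cfg)
    manifest["n"], (manifest["n_majority"], manifest["n_minority"]) = ds.n, ds.class_counts()

    if cfg.mode == "paper":
        log.warning("mode='paper' filters and oversamples before splitting: "
                    "synthetic neighbours of test points leak into training "
                    "and inflate test metrics; use mode='leak_safe' for "
                    "honest generalization estimates")
        fr = stage("cvcf")(cvcf_filter, ds, cfg.n_folds, cfg.voting, cfg.seed)
        enc = FeatureEncoder().fit(fr.clean)
        encoded = enc.transform(fr.clean)
        balanced = stage("smote")(
            smote_oversample, encoded,
            SmoteConfig(cfg.smote_k, cfg.smote_target, cfg.seed))
        train, test = stage("split")(
            stratified_split, balanced, cfg.test_fraction, cfg.seed)
    else:
        raw_train, raw_test = stage("split")(
            stratified_split, ds, cfg.test_fraction, cfg.seed)
        fr = stage("cvcf")(cvcf_filter, raw_train, cfg.n_folds, cfg.voting, cfg.seed)
        enc = FeatureEncoder().fit(fr.clean)
        train = stage("smote")(
            smote_oversample, enc.transform(fr.clean),
            SmoteConfig(cfg.smote_k, cfg.smote_target, cfg.seed))
        test = enc.transform(raw_test)

    manifest["removed"] = int(fr.removed_indices.size)
    manifest["n_after_filter"] = fr.clean.n
    synthetic = train.n + test.n - fr.clean.n if cfg.mode == "paper" \
        else train.n - fr.clean.n
    manifest["synthetic"] = int(synthetic)
    manifest["n_train"], manifest["n_test"] = train.n, test.n

    tuned = stage("tune")(tune_svm, train, cfg.box, cfg.max_iter, cfg.seed,
                          cfg.fitness_folds)
    manifest["best_C"] = tuned.hyperparams.C
    manifest["best_gamma"] = tuned.hyperparams.gamma
    manifest["best_cv_accuracy"] = tuned.best_fitness

    scores = tuned.model.decision_scores(test)
    pred = (scores > 0).astype(int)
    cm = confusion_from_predictions(test.labels, pred)
    ms = compute_metrics(cm)
    test_auc = auc(test.labels, scores)
    manifest["confusion"] = {"TP": cm.TP, "FP": cm.FP, "FN": cm.FN, "TN": cm.TN}
    manifest.update(ms.as_dict())
    manifest["auc"] = test_auc

    if cfg.outdir:
        os.makedirs(cfg.outdir, exist_ok=True)
        fr.to_frame().to_csv(os.path.join(cfg.outdir, "filter_audit.csv"),
                             index=False)
        tuned.trace_frame().to_csv(os.path.join(cfg.outdir, "tune_trace.csv"),
                                   index=False)
        with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)
    for key in ("n", "removed", "synthetic", "best_C", "best_gamma"):
        log.info("%s = %s", key, manifest[key])
    return PipelineResult(ms, test_auc, tuned.hyperparams, fr.removed_indices,
                          int(synthetic), manifest, tuned, fr)


def baseline_svm(ds: Dataset, test_fraction: float = 0.2, seed: int = 0
                 ) -> tuple[MetricSet, float]:
    """Untuned RBF-SVM (C=1, gamma=1/d) on a plain stratified split.

    The no-preprocessing reference the hybrid pipeline is compared
    against: no noise filter, no oversampling, default hyperparameters.
    """
    train_raw, test_raw = stratified_split(ds, test_fraction, seed)
    enc = FeatureEncoder().fit(train_raw)
    train, test = enc.transform(train_raw), enc.transform(test_raw)
    hp = SVMHyperparams(C=1.0, gamma=1.0 / train.d)
    model = train_svm(train, hp)
    scores = model.decision_scores(test)
    cm = confusion_from_predictions(test.labels, (scores > 0).astype(int))
    return compute_metrics(cm), auc(test.labels, scores)
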