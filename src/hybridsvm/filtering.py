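"""Cross-validated committees filter (CVCF) for label-noise removal.

The dataset is split into stratified folds; one gain-ratio tree is trained
on the complement of each fold, and *every* tree then votes on *every*
sample.  A sample is marked as noise and removed when its committee votes
contradict its recorded label — under ``consensus`` voting all trees must
disagree with the label, under ``majority`` voting more than half must.
Majority voting is strictly more aggressive, so its removed set always
contains the consensus one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .data import Dataset
from .tree import fit_tree, predict_tree

__all__ = ["FilterResult", "cvcf_filter"]

VOTING_SCHEMES = ("consensus", "majority")


@dataclass
class FilterResult:
    """Outcome of a CVCF pass, serializable as an audit table."""

    clean: Dataset
    removed_indices: np.ndarray
    vote_matrix: np.ndarray  # n x n_folds predicted labels
    voting: str
    original_labels: np.ndarray

    def votes_against(self) -> np.ndarray:
        return (self.vote_matrix != self.original_labels[:, None]).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        """Audit table: index, label, votes against, removed flag."""
        removed = np.zeros(len(self.original_labels), bool)
        removed[self.removed_indices] = True
        return pd.DataFrame({
            "index": np.arange(len(self.original_labels)),
            "label": self.original_labels,
            "votes_against": self.votes_against(),
            "removed": removed,
        })


def cvcf_filter(ds: Dataset, n_folds: int = 10, voting: str = "majority",
                seed: int = 0, min_leaf: int = 10,
                max_depth: int | None = None) -> FilterResult:
    """Remove samples whose label the cross-validated committee rejects.

    Parameters
    ----------
    ds : dataset to clean (mixed column kinds are fine — the base learner
        handles nominal attributes natively).
    n_folds : number of stratified folds / committee members (default 10).
    voting : "majority" (> n_folds/2 disagreeing votes remove a sample,
        the default) or "consensus" (all must disagree).
    seed : controls the fold assignment.
    min_leaf : leaf-size floor of the committee trees (default 10).  The
        committee votes on *every* sample, including ones a member was
        trained on, so the base learner must generalize rather than
        memorize: classical C4.5 achieves that by pruning, which this
        filter replaces with a leaf floor large enough that an isolated
        mislabeled sample cannot earn its own pure leaf.
    """
    if voting not in VOTING_SCHEMES:
        raise ValueError(f"voting must be one of {VOTING_SCHEMES}")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > ds.n:
        raise ValueError("n_folds cannot exceed the sample count")
    n0, n1 = ds.class_counts()
    if min(n0, n1) < n_folds:
        raise ValueError("both classes need >= n_folds members for stratified folds")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    votes = np.empty((ds.n, n_folds), dtype=np.int64)
    for f, (train_idx, _test_idx) in enumerate(skf.split(ds.features, ds.labels)):
        tree = fit_tree(ds.subset(train_idx), min_leaf=min_leaf, max_depth=max_depth)
        votes[:, f] = predict_tree(tree, ds.features)

    against = (votes != ds.labels[:, None]).sum(axis=1)
    if voting == "consensus":
        removed = np.nonzero(against == n_folds)[0]
    else:
        removed = np.nonzero(against > n_folds / 2)[0]
    keep = np.setdiff1d(np.arange(ds.n), removed)
    if keep.size == 0:
        raise ValueError("filter removed every sample; refusing to return empty data")
    clean = ds.subset(keep, ds.provenance + f"+cvcf({voting},k={n_folds})")
    return FilterResult(clean, removed, votes, voting, ds.labels.copy())
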