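"""Gain-ratio decision tree: the C4.5-style base learner of the noise filter.

Split quality is the information gain ratio
``InfoGain(S, A) / SplitInfo(S, A)`` with base-2 logarithms.  Candidate
splits must have strictly positive information gain (guarding the ratio's
small-SplitInfo pathology); numeric candidates are midpoints between
consecutive distinct sorted values; nominal attributes split multiway, one
branch per observed category.  No pruning, windowing or fractional
missing-value instances: leaves predict their majority class, ties going to
the positive (minority) class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import Dataset, NUMERIC

__all__ = ["GainRatio", "TreeNode", "gain_ratio", "fit_tree", "predict_tree"]

_EPS = 1e-12


@dataclass(frozen=True)
class GainRatio:
    """Split-quality triple; ``valid`` is False for degenerate splits."""

    info_gain: float
    split_info: float
    ratio: float
    valid: bool = True

    @staticmethod
    def invalid() -> "GainRatio":
        return GainRatio(0.0, 0.0, 0.0, valid=False)


def _entropy(labels: np.ndarray) -> float:
    """Shannon entropy in bits of a binary label vector."""
    if labels.size == 0:
        return 0.0
    p = np.bincount(labels, minlength=2) / labels.size
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def _score_partition(labels: np.ndarray, parts: list[np.ndarray]) -> GainRatio:
    nonempty = [p for p in parts if p.size]
    if len(nonempty) < 2:
        return GainRatio.invalid()
    n = labels.size
    cond = sum(p.size / n * _entropy(p) for p in nonempty)
    info_gain = _entropy(labels) - cond
    frac = np.array([p.size / n for p in nonempty])
    split_info = float(-np.sum(frac * np.log2(frac)))
    if info_gain <= _EPS or split_info <= _EPS:
        # zero-gain splits are never worth their split information
        return GainRatio(max(info_gain, 0.0), split_info,
                         0.0, valid=info_gain > _EPS)
    return GainRatio(info_gain, split_info, info_gain / split_info)


def gain_ratio(ds: Dataset, attribute: str, threshold: float | None = None) -> GainRatio:
    """Gain ratio of splitting ``ds`` on ``attribute``.

    ``threshold`` is required for numeric attributes (binary <=/> split) and
    forbidden for nominal ones (multiway split by category).  A split that
    leaves a single nonempty subset is returned as the invalid sentinel and
    never enters the candidate set of :func:`fit_tree`.
    """
    schema = {s.name: s for s in ds.schema}
    if attribute not in schema:
        raise KeyError(attribute)
    numeric = schema[attribute].kind == NUMERIC
    if numeric and threshold is None:
        raise ValueError("numeric attribute needs a threshold")
    if not numeric and threshold is not None:
        raise ValueError("nominal attribute takes no threshold")
    y = ds.labels
    if numeric:
        v = ds.features[attribute].to_numpy(float)
        parts = [y[v <= threshold], y[v > threshold]]
    else:
        v = ds.features[attribute].astype(str)
        parts = [y[(v == c).to_numpy()] for c in schema[attribute].categories]
    return _score_partition(y, parts)


def _best_numeric_split(values: np.ndarray, labels: np.ndarray, min_leaf: int
                        ) -> tuple[float, GainRatio] | None:
    """Vectorized scan over midpoint thresholds; best by gain ratio."""
    order = np.argsort(values, kind="stable")
    v, y = values[order], labels[order]
    n = v.size
    # candidate cut after position i (1-based count on the left)
    cut = np.nonzero(np.diff(v) > 0)[0] + 1
    cut = cut[(cut >= min_leaf) & (n - cut >= min_leaf)]
    if cut.size == 0:
        return None
    pos = np.cumsum(y)
    n1_left = pos[cut - 1]
    n_left = cut.astype(float)
    n_right = n - n_left
    n1_right = pos[-1] - n1_left

    def h(k, n_tot):
        with np.errstate(divide="ignore", invalid="ignore"):
            p = k / n_tot
            q = 1 - p
            t = np.where(p > 0, -p * np.log2(np.where(p > 0, p, 1)), 0.0)
            t += np.where(q > 0, -q * np.log2(np.where(q > 0, q, 1)), 0.0)
        return t

    cond = (n_left / n) * h(n1_left, n_left) + (n_right / n) * h(n1_right, n_right)
    gain = _entropy(y) - cond
    frac_l = n_left / n
    split_info = -(frac_l * np.log2(frac_l) + (1 - frac_l) * np.log2(1 - frac_l))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((gain > _EPS) & (split_info > _EPS), gain / split_info, 0.0)
    best = int(np.argmax(ratio))  # ties -> lowest threshold (argmax takes first)
    if ratio[best] <= 0:
        return None
    i = cut[best]
    thr = float((v[i - 1] + v[i]) / 2)
    return thr, GainRatio(float(gain[best]), float(split_info[best]), float(ratio[best]))


@dataclass
class TreeNode:
    """One node of a gain-ratio tree.

    Internal nodes carry ``split_attribute`` (+ ``threshold`` for numeric
    splits) and children keyed by ``"le"``/``"gt"`` or by category; leaves
    carry ``leaf_class``.  ``support`` is the training sample count.
    """

    support: int
    leaf_class: int | None = None
    split_attribute: str | None = None
    threshold: float | None = None
    children: dict[str, "TreeNode"] = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.leaf_class is not None

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(c.depth() for c in self.children.values())


def _fallback_split(feats: pd.DataFrame, schema, idx: np.ndarray,
                    min_leaf: int) -> tuple[int, float] | None:
    """First valid split ignoring gain: lowest column, lowest threshold."""
    for j, s in enumerate(schema):
        if s.kind == NUMERIC:
            v = np.sort(feats[s.name].to_numpy(float)[idx])
            cut = np.nonzero(np.diff(v) > 0)[0] + 1
            cut = cut[(cut >= min_leaf) & (idx.size - cut >= min_leaf)]
            if cut.size:
                i = cut[0]
                return j, float((v[i - 1] + v[i]) / 2)
        else:
            v = feats[s.name].astype(str).to_numpy()[idx]
            if len(np.unique(v)) >= 2:
                return j, 0.0
    return None


def _majority(labels: np.ndarray) -> int:
    n1 = int(labels.sum())
    n0 = labels.size - n1
    return 1 if n1 >= n0 else 0  # tie -> positive class


def fit_tree(ds: Dataset, min_leaf: int = 2, max_depth: int | None = None) -> TreeNode:
    """Greedy recursive partitioning maximizing gain ratio at each node."""
    if ds.n == 0:
        raise ValueError("cannot fit a tree on an empty dataset")
    schema = list(ds.schema)
    feats = ds.features

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        y = ds.labels[idx]
        node = TreeNode(support=idx.size)
        pure = y.min() == y.max()
        depth_done = max_depth is not None and depth >= max_depth
        if pure or depth_done or idx.size < 2 * min_leaf:
            node.leaf_class = _majority(y)
            return node
        best: tuple[float, int, float] | None = None  # (ratio, col_idx, thr)
        best_kind = None
        for j, s in enumerate(schema):
            if s.kind == NUMERIC:
                v = feats[s.name].to_numpy(float)[idx]
                res = _best_numeric_split(v, y, min_leaf)
                if res is None:
                    continue
                thr, gr = res
                cand = (gr.ratio, j, thr)
            else:
                v = feats[s.name].astype(str).to_numpy()[idx]
                parts = [y[v == c] for c in s.categories]
                gr = _score_partition(y, parts)
                if not gr.valid or gr.ratio <= 0:
                    continue
                cand = (gr.ratio, j, 0.0)
            # ties broken by lower column index, then lower threshold
            if best is None or cand[0] > best[0] + _EPS or (
                    abs(cand[0] - best[0]) <= _EPS and (cand[1], cand[2]) < best[1:]):
                best = cand
                best_kind = s.kind
        if best is None:
            # No split earns positive information gain, yet the node is
            # impure: an XOR-style configuration where the signal only
            # appears one level deeper.  Fall back to the first valid
            # zero-gain split (lowest column index, lowest threshold).
            fb = _fallback_split(feats, schema, idx, min_leaf)
            if fb is None:
                node.leaf_class = _majority(y)
                return node
            j, thr = fb
            best_kind = schema[j].kind
        else:
            _, j, thr = best
        s = schema[j]
        node.split_attribute = s.name
        if best_kind == NUMERIC:
            node.threshold = thr
            v = feats[s.name].to_numpy(float)[idx]
            node.children = {"le": build(idx[v <= thr], depth + 1),
                             "gt": build(idx[v > thr], depth + 1)}
        else:
            v = feats[s.name].astype(str).to_numpy()[idx]
            node.children = {c: build(idx[v == c], depth + 1)
                             for c in s.categories if (v == c).any()}
        return node

    return build(np.arange(ds.n), 0)


def _route(node: TreeNode, row: pd.Series) -> int:
    while not node.is_leaf:
        if node.threshold is not None:
            key = "le" if float(row[node.split_attribute]) <= node.threshold else "gt"
            node = node.children[key]
        else:
            key = str(row[node.split_attribute])
            child = node.children.get(key)
            if child is None:
                # unseen category: follow the best-supported branch
                child = max(node.children.values(), key=lambda c: c.support)
            node = child
    return node.leaf_class


def predict_tree(tree: TreeNode, samples: pd.DataFrame) -> np.ndarray:
    """Route every row of ``samples`` to a leaf and return its class."""
    return np.array([_route(tree, samples.iloc[i]) for i in range(len(samples))],
                    dtype=np.int64)
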