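"""SMOTE: synthetic minority oversampling by segment interpolation.

Each synthetic sample is ``X + delta * (X_i - X)`` for a minority sample X,
one of its k nearest minority neighbours X_i (Euclidean distance in the
encoded unit cube, ties broken by lower index) and ``delta ~ Uniform(0,1)``.
Parents are visited round-robin over a seeded shuffle of the minority class,
so per-parent synthetic counts differ by at most one and the balanced-count
postcondition is exact.  Originals are retained, synthetics appended.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dataset

__all__ = ["SmoteConfig", "minority_neighbour_table", "smote_oversample"]


@dataclass(frozen=True)
class SmoteConfig:
    """k nearest neighbours, target minority count and RNG seed.

    ``target="balanced"`` grows the minority class to the majority count.
    """

    k: int = 5
    target: int | str = "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (self.target == "balanced" or isinstance(self.target, int)):
            raise ValueError("target must be 'balanced' or an integer count")


def minority_neighbour_table(ds: Dataset, k: int) -> np.ndarray:
    """k nearest *other* minority samples for each minority sample.

    Returns an (n_minority, k) array of positions into the minority
    subset, ordered by increasing Euclidean distance with ties broken by
    lower index; self is excluded by index identity, so duplicated points
    are still each other's neighbours.
    """
    if not ds.is_numeric():
        raise ValueError("dataset must be numeric-encoded")
    x = ds.features.to_numpy(float)[ds.labels == 1]
    m = x.shape[0]
    if m < 2:
        raise ValueError("minority class needs >= 2 samples")
    if k > m - 1:
        raise ValueError(f"k={k} exceeds minority size - 1 = {m - 1}")
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    idx = np.arange(m)
    table = np.empty((m, k), dtype=np.int64)
    for i in range(m):
        order = np.lexsort((idx, d2[i]))  # distance first, then index
        table[i] = order[:k]
    return table


def smote_oversample(ds: Dataset, cfg: SmoteConfig = SmoteConfig(),
                     return_provenance: bool = False):
    """Oversample the minority class to ``cfg.target`` by SMOTE interpolation.

    With ``return_provenance=True`` also returns a DataFrame recording, for
    each synthetic row, its parent and neighbour (as row positions in the
    input dataset) and the interpolation coefficient delta — the audit
    trail used to verify the segment geometry.
    """
    if not ds.is_numeric():
        raise ValueError("dataset must be numeric-encoded before SMOTE")
    n0, n1 = ds.class_counts()
    target = n0 if cfg.target == "balanced" else int(cfg.target)
    if target < n1:
        raise ValueError(f"target {target} below current minority count {n1}")
    table = minority_neighbour_table(ds, cfg.k)  # validates minority size & k
    n_new = target - n1
    minority_pos = np.nonzero(ds.labels == 1)[0]
    x_min = ds.features.to_numpy(float)[minority_pos]

    rng = np.random.default_rng(cfg.seed)
    parent_order = rng.permutation(n1)
    rows = np.empty((n_new, ds.d), dtype=float)
    prov = []
    for t in range(n_new):
        p = parent_order[t % n1]
        nb = table[p][rng.integers(cfg.k)]
        delta = rng.uniform()
        rows[t] = x_min[p] + delta * (x_min[nb] - x_min[p])
        prov.append((int(minority_pos[p]), int(minority_pos[nb]), float(delta)))

    feats = pd.concat(
        [ds.features, pd.DataFrame(rows, columns=ds.features.columns)],
        ignore_index=True)
    labels = np.concatenate([ds.labels, np.ones(n_new, dtype=np.int64)])
    out = Dataset(feats, labels, list(ds.schema),
                  provenance=ds.provenance + f"+smote(k={cfg.k},n={n_new})")
    if return_provenance:
        return out, pd.DataFrame(prov, columns=["parent", "neighbour", "delta"])
    return out
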