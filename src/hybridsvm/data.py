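"""Dataset container, file I/O, synthetic generation and preprocessing.

The common currency of every pipeline stage is :class:`Dataset`: an n x d
feature table (mixed numeric / nominal / binary columns described by a
:class:`FeatureSchema` list) plus a binary label vector in which **1 marks
the positive = minority class** (e.g. death within one year of surgery).
All imbalance-aware metrics downstream are asymmetric in that convention.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.io import arff as _scipy_arff
from sklearn.model_selection import train_test_split

__all__ = [
    "FeatureSchema",
    "Dataset",
    "NoiseInjectionRecord",
    "FeatureEncoder",
    "UnsupportedFormatError",
    "read_table",
    "write_table",
    "generate_imbalanced",
    "inject_label_noise",
    "encode_features",
    "stratified_split",
]

NUMERIC, NOMINAL, BINARY = "numeric", "nominal", "binary"


class UnsupportedFormatError(ValueError):
    """Raised for ARFF constructs outside the dense numeric/nominal core."""


@dataclass(frozen=True)
class FeatureSchema:
    """Declared type of one feature column."""

    name: str
    kind: str  # numeric | nominal | binary
    categories: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in (NUMERIC, NOMINAL, BINARY):
            raise ValueError(f"unknown column kind {self.kind!r}")
        if self.kind == NUMERIC:
            if self.categories is not None:
                raise ValueError("numeric columns carry no categories")
        else:
            if self.categories is None or len(self.categories) < 2:
                raise ValueError(f"{self.kind} column {self.name!r} needs >=2 categories")
            if self.kind == BINARY and len(self.categories) != 2:
                raise ValueError(f"binary column {self.name!r} needs exactly 2 categories")


@dataclass
class Dataset:
    """Feature table + binary labels (1 = minority/positive class)."""

    features: pd.DataFrame
    labels: np.ndarray
    schema: list[FeatureSchema]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        n = len(self.features)
        if n < 1:
            raise ValueError("dataset must contain at least one sample")
        if self.labels.shape != (n,):
            raise ValueError("labels length must match feature rows")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        names = [s.name for s in self.schema]
        if names != list(self.features.columns):
            raise ValueError("schema names must match feature columns in order")
        if len(set(names)) != len(names):
            raise ValueError("duplicate column names")
        if self.features.isna().any().any():
            raise ValueError("missing values are not supported")

    # -- convenience -----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def d(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(majority=0 count, minority=1 count)."""
        return int(np.sum(self.labels == 0)), int(np.sum(self.labels == 1))

    def imbalance_ratio(self) -> float:
        """Majority count divided by minority count."""
        n0, n1 = self.class_counts()
        if n1 == 0:
            raise ValueError("no minority samples")
        return n0 / n1

    def is_numeric(self) -> bool:
        return all(s.kind == NUMERIC for s in self.schema)

    def subset(self, indices: np.ndarray, provenance: str | None = None) -> "Dataset":
        return Dataset(
            self.features.iloc[indices].reset_index(drop=True),
            self.labels[np.asarray(indices)],
            list(self.schema),
            provenance if provenance is not None else self.provenance,
        )


@dataclass(frozen=True)
class NoiseInjectionRecord:
    """Ground truth of a label-noise injection, for filter-recovery tests."""

    flipped_indices: tuple[int, ...]
    rate: float
    seed: int


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _infer_csv_schema(df: pd.DataFrame) -> list[FeatureSchema]:
    schema = []
    for col in df.columns:
        if pd.api.types.is_numeric_dtype(df[col]):
            schema.append(FeatureSchema(col, NUMERIC))
        else:
            cats = tuple(sorted(df[col].astype(str).unique()))
            kind = BINARY if len(cats) == 2 else NOMINAL
            schema.append(FeatureSchema(col, kind, cats))
    return schema


def _schema_from_sidecar(df: pd.DataFrame, sidecar: dict) -> list[FeatureSchema]:
    kinds = sidecar.get("columns", {})
    schema = []
    for col in df.columns:
        kind = kinds.get(col)
        if kind is None or kind == NUMERIC:
            inferred = _infer_csv_schema(df[[col]])[0]
            if kind == NUMERIC and inferred.kind != NUMERIC:
                raise ValueError(f"column {col!r} declared numeric but not parseable")
            schema.append(inferred if kind is None else FeatureSchema(col, NUMERIC))
        else:
            cats = tuple(sorted(df[col].astype(str).unique()))
            schema.append(FeatureSchema(col, kind, cats))
    return schema


def _read_csv(path: str, label: str | None, sidecar_path: str | None) -> Dataset:
    df = pd.read_csv(path)
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values are rejected at read time")
    sidecar: dict = {}
    if sidecar_path is not None:
        with open(sidecar_path) as fh:
            sidecar = yaml.safe_load(fh) or {}
    label = label or sidecar.get("label") or df.columns[-1]
    if label not in df.columns:
        raise ValueError(f"class column {label!r} not found")
    y_raw = df[label]
    df = df.drop(columns=[label])
    schema = _schema_from_sidecar(df, sidecar) if sidecar else _infer_csv_schema(df)
    labels = _binarize_labels(y_raw, sidecar.get("positive"))
    for s in schema:
        if s.kind != NUMERIC:
            df[s.name] = df[s.name].astype(str)
    return Dataset(df.reset_index(drop=True), labels, schema, provenance=f"csv:{path}")


def _binarize_labels(y: pd.Series, positive=None) -> np.ndarray:
    vals = y.astype(str)
    uniq, counts = np.unique(vals, return_counts=True)
    if len(uniq) != 2:
        raise ValueError(f"class column must be binary, found {list(uniq)}")
    if positive is None:
        # minority category is the positive class; ties broken alphabetically
        positive = uniq[np.lexsort((uniq, counts))[0]]
    return (vals == str(positive)).to_numpy().astype(np.int64)


_ARFF_UNSUPPORTED = re.compile(r"^\s*@attribute\s+\S+\s+(relational|date)", re.I)


def _read_arff(path: str, label: str | None) -> Dataset:
    with open(path) as fh:
        text = fh.read()
    in_data = False
    for line in text.splitlines():
        if _ARFF_UNSUPPORTED.match(line):
            raise UnsupportedFormatError(f"{path}: relational/date attributes unsupported")
        if in_data and line.strip().startswith("{"):
            raise UnsupportedFormatError(f"{path}: sparse ARFF data unsupported")
        if line.strip().lower().startswith("@data"):
            in_data = True
    try:
        data, meta = _scipy_arff.loadarff(io.StringIO(text))
    except Exception as exc:  # noqa: BLE001 - scipy raises several parse errors
        raise UnsupportedFormatError(f"{path}: cannot parse ARFF ({exc})") from exc
    df = pd.DataFrame(data)
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].str.decode("utf-8")
    label = label or meta.names()[-1]
    if label not in df.columns:
        raise ValueError(f"class column {label!r} not found")
    schema = []
    for name in meta.names():
        if name == label:
            continue
        kind, cats = meta[name]
        if kind == "numeric":
            schema.append(FeatureSchema(name, NUMERIC))
        else:
            cats = tuple(str(c) for c in cats)
            schema.append(FeatureSchema(name, BINARY if len(cats) == 2 else NOMINAL, cats))
    y_raw = df[label]
    df = df.drop(columns=[label])
    if df.isna().any().any() or (df.select_dtypes(object) == "?").any().any():
        raise ValueError(f"{path}: missing values are rejected at read time")
    return Dataset(df.reset_index(drop=True), _binarize_labels(y_raw), schema,
                   provenance=f"arff:{path}")


def read_table(path: str, format: str | None = None, label: str | None = None,
               sidecar: str | None = None) -> Dataset:
    """Read a labeled table from CSV or dense ARFF.

    Parameters
    ----------
    path : file path.
    format : "csv" or "arff"; inferred from the extension when omitted.
    label : class column name; defaults to the last column (CSV) or last
        declared attribute (ARFF).
    sidecar : optional YAML file declaring CSV column kinds
        (``columns: {name: nominal, ...}``), the label column and the
        positive category.

    The minority category of the class column becomes label 1.
    """
    fmt = format or ("arff" if str(path).lower().endswith(".arff") else "csv")
    if fmt == "csv":
        return _read_csv(path, label, sidecar)
    if fmt == "arff":
        return _read_arff(path, label)
    raise ValueError(f"unknown format {fmt!r}")


def write_table(ds: Dataset, path: str, format: str | None = None,
                label: str = "Class") -> None:
    """Write a Dataset to CSV or dense ARFF (labels as pos/neg categories)."""
    fmt = format or ("arff" if str(path).lower().endswith(".arff") else "csv")
    df = ds.features.copy()
    y = np.where(ds.labels == 1, "pos", "neg")
    if fmt == "csv":
        df[label] = y
        df.to_csv(path, index=False)
        return
    if fmt != "arff":
        raise ValueError(f"unknown format {fmt!r}")
    lines = ["@relation hybridsvm"]
    for s in ds.schema:
        if s.kind == NUMERIC:
            lines.append(f"@attribute {s.name} numeric")
        else:
            lines.append(f"@attribute {s.name} {{{','.join(s.categories)}}}")
    lines.append(f"@attribute {label} {{neg,pos}}")
    lines.append("@data")
    for i in range(ds.n):
        row = [repr(float(v)) if s.kind == NUMERIC else str(v)
               for v, s in zip(ds.features.iloc[i], ds.schema)]
        lines.append(",".join(row + [y[i]]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Synthetic generation
# ---------------------------------------------------------------------------

def generate_imbalanced(n_majority: int, n_minority: int, d: int = 2,
                        separation: float = 4.0, seed: int = 0,
                        n_nominal: int = 0, n_bins: int = 3) -> Dataset:
    """Two spherical unit-variance Gaussian clusters with exact class counts.

    The majority cluster (label 0) is centred at the origin; the minority
    cluster (label 1) at distance ``separation`` along the diagonal.  With
    ``n_nominal > 0`` the first ``n_nominal`` coordinates are discretized
    into ``n_bins`` equal-frequency categories, emulating the nominal
    attributes of clinical tables.
    """
    if n_majority < 1 or n_minority < 1 or d < 1:
        raise ValueError("counts and dimension must be >= 1")
    if not 0 <= n_nominal <= d:
        raise ValueError("n_nominal must lie in [0, d]")
    rng = np.random.default_rng(seed)
    mu = np.full(d, separation / np.sqrt(d))
    x_maj = rng.standard_normal((n_majority, d))
    x_min = rng.standard_normal((n_minority, d)) + mu
    x = np.vstack([x_maj, x_min])
    y = np.concatenate([np.zeros(n_majority, int), np.ones(n_minority, int)])
    df = pd.DataFrame(x, columns=[f"x{j}" for j in range(d)])
    schema: list[FeatureSchema] = []
    for j, col in enumerate(df.columns):
        if j < n_nominal:
            binned = pd.qcut(df[col], q=n_bins, labels=False, duplicates="drop")
            cats = tuple(f"c{b}" for b in range(int(binned.max()) + 1))
            df[col] = np.array([f"c{b}" for b in binned])
            schema.append(FeatureSchema(col, BINARY if len(cats) == 2 else NOMINAL, cats))
        else:
            schema.append(FeatureSchema(col, NUMERIC))
    return Dataset(df, y, schema,
                   provenance=f"synthetic(maj={n_majority},min={n_minority},"
                              f"d={d},sep={separation},seed={seed})")


def inject_label_noise(ds: Dataset, rate: float, seed: int = 0
                       ) -> tuple[Dataset, NoiseInjectionRecord]:
    """Flip ``round(rate * n)`` uniformly chosen labels.

    Rates of 0.5 or more are rejected: the noise would dominate the signal
    and no filter could be expected to recover the original labelling.
    Applying the same record twice restores the original labels.
    """
    if not 0 <= rate < 0.5:
        raise ValueError("noise rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    k = int(round(rate * ds.n))
    flipped = np.sort(rng.choice(ds.n, size=k, replace=False)) if k else np.array([], int)
    labels = ds.labels.copy()
    labels[flipped] = 1 - labels[flipped]
    noisy = Dataset(ds.features.copy(), labels, list(ds.schema),
                    provenance=ds.provenance + f"+noise(rate={rate},seed={seed})")
    return noisy, NoiseInjectionRecord(tuple(int(i) for i in flipped), rate, seed)


# ---------------------------------------------------------------------------
# Encoding and splitting
# ---------------------------------------------------------------------------

class FeatureEncoder:
    """One-hot nominal, {0,1} binary, min-max numeric -> unit cube.

    Fit on training data; ``transform`` raises on categories unseen at fit
    time and clips numeric columns of new data into [0, 1] so that RBF
    distances and SMOTE interpolation stay in a bounded cube.
    """

    def __init__(self) -> None:
        self.schema_: list[FeatureSchema] | None = None
        self.ranges_: dict[str, tuple[float, float]] = {}

    def fit(self, ds: Dataset) -> "FeatureEncoder":
        self.schema_ = list(ds.schema)
        for s in ds.schema:
            if s.kind == NUMERIC:
                col = ds.features[s.name].to_numpy(float)
                self.ranges_[s.name] = (float(col.min()), float(col.max()))
        return self

    def transform(self, ds: Dataset) -> Dataset:
        if self.schema_ is None:
            raise RuntimeError("encoder not fitted")
        if [s.name for s in ds.schema] != [s.name for s in self.schema_]:
            raise ValueError("column mismatch with fitted schema")
        cols: dict[str, np.ndarray] = {}
        schema: list[FeatureSchema] = []
        for s in self.schema_:
            raw = ds.features[s.name]
            if s.kind == NUMERIC:
                lo, hi = self.ranges_[s.name]
                v = raw.to_numpy(float)
                scaled = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
                cols[s.name] = np.clip(scaled, 0.0, 1.0)
                schema.append(FeatureSchema(s.name, NUMERIC))
            else:
                vals = raw.astype(str)
                unseen = set(vals.unique()) - set(s.categories)
                if unseen:
                    raise ValueError(f"unseen categories {sorted(unseen)} in {s.name!r}")
                if s.kind == BINARY:
                    cols[s.name] = (vals == s.categories[1]).to_numpy(float)
                    schema.append(FeatureSchema(s.name, NUMERIC))
                else:
                    for cat in s.categories:
                        name = f"{s.name}={cat}"
                        cols[name] = (vals == cat).to_numpy(float)
                        schema.append(FeatureSchema(name, NUMERIC))
        df = pd.DataFrame(cols)
        return Dataset(df, ds.labels.copy(), schema,
                       provenance=ds.provenance + "+encoded")


def encode_features(ds: Dataset) -> Dataset:
    """Fit-and-transform convenience wrapper around :class:`FeatureEncoder`."""
    return FeatureEncoder().fit(ds).transform(ds)


def stratified_split(ds: Dataset, test_fraction: float, seed: int = 0
                     ) -> tuple[Dataset, Dataset]:
    """Disjoint, exhaustive stratified split preserving class proportions."""
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    n0, n1 = ds.class_counts()
    if min(n0, n1) < 2:
        raise ValueError("each class needs >= 2 members to stratify")
    idx = np.arange(ds.n)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=ds.labels, random_state=seed)
    return (ds.subset(np.sort(train_idx), ds.provenance + "+train"),
            ds.subset(np.sort(test_idx), ds.provenance + "+test"))
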