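import numpy as np
import pandas as pd
import pytest

from hybridsvm.data import Dataset, FeatureSchema


def make_dataset(values, labels, kinds=None):
    """Small mixed-type Dataset from a column dict."""
    df = pd.DataFrame(values)
    kinds = kinds or {}
    schema = []
    for col in df.columns:
        kind = kinds.get(col, "numeric")
        if kind == "numeric":
            schema.append(FeatureSchema(col, "numeric"))
        else:
            cats = tuple(sorted(df[col].astype(str).unique()))
            schema.append(FeatureSchema(col, kind, cats))
            df[col] = df[col].astype(str)
    return Dataset(df, np.asarray(labels), schema)


@pytest.fixture
def xor_dataset():
    """The 2-D XOR pattern, each corner duplicated ten times."""
    pts = [(0, 0, 0), (1, 1, 0), (0, 1, 1), (1, 0, 1)] * 10
    return make_dataset({"x0": [p[0] for p in pts], "x1": [p[1] for p in pts]},
                        [p[2] for p in pts])


@pytest.fixture
def separable_encoded():
    """Well-separated encoded two-cluster data, 60/20."""
    from hybridsvm.data import encode_features, generate_imbalanced

    return encode_features(generate_imbalanced(60, 20, d=2, separation=6, seed=7))
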