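import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression

from hybridsvm.data import (Dataset, FeatureEncoder, FeatureSchema,
                            UnsupportedFormatError, encode_features,
                            generate_imbalanced, inject_label_noise,
                            read_table, stratified_split, write_table)
from tests.conftest import make_dataset

ARFF_NOMINAL = """@relation demo
@attribute a1 numeric
@attribute a2 {a,b,c}
@attribute Class {neg,pos}
@data
1.0,a,neg
2.0,b,neg
3.0,c,pos
4.0,a,neg
"""


class TestReadTable:
    def test_csv_roundtrip_identity(self, tmp_path):
        ds = make_dataset({"x": [1.5, 2.0, 3.25], "y": [0.0, 1.0, 2.0]}, [0, 0, 1])
        path = tmp_path / "t.csv"
        write_table(ds, str(path))
        back = read_table(str(path))
        assert back.n == 3 and back.d == 2
        np.testing.assert_array_equal(back.labels, ds.labels)
        pd.testing.assert_frame_equal(back.features, ds.features)

    def test_arff_nominal_header_echo(self, tmp_path):
        path = tmp_path / "t.arff"
        path.write_text(ARFF_NOMINAL)
        ds = read_table(str(path))
        s = {f.name: f for f in ds.schema}
        assert s["a2"].kind == "nominal"
        assert s["a2"].categories == ("a", "b", "c")
        assert s["a1"].kind == "numeric"
        # 'pos' is the minority category -> positive class
        np.testing.assert_array_equal(ds.labels, [0, 0, 1, 0])

    def test_arff_roundtrip(self, tmp_path):
        ds = make_dataset({"x": [0.125, -3.5, 7.0, 1.0],
                           "c": ["u", "v", "u", "w"]},
                          [0, 0, 1, 1], kinds={"c": "nominal"})
        path = tmp_path / "rt.arff"
        write_table(ds, str(path))
        back = read_table(str(path))
        np.testing.assert_array_equal(back.features["x"], ds.features["x"])
        assert list(back.features["c"]) == list(ds.features["c"])

    @pytest.mark.parametrize("body", [
        "@relation r\n@attribute a relational\n@data\n",
        "@relation r\n@attribute a numeric\n@attribute Class {x,y}\n@data\n{0 1.0}\n",
    ])
    def test_sparse_or_relational_rejected(self, tmp_path, body):
        path = tmp_path / "bad.arff"
        path.write_text(body)
        with pytest.raises(UnsupportedFormatError):
            read_table(str(path))

    def test_missing_values_rejected(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("x,Class\n1.0,neg\n,pos\n")
        with pytest.raises(ValueError, match="missing"):
            read_table(str(path))

    def test_sidecar_declares_kinds_and_label(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("grade,age,outcome\n1,50,neg\n2,60,pos\n1,70,neg\n2,55,neg\n")
        side = tmp_path / "s.yaml"
        side.write_text("label: outcome\ncolumns:\n  grade: nominal\n")
        ds = read_table(str(path), sidecar=str(side))
        kinds = {f.name: f.kind for f in ds.schema}
        assert kinds == {"grade": "nominal", "age": "numeric"}


class TestGenerator:
    def test_imbalance_ratio_matches_clinical_counts(self):
        ds = generate_imbalanced(400, 70, seed=0)
        assert round(ds.imbalance_ratio(), 2) == 5.71
        assert ds.class_counts() == (400, 70)

    def test_deterministic_given_seed(self):
        a = generate_imbalanced(50, 10, d=3, separation=2, seed=42)
        b = generate_imbalanced(50, 10, d=3, separation=2, seed=42)
        pd.testing.assert_frame_equal(a.features, b.features)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_separated_clusters_linearly_separable(self):
        ds = generate_imbalanced(200, 50, d=2, separation=6, seed=3)
        clf = LogisticRegression().fit(ds.features, ds.labels)
        assert clf.score(ds.features, ds.labels) >= 0.99

    def test_discretized_features_get_nominal_schema(self):
        ds = generate_imbalanced(60, 20, d=3, separation=4, seed=0, n_nominal=2)
        kinds = [s.kind for s in ds.schema]
        assert kinds[2] == "numeric" and kinds[0] in ("nominal", "binary")


class TestNoiseInjection:
    def test_zero_rate_is_identity(self):
        ds = generate_imbalanced(30, 10, seed=0)
        noisy, rec = inject_label_noise(ds, 0.0, seed=1)
        assert rec.flipped_indices == ()
        np.testing.assert_array_equal(noisy.labels, ds.labels)

    def test_flip_count_arithmetic(self):
        ds = generate_imbalanced(150, 50, seed=0)
        _, rec = inject_label_noise(ds, 0.1, seed=1)
        assert len(rec.flipped_indices) == 20
        assert len(set(rec.flipped_indices)) == 20

    def test_double_flip_is_involution(self):
        ds = generate_imbalanced(80, 20, seed=0)
        noisy, rec = inject_label_noise(ds, 0.2, seed=5)
        idx = np.array(rec.flipped_indices)
        restored = noisy.labels.copy()
        restored[idx] = 1 - restored[idx]
        np.testing.assert_array_equal(restored, ds.labels)

    def test_only_recorded_indices_change(self):
        ds = generate_imbalanced(80, 20, seed=0)
        noisy, rec = inject_label_noise(ds, 0.15, seed=5)
        changed = np.nonzero(noisy.labels != ds.labels)[0]
        np.testing.assert_array_equal(changed, np.array(rec.flipped_indices))

    def test_dominant_noise_rejected(self):
        ds = generate_imbalanced(30, 10, seed=0)
        with pytest.raises(ValueError):
            inject_label_noise(ds, 0.5, seed=1)


class TestEncoding:
    def test_numeric_minmax_into_unit_interval(self):
        ds = make_dataset({"x": [2.0, 4.0, 6.0], "y": [-1.0, 0.0, 3.0]}, [0, 1, 0])
        enc = encode_features(ds)
        assert enc.d == 2
        v = enc.features.to_numpy()
        assert v.min() >= 0 and v.max() <= 1
        np.testing.assert_allclose(enc.features["x"], [0, 0.5, 1])

    def test_one_hot_expands_three_categories_by_two(self):
        ds = make_dataset({"c": ["a", "b", "c", "a"]}, [0, 0, 1, 1],
                          kinds={"c": "nominal"})
        enc = encode_features(ds)
        assert enc.d == 3
        assert set(enc.features.columns) == {"c=a", "c=b", "c=c"}
        np.testing.assert_array_equal(enc.features.sum(axis=1), np.ones(4))

    def test_constant_numeric_column_maps_to_zero(self):
        ds = make_dataset({"x": [5.0, 5.0, 5.0]}, [0, 1, 0])
        enc = encode_features(ds)
        np.testing.assert_array_equal(enc.features["x"], np.zeros(3))

    def test_binary_maps_to_01(self):
        ds = make_dataset({"b": ["F", "T", "F"]}, [0, 1, 0], kinds={"b": "binary"})
        enc = encode_features(ds)
        np.testing.assert_array_equal(enc.features["b"], [0.0, 1.0, 0.0])

    def test_unseen_category_at_transform_errors(self):
        train = make_dataset({"c": ["a", "b", "a", "b"]}, [0, 1, 0, 1],
                             kinds={"c": "nominal"})
        test = make_dataset({"c": ["a", "z"]}, [0, 1], kinds={"c": "nominal"})
        fe = FeatureEncoder().fit(train)
        with pytest.raises(ValueError, match="unseen"):
            fe.transform(test)

    def test_transform_clips_out_of_range_numerics(self):
        train = make_dataset({"x": [0.0, 10.0]}, [0, 1])
        test = make_dataset({"x": [-5.0, 15.0]}, [0, 1])
        out = FeatureEncoder().fit(train).transform(test)
        np.testing.assert_array_equal(out.features["x"], [0.0, 1.0])


class TestStratifiedSplit:
    def test_proportions_preserved(self):
        ds = generate_imbalanced(400, 70, seed=0)
        train, test = stratified_split(ds, 0.2, seed=1)
        n0, n1 = test.class_counts()
        assert abs(n0 - 80) <= 1 and abs(n1 - 14) <= 1
        assert train.n + test.n == 470

    def test_partition_is_exhaustive_and_disjoint(self):
        ds = generate_imbalanced(40, 20, seed=0)
        train, test = stratified_split(ds, 0.25, seed=3)
        merged = pd.concat([train.features, test.features])
        assert len(merged) == ds.n
        assert len(merged.drop_duplicates()) == ds.n  # gaussian rows are unique

    def test_seeds_change_assignment_not_proportions(self):
        ds = generate_imbalanced(100, 30, seed=0)
        _, t1 = stratified_split(ds, 0.2, seed=1)
        _, t2 = stratified_split(ds, 0.2, seed=2)
        assert t1.class_counts() == t2.class_counts()
        assert not t1.features.equals(t2.features)

    def test_tiny_class_rejected(self):
        ds = make_dataset({"x": [1.0, 2.0, 3.0]}, [0, 0, 1])
        with pytest.raises(ValueError):
            stratified_split(ds, 0.3, seed=0)
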