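"""Normalization, F-score ranking, SVM tuning and the split protocols."""

import numpy as np
import pandas as pd
import pytest
from sklearn.svm import SVC

from myomorph.core import DataError
from myomorph.classify import (
    SplitSpec,
    fscore_rank,
    make_splits,
    normalize,
    predict,
    tune_and_train,
)


def blobs(rng, n=80, d=2, sep=5.0):
    x = np.concatenate([rng.normal(0, 1, (n, d)), rng.normal(sep, 1, (n, d))])
    y = np.array(["a"] * n + ["b"] * n)
    cols = [f"f{i}" for i in range(d)]
    return pd.DataFrame(x, columns=cols), y, tuple(cols)


class TestNormalize:
    def test_train_columns_standardized(self, rng):
        df, _, cols = blobs(rng)
        xn, _, _ = normalize(df, feature_names=cols)
        assert np.allclose(xn.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(xn.std(axis=0), 1.0, atol=1e-9)

    def test_constant_feature_passes_through(self):
        df = pd.DataFrame({"f": [2.0, 2.0, 2.0]})
        xn, _, stats = normalize(df, feature_names=("f",))
        assert stats.scale[0] == 1.0
        assert np.allclose(xn, 0.0)

    def test_test_row_at_training_mean_maps_to_zero(self, rng):
        df, _, cols = blobs(rng)
        mean_row = pd.DataFrame([df.mean()], columns=df.columns)
        _, xt, _ = normalize(df, mean_row, feature_names=cols)
        assert np.allclose(xt, 0.0, atol=1e-9)

    def test_missing_feature_column_named(self, rng):
        df, _, cols = blobs(rng)
        _, _, stats = normalize(df, feature_names=cols)
        with pytest.raises(DataError, match="f1"):
            stats.transform(df[["f0"]])


class TestFscoreRank:
    def test_hand_computed_two_class_value(self):
        df = pd.DataFrame({"f": [0.0, 2.0, 4.0, 6.0]})
        r = fscore_rank(df, ["a", "a", "b", "b"], feature_names=("f",))
        assert r.scores[0] == pytest.approx(2.0)

    def test_identical_distributions_zero_score(self):
        df = pd.DataFrame({"f": [1.0, 2.0, 1.0, 2.0]})
        r = fscore_rank(df, ["a", "a", "b", "b"], feature_names=("f",))
        assert r.scores[0] == 0.0

    def test_row_permutation_invariant(self, rng):
        df, y, cols = blobs(rng, d=4)
        perm = rng.permutation(len(df))
        a = fscore_rank(df, y, feature_names=cols)
        b = fscore_rank(df.iloc[perm].reset_index(drop=True), y[perm], feature_names=cols)
        assert np.allclose(a.scores, b.scores)
        assert a.order == b.order

    def test_single_class_rejected(self):
        df = pd.DataFrame({"f": [1.0, 2.0]})
        with pytest.raises(DataError):
            fscore_rank(df, ["a", "a"], feature_names=("f",))

    def test_perfect_separation_infinite(self):
        df = pd.DataFrame({"f": [0.0, 0.0, 1.0, 1.0]})
        r = fscore_rank(df, ["a", "a", "b", "b"], feature_names=("f",))
        assert np.isinf(r.scores[0])


class TestTuneAndTrain:
    def test_separated_blobs_high_cv_accuracy(self, rng):
        df, y, cols = blobs(rng)
        model = tune_and_train(df, y, feature_names=cols)
        assert model.cv_accuracy >= 0.95

    def test_xor_needs_nonlinear_kernel(self, rng):
        n = 50
        x = np.concatenate(
            [
                rng.normal([0, 0], 0.3, (n, 2)),
                rng.normal([1, 1], 0.3, (n, 2)),
                rng.normal([0, 1], 0.3, (n, 2)),
                rng.normal([1, 0], 0.3, (n, 2)),
            ]
        )
        y = np.array(["a"] * 2 * n + ["b"] * 2 * n)
        df = pd.DataFrame(x, columns=["f0", "f1"])
        model = tune_and_train(df, y, feature_names=("f0", "f1"))
        rbf_acc = (predict(model, df) == y).mean()
        xn, _, _ = normalize(df, feature_names=("f0", "f1"))
        linear_acc = (SVC(kernel="linear").fit(xn, y).predict(xn) == y).mean()
        assert rbf_acc >= 0.9
        assert linear_acc <= 0.7  # symmetry caps a linear rule near chance

    def test_same_data_same_seed_same_hyperparameters(self, rng):
        df, y, cols = blobs(rng, n=40)
        a = tune_and_train(df, y, seed=3, feature_names=cols)
        b = tune_and_train(df, y, seed=3, feature_names=cols)
        assert (a.C, a.gamma) == (b.C, b.gamma)

    def test_training_accuracy_tracks_cv_accuracy(self, rng):
        df, y, cols = blobs(rng)
        model = tune_and_train(df, y, feature_names=cols)
        train_acc = (predict(model, df) == y).mean()
        assert train_acc >= model.cv_accuracy - 0.05

    def test_tiny_class_reduces_folds_with_warning(self, rng):
        df, y, cols = blobs(rng, n=30)
        y = y.copy()
        y[57:] = "c"  # a 3-member class forces fewer folds
        with pytest.warns(UserWarning, match="folds"):
            tune_and_train(df, y, folds=5, feature_names=cols)

    def test_no_information_leak_from_test_rows(self, rng):
        # stats and hyper-parameters must depend on training rows only
        df, y, cols = blobs(rng)
        model_a = tune_and_train(df, y, seed=0, feature_names=cols)
        extra = pd.DataFrame(
            rng.normal(100, 1, (30, 2)), columns=cols
        )  # wild test rows, never shown to training
        model_b = tune_and_train(df, y, seed=0, feature_names=cols)
        predict(model_b, extra)
        assert np.array_equal(model_a.stats.mean, model_b.stats.mean)
        assert (model_a.C, model_a.gamma) == (model_b.C, model_b.gamma)


class TestPredict:
    def test_duplicated_row_identical_labels(self, rng):
        df, y, cols = blobs(rng, n=30)
        model = tune_and_train(df, y, feature_names=cols)
        row = pd.concat([df.iloc[[0]]] * 5, ignore_index=True)
        assert len(set(predict(model, row))) == 1

    def test_labels_subset_of_training_labels(self, rng):
        df, y, cols = blobs(rng, n=30)
        model = tune_and_train(df, y, feature_names=cols)
        out = predict(model, df)
        assert set(out) <= set(y)


class TestMakeSplits:
    def _table(self, n_cases=22, per_case=10):
        rows = []
        classes = ["Normal", "UDH", "LG_DCIS", "HG_DCIS"]
        for i in range(n_cases):
            for j in range(per_case):
                rows.append(
                    {"case_id": f"case{i:02d}", "histotype": classes[i % 4]}
                )
        return pd.DataFrame(rows)

    def test_cell_mode_70_30_sizes(self):
        df = self._table(10, 10)
        splits = make_splits(df, SplitSpec(seed=1))
        for tr, te in splits:
            assert len(tr) == 70 and len(te) == 30
            assert set(tr) & set(te) == set()

    def test_case_mode_ten_distinct_single_case_folds(self):
        df = self._table(22, 5)
        splits = make_splits(
            df, SplitSpec(mode="leave_one_case_out_21_1", repetitions=10, seed=2)
        )
        test_cases = []
        for tr, te in splits:
            cases = set(df["case_id"].iloc[te])
            assert len(cases) == 1
            assert cases.isdisjoint(set(df["case_id"].iloc[tr]) & cases)
            test_cases.append(cases.pop())
        assert len(set(test_cases)) == 10

    def test_same_seed_identical_folds(self):
        df = self._table(8, 12)
        a = make_splits(df, SplitSpec(seed=9))
        b = make_splits(df, SplitSpec(seed=9))
        for (ta, ea), (tb, eb) in zip(a, b):
            assert np.array_equal(ta, tb) and np.array_equal(ea, eb)

    def test_cell_mode_stratified_by_class(self):
        df = self._table(8, 12)
        for tr, te in make_splits(df, SplitSpec(seed=4)):
            frac_tr = (df["histotype"].iloc[tr] == "Normal").mean()
            frac_te = (df["histotype"].iloc[te] == "Normal").mean()
            assert abs(frac_tr - frac_te) < 0.05
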