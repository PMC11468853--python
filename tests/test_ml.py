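import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier

import klsnet.ml as ml
from klsnet.ml import (
    DEFAULT_GRIDS,
    feature_contributions,
    nested_cv,
    permutation_significance,
    roc_curve,
)

SMALL_RF_GRID = [10, 20, 30]


def separable_data(rng, n_per=25, delta=4.0, n_features=5):
    X = np.vstack([
        rng.normal(0.0, 1.0, (n_per, n_features)),
        rng.normal(delta, 1.0, (n_per, n_features)),
    ])
    y = np.r_[np.zeros(n_per), np.ones(n_per)].astype(int)
    return X, y


class TestNestedCv:
    @pytest.mark.parametrize("model,grid", [
        ("lr", None), ("svm", None), ("rf", SMALL_RF_GRID),
    ])
    def test_separable_classes_are_learned(self, rng, model, grid):
        X, y = separable_data(rng)
        res = nested_cv(X, y, model, grid=grid, rng_seed=3)
        assert res.accuracy >= 0.9
        assert res.auc >= 0.9

    @pytest.mark.parametrize("model,grid", [
        ("lr", None), ("svm", None), ("rf", SMALL_RF_GRID),
    ])
    def test_same_seed_is_bit_identical(self, rng, model, grid):
        X, y = separable_data(rng, delta=1.0)
        a = nested_cv(X, y, model, grid=grid, rng_seed=9)
        b = nested_cv(X, y, model, grid=grid, rng_seed=9)
        assert a.accuracy == b.accuracy and a.auc == b.auc
        assert np.array_equal(a.scores, b.scores)
        assert np.array_equal(a.predictions, b.predictions)
        assert np.array_equal(a.contributions, b.contributions)
        assert a.best_params == b.best_params

    def test_confusion_matrix_identities(self, rng):
        X, y = separable_data(rng, delta=1.0)
        res = nested_cv(X, y, "lr", rng_seed=1)
        tn, fp, fn, tp = res.confusion
        assert tn + fp + fn + tp == len(y)
        assert res.sensitivity == pytest.approx(tp / (tp + fn))
        assert res.specificity == pytest.approx(tn / (tn + fp))
        assert res.accuracy == pytest.approx((tp + tn) / len(y))

    def test_scaler_never_sees_test_rows(self, rng, monkeypatch):
        """Record every min-max fit; each must use exactly the outer-training
        rows, even when test rows carry poisoned extreme values."""
        X, y = separable_data(rng, delta=1.0)
        X[::7] += 1e6                       # poison a subset of rows
        fitted_rows = []

        real = ml.MinMaxScaler

        class Recorder(real):
            def fit(self, data, y_=None):
                fitted_rows.append(np.asarray(data).copy())
                return super().fit(data, y_)

        monkeypatch.setattr(ml, "MinMaxScaler", Recorder)
        nested_cv(X, y, "lr", outer_k=10, rng_seed=4)
        assert len(fitted_rows) == 10
        all_rows = {tuple(r) for r in X}
        for fold_data in fitted_rows:
            assert fold_data.shape[0] == len(y) - len(y) // 10
            for row in fold_data:
                assert tuple(row) in all_rows

    def test_single_class_and_bad_shapes_rejected(self, rng):
        X = rng.normal(size=(30, 3))
        with pytest.raises(ValueError):
            nested_cv(X, np.zeros(30, dtype=int), "lr")
        with pytest.raises(ValueError):
            nested_cv(X, np.r_[np.ones(15), np.zeros(15)], "nope")


class TestRfGridShortcut:
    def test_grown_trees_replicate_the_forest_exactly(self, rng):
        """The direct tree-growing path must reproduce
        RandomForestClassifier bit for bit (seeding + bootstrap scheme)."""
        X, y = separable_data(rng, delta=1.0)
        Xv = rng.normal(0.5, 1.0, (20, 5))
        X32 = np.ascontiguousarray(X, dtype=np.float32)
        Xv32 = np.ascontiguousarray(Xv, dtype=np.float32)
        for seed in (7, 12345):
            trees = ml._grow_forest_trees(X32, y, 30, seed)
            proba = np.stack(
                [t.predict_proba(Xv32, check_input=False) for t in trees]
            )
            for k in (10, 30):
                ref = RandomForestClassifier(n_estimators=k,
                                             random_state=seed).fit(X, y)
                assert np.array_equal(proba[:k].mean(axis=0),
                                      ref.predict_proba(Xv))

    def test_prefix_trees_reproduce_small_forests(self, rng):
        """A forest's first k trees equal the k-tree forest for the same
        random state, so prefix scoring of the n_estimators grid is exact."""
        X, y = separable_data(rng, delta=1.0)
        Xv = rng.normal(0.5, 1.0, (20, 5))
        big = RandomForestClassifier(n_estimators=60, random_state=7).fit(X, y)
        proba = np.stack([t.predict_proba(Xv) for t in big.estimators_])
        cum = np.cumsum(proba, axis=0)
        for k in (10, 30, 60):
            small = RandomForestClassifier(n_estimators=k, random_state=7).fit(X, y)
            pred_prefix = big.classes_[np.argmax(cum[k - 1] / k, axis=1)]
            assert np.array_equal(pred_prefix, small.predict(Xv))


class TestPermutationSignificance:
    def test_minimum_attainable_p(self, rng):
        X, y = separable_data(rng)
        with pytest.warns(UserWarning, match="n_perm"):
            p_acc, p_auc = permutation_significance(
                X, y, "lr", n_perm=24, rng_seed=0, outer_k=5, inner_k=3
            )
        assert p_acc == pytest.approx(1 / 25)
        assert p_auc == pytest.approx(1 / 25)

    def test_null_labels_are_not_significant(self, rng):
        X = rng.normal(size=(40, 4))
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        with pytest.warns(UserWarning, match="n_perm"):
            p_acc, _ = permutation_significance(X, y, "lr", n_perm=60,
                                                rng_seed=1, outer_k=5, inner_k=3)
        assert p_acc > 0.05


class TestFeatureContributions:
    def test_top_fraction_arithmetic_and_identical_models(self, rng):
        contrib = rng.normal(size=20)
        results = {}
        for m in ("lr", "svm", "rf"):
            r = ml.CVResult(m, 1, 1, 1, 1, (0, 0, 0, 0))
            r.feature_names = tuple(f"f{i}" for i in range(20))
            r.contributions = contrib
            results[m] = r
        top = feature_contributions(results, top_fraction=0.20)
        assert len(top) == 4                    # ceil(0.2 * 20)
        expected = {f"f{i}" for i in np.argsort(-np.abs(contrib))[:4]}
        assert set(top) == expected

    def test_informative_feature_found_by_all_models(self, rng):
        n = 50
        X = rng.normal(size=(n, 10))
        y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
        X[:, 3] += 4.0 * y                      # single predictive feature
        results = {
            m: nested_cv(X, y, m, grid=(SMALL_RF_GRID if m == "rf" else None),
                         rng_seed=2)
            for m in ("lr", "svm", "rf")
        }
        top = feature_contributions(results, top_fraction=0.20)
        assert "f3" in top

    def test_mismatched_feature_sets_rejected(self):
        a = ml.CVResult("lr", 1, 1, 1, 1, (0, 0, 0, 0))
        a.feature_names, a.contributions = ("x", "y"), np.array([1.0, 2.0])
        b = ml.CVResult("svm", 1, 1, 1, 1, (0, 0, 0, 0))
        b.feature_names, b.contributions = ("x", "z"), np.array([1.0, 2.0])
        with pytest.raises(ValueError):
            feature_contributions({"lr": a, "svm": b})


class TestRoc:
    def test_perfect_scores(self):
        labels = np.array([0, 0, 1, 1])
        _, _, auc = roc_curve(labels.astype(float), labels)
        assert auc == 1.0

    def test_sign_reversal_flips_auc(self, rng):
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        scores = rng.normal(size=200) + 0.8 * labels
        _, _, auc = roc_curve(scores, labels)
        _, _, auc_rev = roc_curve(-scores, labels)
        assert auc_rev == pytest.approx(1 - auc, abs=1e-12)

    def test_uninformative_scores_are_chance_level(self, rng):
        labels = rng.integers(0, 2, 1000)
        _, _, auc = roc_curve(rng.normal(size=1000), labels)
        assert abs(auc - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_monotone_transform_invariance(self, rng):
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        scores = rng.normal(size=100) + labels
        _, _, a1 = roc_curve(scores, labels)
        _, _, a2 = roc_curve(np.exp(scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)
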