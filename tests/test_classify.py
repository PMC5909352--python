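import numpy as np
import pandas as pd
import pytest

from dcemcs import (TreeConfig, NBConfig, ProbPair, train_tree, train_nb,
                    predict_proba, voxel_dynamic_probabilities, cross_validate,
                    DecisionTreeModel, NaiveBayesModel)
from dcemcs.features import DynFeatures


def _table(values, labels, name="x"):
    return pd.DataFrame({name: values, "label": labels})


class TestDecisionTree:
    def test_single_split_with_laplace_leaves(self):
        table = _table([1.0, 2.0, 8.0, 9.0],
                       ["benign", "benign", "malignant", "malignant"])
        model = train_tree(table, TreeConfig())
        assert model.root.feature == "x"
        assert 2.0 < model.root.threshold < 8.0
        left = predict_proba(model, {"x": 1.5})
        assert left.p_benign == pytest.approx(3 / 4)       # (2+1)/(2+2)
        right = predict_proba(model, {"x": 8.5})
        assert right.p_malignant == pytest.approx(3 / 4)

    def test_pure_leaf_of_size_ten(self):
        table = _table([float(i) for i in range(10)] + [20.0, 21.0],
                       ["malignant"] * 10 + ["benign"] * 2)
        model = train_tree(table, TreeConfig())
        assert predict_proba(model, {"x": 3.0}).p_malignant == pytest.approx(11 / 12)

    def test_constant_feature_never_selected(self):
        table = pd.DataFrame({
            "const": np.ones(8),
            "useful": [0, 1, 0, 1, 10, 11, 10, 11],
            "label": ["benign"] * 4 + ["malignant"] * 4})
        model = train_tree(table, TreeConfig())
        def features_used(node, acc):
            if not node.is_leaf:
                acc.add(node.feature)
                features_used(node.left, acc)
                features_used(node.right, acc)
            return acc
        assert features_used(model.root, set()) == {"useful"}

    def test_unpruned_tree_fits_consistent_training_data(self):
        rng = np.random.default_rng(0)
        table = pd.DataFrame({
            "a": rng.normal(size=30), "b": rng.normal(size=30),
            "label": rng.choice(["benign", "malignant"], size=30)})
        if table["label"].nunique() < 2 or table["label"].value_counts().min() < 2:
            pytest.skip("degenerate draw")
        model = train_tree(table, TreeConfig(min_leaf=1))
        preds = [predict_proba(model, row[["a", "b"]].to_dict()).predicted
                 for _, row in table.iterrows()]
        assert (np.array(preds) == table["label"].to_numpy()).all()

    def test_pruning_collapses_isolated_outlier_split(self):
        # 9:2 labels along a noise axis: the unpruned tree isolates the two
        # stray instances; pessimistic pruning should collapse those splits
        table = pd.DataFrame({
            "x": [1.0, 2, 3, 4, 5, 6, 7, 8, 9, 5.5, 6.5],
            "label": ["malignant"] * 9 + ["benign"] * 2})
        def count(node):
            return 1 if node.is_leaf else 1 + count(node.left) + count(node.right)
        full = train_tree(table, TreeConfig(pruned=False, min_leaf=1))
        pruned = train_tree(table, TreeConfig(pruned=True, min_leaf=1))
        assert count(full.root) > 1
        assert count(pruned.root) < count(full.root)

    def test_agrees_with_sklearn_on_separable_data(self):
        from sklearn.tree import DecisionTreeClassifier
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0, 1, 25), rng.normal(10, 1, 25)])
        labels = ["benign"] * 25 + ["malignant"] * 25
        table = _table(x, labels)
        ours = train_tree(table, TreeConfig(min_leaf=1))
        ref = DecisionTreeClassifier(criterion="entropy").fit(x[:, None], labels)
        grid = np.linspace(-3, 13, 101)
        mine = [predict_proba(ours, {"x": g}).predicted for g in grid]
        theirs = ref.predict(grid[:, None])
        assert (np.asarray(mine) == theirs).all()

    def test_json_round_trip(self):
        table = _table([1.0, 2.0, 8.0, 9.0],
                       ["benign", "benign", "malignant", "malignant"])
        model = train_tree(table, TreeConfig())
        back = DecisionTreeModel.from_json(model.to_json())
        for q in (0.5, 5.0, 9.5):
            assert predict_proba(back, {"x": q}) == predict_proba(model, {"x": q})

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="each class"):
            train_tree(_table([1.0, 2.0], ["benign", "benign"]), TreeConfig())


class TestNaiveBayes:
    def test_well_separated_classes(self):
        table = _table([-1.0, 0.0, 1.0, 9.0, 10.0, 11.0],
                       ["benign"] * 3 + ["malignant"] * 3)
        model = train_nb(table, NBConfig())
        assert predict_proba(model, {"x": 0.0}).p_benign > 0.999

    def test_symmetric_midpoint_is_even(self):
        table = _table([-2.0, -1.0, 1.0, 2.0],
                       ["benign", "benign", "malignant", "malignant"])
        model = train_nb(table, NBConfig())
        pair = predict_proba(model, {"x": 0.0})
        assert pair.p_malignant == pytest.approx(0.5, abs=1e-12)

    def test_identical_likelihoods_return_priors(self):
        values = [5.0] * 18 + [5.0] * 2
        table = _table(values, ["malignant"] * 18 + ["benign"] * 2)
        model = train_nb(table, NBConfig())
        pair = predict_proba(model, {"x": 5.0})
        assert pair.p_malignant == pytest.approx(0.9, abs=1e-9)

    def test_matches_sklearn_gaussian_nb(self):
        from sklearn.naive_bayes import GaussianNB
        rng = np.random.default_rng(3)
        X = np.concatenate([rng.normal(0, 1, (30, 2)), rng.normal(3, 2, (30, 2))])
        labels = ["benign"] * 30 + ["malignant"] * 30
        table = pd.DataFrame({"a": X[:, 0], "b": X[:, 1], "label": labels})
        ours = train_nb(table, NBConfig())
        ref = GaussianNB(var_smoothing=1e-12).fit(X, labels)
        queries = rng.normal(1.5, 2, (20, 2))
        mine = ours.predict_proba_matrix(queries)
        theirs = ref.predict_proba(queries)    # columns sorted: benign, malignant
        np.testing.assert_allclose(mine, theirs, atol=1e-9)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(0, 1, 20), rng.normal(4, 1, 20)])
        labels = ["benign"] * 20 + ["malignant"] * 20
        a = train_nb(_table(x, labels), NBConfig())
        b = train_nb(_table(7.0 * x + 3.0, labels), NBConfig())
        for q in (-1.0, 1.7, 5.0):
            pa = predict_proba(a, {"x": q}).p_malignant
            pb = predict_proba(b, {"x": 7.0 * q + 3.0}).p_malignant
            assert pa == pytest.approx(pb, abs=1e-9)

    def test_kernel_estimator_unsupported(self):
        table = _table([1.0, 2.0, 8.0, 9.0],
                       ["benign", "benign", "malignant", "malignant"])
        with pytest.raises(NotImplementedError):
            train_nb(table, NBConfig(kernel_estimator=True))

    def test_json_round_trip(self):
        table = _table([-1.0, 0.0, 1.0, 9.0, 10.0, 11.0],
                       ["benign"] * 3 + ["malignant"] * 3)
        model = train_nb(table, NBConfig())
        back = NaiveBayesModel.from_json(model.to_json())
        assert predict_proba(back, {"x": 4.2}).p_malignant == pytest.approx(
            predict_proba(model, {"x": 4.2}).p_malignant)


class TestProbabilityContract:
    def test_missing_feature_rejected(self):
        table = _table([1.0, 2.0, 8.0, 9.0],
                       ["benign", "benign", "malignant", "malignant"])
        for model in (train_tree(table, TreeConfig()), train_nb(table, NBConfig())):
            with pytest.raises(ValueError, match="missing feature"):
                predict_proba(model, {"y": 1.0})

    def test_prob_pair_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ProbPair(p_malignant=0.7, p_benign=0.4)


class TestVoxelVote:
    def _model(self):
        table = _table([0.0, 1.0, 9.0, 10.0],
                       ["benign", "benign", "malignant", "malignant"])
        return train_nb(table, NBConfig())

    def test_seven_of_ten_vote(self):
        model = self._model()
        dyn = [DynFeatures(sod=0, bs=0, re_slope=0)] * 10
        # feature 'x' lives in sod slot? use explicit features via monkey table
        model = train_nb(pd.DataFrame({
            "sod": [0.0, 1.0, 9.0, 10.0], "bs": [1, 1, 1, 1],
            "re_slope": [0, 0, 0, 0],
            "label": ["benign", "benign", "malignant", "malignant"]}), NBConfig())
        dyn = [DynFeatures(sod=9.5, bs=1.0, re_slope=0.0)] * 7 + \
              [DynFeatures(sod=0.5, bs=1.0, re_slope=0.0)] * 3
        d_m, d_b = voxel_dynamic_probabilities(10, dyn, model)
        assert (d_m, d_b) == (pytest.approx(0.7), pytest.approx(0.3))

    def test_unanimous_vote(self):
        model = train_nb(pd.DataFrame({
            "sod": [0.0, 1.0, 9.0, 10.0], "bs": [1, 1, 1, 1],
            "re_slope": [0, 0, 0, 0],
            "label": ["benign", "benign", "malignant", "malignant"]}), NBConfig())
        dyn = [DynFeatures(sod=9.5, bs=1.0, re_slope=0.0)] * 5
        assert voxel_dynamic_probabilities(5, dyn, model) == (1.0, 0.0)

    def test_fractions_always_sum_to_one(self):
        model = train_nb(pd.DataFrame({
            "sod": [0.0, 1.0, 9.0, 10.0], "bs": [1, 1, 1, 1],
            "re_slope": [0, 0, 0, 0],
            "label": ["benign", "benign", "malignant", "malignant"]}), NBConfig())
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(1, 30))
            dyn = [DynFeatures(sod=float(rng.uniform(-5, 15)), bs=1.0,
                               re_slope=float(rng.normal())) for _ in range(n)]
            d_m, d_b = voxel_dynamic_probabilities(n, dyn, model)
            assert d_m + d_b == pytest.approx(1.0, abs=1e-12)


class TestCrossValidation:
    def _separable(self, n=40):
        x = np.concatenate([np.linspace(0, 1, n // 2), np.linspace(9, 10, n // 2)])
        return _table(x, ["benign"] * (n // 2) + ["malignant"] * (n // 2))

    @pytest.mark.parametrize("kind", ["tree", "nb"])
    def test_separable_table_scores_perfectly(self, kind):
        assert cross_validate(self._separable(), kind, folds=10, seed=0) == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(6)
        n = 100
        x = rng.normal(size=n)
        labels = rng.permutation(["benign", "malignant"] * (n // 2))
        acc = cross_validate(_table(x, list(labels)), "nb", folds=10, seed=1)
        assert 0.3 <= acc <= 0.7

    def test_same_seed_reproduces_estimate(self):
        table = self._separable(30)
        a = cross_validate(table, "tree", folds=5, seed=3)
        b = cross_validate(table, "tree", folds=5, seed=3)
        assert a == b
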