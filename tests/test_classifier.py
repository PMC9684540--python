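"""Gini forest, features, ROC/AUC and fold-dropout evaluation."""

import math

import numpy as np
import pandas as pd
import pytest

from foldsmith.classifier import (
    DEFAULT_REGISTRY,
    ForestConfig,
    LabeledDataset,
    dropout_eval,
    extract_features,
    gini_index,
    roc_auc,
    train_forest,
)
from foldsmith.geometry import torsions_to_coords


class TestGini:
    @pytest.mark.parametrize(
        "probs,want",
        [((1.0,), 0.0), ((0.5, 0.5), 0.5), ((1 / 3, 1 / 3, 1 / 3), 2 / 3)],
    )
    def test_closed_forms(self, probs, want):
        assert abs(gini_index(probs) - want) < 1e-12

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_uniform_maximises_impurity(self, n, rng):
        # brute-force search over random simplex points never beats uniform
        uniform = gini_index([1.0 / n] * n)
        assert abs(uniform - (1.0 - 1.0 / n)) < 1e-12
        for _ in range(500):
            p = rng.dirichlet(np.ones(n))
            assert gini_index(p) <= uniform + 1e-12

    def test_unnormalised_rejected(self):
        with pytest.raises(ValueError):
            gini_index([0.5, 0.4])


class TestFeatures:
    def test_extended_chain(self):
        chain = torsions_to_coords([(180.0, 180.0, 180.0)] * 14, ss="L" * 14)
        feats = extract_features(chain, "A" * 14)
        assert feats["max_contact_degree"] <= 2
        assert feats["buried_hydrophobic_count"] == 0

    def test_bundle_fixture(self, bundle_fixture):
        chain = bundle_fixture.chain
        seq = "L" * len(chain)
        feats = extract_features(chain, seq)
        assert feats["buried_hydrophobic_count"] > 0
        assert feats["mean_contact_degree"] > 2

    def test_helix_fragment_agreement_near_zero(self, ideal_helix12):
        feats = extract_features(ideal_helix12, "A" * 12)
        assert feats["fragment_agreement_rmsd"] < 0.5

    def test_registry_order_irrelevant(self, ideal_helix12):
        seq = "A" * 12
        fwd = extract_features(ideal_helix12, seq, DEFAULT_REGISTRY)
        rev = extract_features(
            ideal_helix12, seq, dict(reversed(list(DEFAULT_REGISTRY.items())))
        )
        for name in DEFAULT_REGISTRY:
            assert fwd[name] == rev[name]

    def test_length_mismatch_rejected(self, ideal_helix12):
        with pytest.raises(ValueError):
            extract_features(ideal_helix12, "AAA")


def make_synthetic_dataset(
    n_per_fold=100,
    folds=("3H", "4H", "ferredoxin", "betagrasp"),
    informative=True,
    seed=0,
    n_features=8,
):
    """Gaussian feature table with a fold-independent stability rule.

    When ``informative``, the label depends on two features through a
    threshold on their sum (the same rule in every fold); otherwise labels
    are fair coin flips independent of everything.
    """
    rng = np.random.default_rng(seed)
    rows, labels, fold_col = [], [], []
    for fi, fold in enumerate(folds):
        X = rng.normal(size=(n_per_fold, n_features))
        X[:, 2] += 0.3 * fi  # mild fold-specific shift on a nuisance feature
        if informative:
            y = (X[:, 0] + X[:, 1] + 0.3 * rng.normal(size=n_per_fold) > 0).astype(int)
        else:
            y = rng.integers(0, 2, size=n_per_fold)
        rows.append(X)
        labels.append(y)
        fold_col.extend([fold] * n_per_fold)
    X = pd.DataFrame(
        np.vstack(rows), columns=[f"f{i}" for i in range(n_features)]
    )
    return LabeledDataset(X=X, y=np.concatenate(labels), folds=np.array(fold_col))


class TestForest:
    def test_separable_data_high_oob(self):
        rng = np.random.default_rng(0)
        X = np.vstack([
            rng.normal(-2.0, 1.0, size=(200, 4)),
            rng.normal(2.0, 1.0, size=(200, 4)),
        ])
        y = np.array([0] * 200 + [1] * 200)
        ds = LabeledDataset(pd.DataFrame(X, columns=list("abcd")), y,
                            np.array(["x"] * 400))
        forest = train_forest(ds, seed=0)
        assert forest.oob_accuracy > 0.95
        assert forest.cv_accuracy > 0.95
        assert len(forest.model.estimators_) == 500

    def test_permuted_labels_are_chance(self):
        ds = make_synthetic_dataset(n_per_fold=100, informative=False, seed=1)
        forest = train_forest(ds, ForestConfig(n_trees=200), seed=0, cv_folds=None)
        assert abs(forest.oob_accuracy - 0.5) < 0.1

    def test_deterministic(self):
        ds = make_synthetic_dataset(n_per_fold=50, seed=2)
        a = train_forest(ds, ForestConfig(n_trees=100), seed=3, cv_folds=None)
        b = train_forest(ds, ForestConfig(n_trees=100), seed=3, cv_folds=None)
        assert np.array_equal(
            a.predict_proba_stable(ds.X), b.predict_proba_stable(ds.X)
        )

    def test_single_class_rejected(self):
        ds = make_synthetic_dataset(n_per_fold=20, seed=0)
        ds.y[:] = 1
        with pytest.raises(ValueError):
            train_forest(LabeledDataset(ds.X, ds.y, ds.folds))


class TestRocAuc:
    def test_perfect_ordering(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert roc_auc([0.5] * 10, [0, 1] * 5) == 0.5

    def test_matches_pairwise_oracle(self, rng):
        scores = rng.normal(size=200)
        scores[::4] = scores[1::4]  # inject ties
        labels = rng.integers(0, 2, size=200)
        if labels.sum() in (0, 200):
            labels[0] = 1 - labels[0]
        wins = 0.0
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        for s_p in pos:
            for s_n in neg:
                wins += 1.0 if s_p > s_n else (0.5 if s_p == s_n else 0.0)
        oracle = wins / (len(pos) * len(neg))
        assert abs(roc_auc(scores, labels) - oracle) < 1e-12

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=100)
        labels = rng.integers(0, 2, size=100)
        labels[0], labels[1] = 0, 1
        a = roc_auc(scores, labels)
        b = roc_auc(np.exp(3.0 * scores), labels)
        assert abs(a - b) < 1e-12

    def test_single_class_sentinel(self):
        assert math.isnan(roc_auc([0.1, 0.9], [1, 1]))


class TestDropout:
    def test_fold_independent_signal_generalises(self):
        ds = make_synthetic_dataset(n_per_fold=100, informative=True, seed=4)
        report = dropout_eval(ds, ForestConfig(n_trees=150), n_repeats=2, seed=0)
        for fold, summary in report.per_fold.items():
            assert summary["min"] > 0.9, (fold, summary)
        assert report.whole_set_auc > 0.9
        assert report.mixed_heldout_auc > 0.9

    def test_uninformative_labels_are_chance(self):
        ds = make_synthetic_dataset(n_per_fold=300, informative=False, seed=5)
        report = dropout_eval(ds, ForestConfig(n_trees=150), n_repeats=2, seed=0)
        for fold, summary in report.per_fold.items():
            assert abs(summary["median"] - 0.5) < 0.12

    def test_degenerate_fold_is_flagged(self):
        ds = make_synthetic_dataset(n_per_fold=40, informative=True, seed=6,
                                    folds=("a", "b"))
        y = ds.y.copy()
        y[ds.folds == "b"] = 1  # single-class fold
        ds2 = LabeledDataset(ds.X, y, ds.folds)
        report = dropout_eval(ds2, ForestConfig(n_trees=50), n_repeats=1, seed=0)
        assert "b" in report.degenerate_folds
        assert math.isnan(report.per_fold["b"]["min"])

    def test_single_fold_rejected(self):
        ds = make_synthetic_dataset(n_per_fold=30, folds=("only",), seed=7)
        with pytest.raises(ValueError):
            dropout_eval(ds)


class TestDatasetCsv:
    def test_roundtrip(self, tmp_path):
        ds = make_synthetic_dataset(n_per_fold=10, seed=8)
        path = tmp_path / "data.csv"
        ds.to_csv(path)
        back = LabeledDataset.from_csv(path)
        assert np.array_equal(back.y, ds.y)
        assert list(back.X.columns) == list(ds.X.columns)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"id": [1], "label": [0], "f0": [0.1]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="fold"):
            LabeledDataset.from_csv(path)
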