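"""Decision-tree training, prediction, reclassification and bagging."""

import json

import numpy as np
import pandas as pd
import pytest

import spheropol as sp
from spheropol.classify import (
    ClassificationRecord,
    EnsembleModel,
    TreeModel,
    feature_importance,
    predict,
    reclassify,
    records_table,
    train_bagged,
    train_secondary_tree,
    train_tree,
)
from spheropol.types import FEATURE_NAMES


def toy_frame(n_per_class=20, noise=0.0, seed=0, classes=(1, 2, 3)):
    """Feature frame whose f1 column alone separates the classes."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    centres = {1: 0.4, 2: -0.4, 3: 0.0}
    for c in classes:
        for i in range(n_per_class):
            row = {name: rng.normal(0, 1) if noise else 0.0 for name in FEATURE_NAMES}
            row["f1_delta_gp58_gp135"] = centres[c] + rng.normal(0, noise)
            row["spheroid_id"] = f"{c}_{i}"
            rows.append(row)
            labels.append(c)
    return pd.DataFrame(rows), labels


class TestTrainTree:
    def test_separable_data_perfect_cv(self):
        frame, labels = toy_frame()
        model = train_tree(frame, labels, folds=10, seed=0)
        assert model.cv_accuracy == 1.0
        assert set(model.classes) == {1, 2, 3}

    def test_splits_only_use_subset_features(self):
        frame, labels = toy_frame(noise=0.05)
        subset = ("f1_delta_gp58_gp135", "f9_nuclear_initial_slope")
        model = train_tree(frame, labels, subset=subset, folds=5, seed=1)
        used = model.nodes.feature[model.nodes.feature >= 0]
        assert np.all(used < len(subset))

    def test_permuted_labels_near_chance(self):
        frame, labels = toy_frame(n_per_class=30, noise=0.05)
        rng = np.random.default_rng(7)
        permuted = rng.permutation(labels).tolist()
        model = train_tree(frame, permuted, folds=10, seed=7)
        # majority share is 1/3 for balanced classes
        assert abs(model.cv_accuracy - 1 / 3) < 0.15

    def test_single_class_and_bad_folds_rejected(self):
        frame, labels = toy_frame(classes=(1,))
        with pytest.raises(ValueError, match="two classes"):
            train_tree(frame, labels, folds=5)
        frame2, labels2 = toy_frame(n_per_class=3)
        with pytest.raises(ValueError, match="folds"):
            train_tree(frame2, labels2, folds=50)

    def test_determinism(self):
        frame, labels = toy_frame(noise=0.1)
        m1 = train_tree(frame, labels, folds=10, seed=3)
        m2 = train_tree(frame, labels, folds=10, seed=3)
        assert m1.to_json() == m2.to_json()


class TestPredict:
    def test_resubstitution_bound(self, small_features):
        feats, labels = small_features
        model = train_tree(feats, labels, folds=4, seed=0)
        records = predict(model, feats)
        train_acc = np.mean([r.predicted == y for r, y in zip(records, labels)])
        assert train_acc >= model.cv_accuracy

    def test_json_roundtrip_preserves_predictions(self):
        frame, labels = toy_frame(noise=0.1)
        model = train_tree(frame, labels, folds=5, seed=2)
        clone = TreeModel.from_json(model.to_json())
        assert np.array_equal(model.predict(frame), clone.predict(frame))

    def test_missing_feature_column_rejected(self):
        frame, labels = toy_frame()
        model = train_tree(frame, labels, folds=5, seed=0)
        with pytest.raises(ValueError, match="missing feature"):
            model.predict(frame.drop(columns=["f9_nuclear_initial_slope"]))

    def test_single_tree_ensemble_equals_tree(self):
        frame, labels = toy_frame(noise=0.1)
        tree = train_tree(frame, labels, folds=5, seed=4)
        ens = EnsembleModel(trees=[tree], classes=tree.classes)
        assert np.array_equal(ens.predict(frame), tree.predict(frame))

    def test_majority_vote_and_tie_break(self):
        frame, labels = toy_frame(noise=0.05)
        tree = train_tree(frame, labels, folds=5, seed=5)
        votes = np.array([[1, 3, 3], [2, 1, 2], [1, 3, 2]])
        from spheropol.classify import _majority_vote

        out = _majority_vote(votes, (1, 2, 3))
        assert out.tolist() == [3, 2, 1]  # last row ties 1/2/3 -> lowest group


class TestReclassify:
    def test_group2_passes_through(self):
        frame, labels = toy_frame(noise=0.05)
        secondary = train_secondary_tree(frame, labels, folds=4, seed=0)
        records = [ClassificationRecord("a", predicted=2)]
        out = reclassify(records, frame.iloc[:1], secondary)
        assert out[0].final == 2 and not out[0].reclassified

    def test_aggregate_mislabelled_as_1_is_flipped(self):
        # secondary subset separates 1 vs 3 through the nuclear slope f9
        rng = np.random.default_rng(0)
        rows, labels = [], []
        for c, f9 in ((1, 0.05), (3, 2.0)):
            for i in range(25):
                row = {name: 0.0 for name in FEATURE_NAMES}
                row["f9_nuclear_initial_slope"] = f9 + rng.normal(0, 0.05)
                row["f13_nuclei_count"] = 14.0
                rows.append(row)
                labels.append(c)
        frame = pd.DataFrame(rows)
        secondary = train_secondary_tree(frame, labels, folds=4, seed=0)
        # an aggregate with strong central nuclear signal, mislabelled 1
        sample = pd.DataFrame([{**{n: 0.0 for n in FEATURE_NAMES},
                                "f9_nuclear_initial_slope": 2.1,
                                "f13_nuclei_count": 14.0}])
        out = reclassify([ClassificationRecord("x", predicted=1)], sample, secondary)
        assert out[0].final == 3 and out[0].reclassified

    def test_agreeing_secondary_changes_nothing(self):
        frame, labels = toy_frame(noise=0.02)
        y = np.asarray(labels)
        keep = np.isin(y, (1, 3))
        sec_frame = frame[keep].reset_index(drop=True).copy()
        sec_frame["f9_nuclear_initial_slope"] = np.where(y[keep] == 3, 2.0, 0.0)
        secondary = train_secondary_tree(sec_frame, y[keep], folds=4, seed=1)
        records = [
            ClassificationRecord(str(i), predicted=int(c))
            for i, c in enumerate(y[keep])
        ]
        out = reclassify(records, sec_frame, secondary)
        assert not any(r.reclassified for r in out)

    def test_wrong_label_set_rejected(self):
        frame, labels = toy_frame(noise=0.05)
        full = train_tree(frame, labels, folds=5, seed=0)
        with pytest.raises(ValueError, match="groups 1 and 3"):
            reclassify([ClassificationRecord("a", 1)], frame.iloc[:1], full)

    def test_records_table_columns(self):
        frame, labels = toy_frame(n_per_class=4)
        model = train_tree(frame, labels, folds=4, seed=0)
        records = predict(model, frame)
        table = records_table(records, frame)
        assert list(table.columns[:4]) == ["spheroid_id", "predicted", "reclassified", "final"]
        assert len(table) == len(frame)


class TestBagged:
    def test_determinism_bit_identical(self):
        frame, labels = toy_frame(noise=0.15)
        e1 = train_bagged(frame, labels, n_trees=10, seed=9)
        e2 = train_bagged(frame, labels, n_trees=10, seed=9)
        assert e1.to_json() == e2.to_json()

    def test_oob_accuracy_reported(self):
        frame, labels = toy_frame(noise=0.1)
        ens = train_bagged(frame, labels, n_trees=15, seed=1)
        assert ens.oob_accuracy is not None
        assert ens.oob_accuracy > 0.8

    def test_json_roundtrip(self):
        frame, labels = toy_frame(noise=0.1)
        ens = train_bagged(frame, labels, n_trees=5, seed=2)
        clone = EnsembleModel.from_json(ens.to_json())
        assert np.array_equal(ens.predict(frame), clone.predict(frame))


class TestFeatureImportance:
    def test_single_informative_feature_ranks_first(self):
        frame, labels = toy_frame(n_per_class=30, noise=0.05)
        ranked = feature_importance(frame, labels, n_trees=20, seed=0)
        assert ranked[0][0] == "f1_delta_gp58_gp135"
        assert ranked[0][1] > 0.5

    def test_pure_noise_importances_spread(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(
            rng.normal(size=(120, len(FEATURE_NAMES))), columns=FEATURE_NAMES
        )
        labels = rng.integers(1, 4, 120).tolist()
        ranked = feature_importance(frame, labels, n_trees=20, seed=1)
        assert ranked[0][1] < 3 / 15

    def test_scores_sum_to_one(self):
        frame, labels = toy_frame(noise=0.1)
        ranked = feature_importance(frame, labels, n_trees=10, seed=2)
        assert sum(s for _, s in ranked) == pytest.approx(1.0)
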