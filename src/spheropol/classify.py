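"""Decision-tree classification of spheroid polarity from the 15 features.

A "complex" (unpruned, minimum leaf size 3) CART tree is trained on a
feature subset — by default features 1, 2 and 6-15 — with stratified 20-fold
cross-validation reporting the held-out accuracy.  Because a single tree
tends to confuse regular spheroids (group 1) with aggregates (group 3), a
second tree trained only on groups 1 and 3 over the lumen/nuclei
descriptors can re-examine those calls (reclassification).  A bagged
ensemble with majority voting (ties broken toward the lower group number)
is available for datasets with more batch-to-batch variation.

Tree growing, cross-validation and bootstrap machinery are delegated to
scikit-learn; serialized models are self-describing JSON documents whose
predictions are reproduced by an in-package traversal of the stored node
arrays (no pickle involved).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .types import DEFAULT_SECONDARY_SUBSET, DEFAULT_TREE_SUBSET, FEATURE_NAMES, FeatureVector

MIN_LEAF_SIZE = 3


def _as_frame(features: Union[pd.DataFrame, Sequence[FeatureVector]]) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        return features
    return pd.DataFrame([f.as_dict() for f in features])


def _matrix(frame: pd.DataFrame, subset: Sequence[str]) -> np.ndarray:
    missing = [f for f in subset if f not in frame.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    return frame[list(subset)].to_numpy(dtype=float)


@dataclass
class _TreeNodes:
    """Exported CART structure: arrays indexed by node id."""

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray  # index into the feature subset; -2 at leaves
    threshold: np.ndarray
    value: np.ndarray  # (n_nodes, n_classes) class distribution, rows sum to 1

    @classmethod
    def from_sklearn(cls, clf: DecisionTreeClassifier) -> "_TreeNodes":
        t = clf.tree_
        value = t.value[:, 0, :]
        value = value / value.sum(axis=1, keepdims=True)
        return cls(
            children_left=t.children_left.copy(),
            children_right=t.children_right.copy(),
            feature=t.feature.copy(),
            threshold=t.threshold.copy(),
            value=value,
        )

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        out = np.empty((X.shape[0], self.value.shape[1]))
        for i, row in enumerate(X):
            node = 0
            while self.children_left[node] != -1:
                if row[self.feature[node]] <= self.threshold[node]:
                    node = self.children_left[node]
                else:
                    node = self.children_right[node]
            out[i] = self.value[node]
        return out

    def to_dict(self) -> dict:
        return {
            "children_left": self.children_left.tolist(),
            "children_right": self.children_right.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "value": self.value.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_TreeNodes":
        return cls(
            children_left=np.asarray(d["children_left"], dtype=int),
            children_right=np.asarray(d["children_right"], dtype=int),
            feature=np.asarray(d["feature"], dtype=int),
            threshold=np.asarray(d["threshold"], dtype=float),
            value=np.asarray(d["value"], dtype=float),
        )


@dataclass
class TreeModel:
    """A fitted polarity decision tree over a named feature subset."""

    nodes: _TreeNodes
    classes: Tuple[int, ...]
    feature_subset: Tuple[str, ...]
    cv_folds: int
    cv_accuracy: float
    training_seed: int

    def predict(self, features: Union[pd.DataFrame, Sequence[FeatureVector]]) -> np.ndarray:
        X = _matrix(_as_frame(features), self.feature_subset)
        proba = self.nodes.predict_proba(X)
        return np.asarray(self.classes)[np.argmax(proba, axis=1)]

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_type": "polarity_decision_tree",
                "classes": list(self.classes),
                "feature_subset": list(self.feature_subset),
                "cv_folds": self.cv_folds,
                "cv_accuracy": self.cv_accuracy,
                "training_seed": self.training_seed,
                "nodes": self.nodes.to_dict(),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "TreeModel":
        d = json.loads(text)
        return cls(
            nodes=_TreeNodes.from_dict(d["nodes"]),
            classes=tuple(d["classes"]),
            feature_subset=tuple(d["feature_subset"]),
            cv_folds=d["cv_folds"],
            cv_accuracy=d["cv_accuracy"],
            training_seed=d["training_seed"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "TreeModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass
class EnsembleModel:
    """Bagged decision trees with majority voting.

    Ties are broken toward the lower group number, the conservative choice
    for the dominant regular-polarity class.
    """

    trees: List[TreeModel]
    classes: Tuple[int, ...]
    oob_accuracy: Optional[float] = None
    training_seed: int = 0

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def predict(self, features: Union[pd.DataFrame, Sequence[FeatureVector]]) -> np.ndarray:
        frame = _as_frame(features)
        votes = np.stack([t.predict(frame) for t in self.trees], axis=1)
        return _majority_vote(votes, self.classes)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_type": "polarity_bagged_trees",
                "classes": list(self.classes),
                "oob_accuracy": self.oob_accuracy,
                "training_seed": self.training_seed,
                "trees": [json.loads(t.to_json()) for t in self.trees],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "EnsembleModel":
        d = json.loads(text)
        trees = [TreeModel.from_json(json.dumps(t)) for t in d["trees"]]
        return cls(
            trees=trees,
            classes=tuple(d["classes"]),
            oob_accuracy=d["oob_accuracy"],
            training_seed=d["training_seed"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "EnsembleModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _majority_vote(votes: np.ndarray, classes: Sequence[int]) -> np.ndarray:
    """Row-wise majority over ``votes``; ties go to the lowest class label."""
    ordered = np.sort(np.asarray(classes))
    counts = np.stack([(votes == c).sum(axis=1) for c in ordered], axis=1)
    return ordered[np.argmax(counts, axis=1)]  # argmax takes the first (lowest) tie


@dataclass
class ClassificationRecord:
    """One spheroid's classification outcome, including reclassification."""

    spheroid_id: str
    predicted: int
    reclassified: bool = False
    final: int = 0

    def __post_init__(self) -> None:
        if self.final == 0:
            self.final = self.predicted
        if not self.reclassified and self.final != self.predicted:
            raise ValueError("final may differ from predicted only when reclassified")


def _check_training_inputs(y: np.ndarray, folds: int) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data must contain at least two classes")
    if folds > len(y):
        raise ValueError(f"folds={folds} exceeds the {len(y)} available samples")
    if folds < 2:
        raise ValueError("folds must be >= 2")


def _fit_sklearn_tree(X, y, seed, min_leaf=MIN_LEAF_SIZE) -> DecisionTreeClassifier:
    clf = DecisionTreeClassifier(
        criterion="gini", min_samples_leaf=min_leaf, random_state=seed
    )
    clf.fit(X, y)
    return clf


def train_tree(
    features: Union[pd.DataFrame, Sequence[FeatureVector]],
    labels: Sequence[int],
    subset: Sequence[str] = DEFAULT_TREE_SUBSET,
    folds: int = 20,
    seed: int = 0,
    min_leaf_size: Optional[int] = None,
    tune: bool = False,
) -> TreeModel:
    """Train a complex decision tree with stratified k-fold cross-validation.

    ``cv_accuracy`` is the mean held-out accuracy over the stratified folds;
    the returned model is refit on all samples.  With ``tune=True`` a small
    grid over minimum leaf sizes {1, 3, 5} is selected by the same CV.
    """
    frame = _as_frame(features)
    X = _matrix(frame, subset)
    y = np.asarray(labels, dtype=int)
    if len(X) != len(y):
        raise ValueError("features and labels must align")
    _check_training_inputs(y, folds)

    candidates = [min_leaf_size or MIN_LEAF_SIZE] if not tune else [1, 3, 5]
    best: Tuple[float, int] = (-1.0, candidates[0])
    for leaf in candidates:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        accs = []
        for tr, te in skf.split(X, y):
            clf = _fit_sklearn_tree(X[tr], y[tr], seed, min_leaf=leaf)
            accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
        cv_acc = float(np.mean(accs))
        if cv_acc > best[0]:
            best = (cv_acc, leaf)

    cv_accuracy, leaf = best
    clf = _fit_sklearn_tree(X, y, seed, min_leaf=leaf)
    return TreeModel(
        nodes=_TreeNodes.from_sklearn(clf),
        classes=tuple(int(c) for c in clf.classes_),
        feature_subset=tuple(subset),
        cv_folds=folds,
        cv_accuracy=cv_accuracy,
        training_seed=seed,
    )


def train_bagged(
    features: Union[pd.DataFrame, Sequence[FeatureVector]],
    labels: Sequence[int],
    n_trees: int = 30,
    subset: Sequence[str] = DEFAULT_TREE_SUBSET,
    seed: int = 0,
) -> EnsembleModel:
    """Train a bagged-tree ensemble on bootstrap resamples (seeded).

    Out-of-bag accuracy is reported when every sample is left out by at
    least one tree; otherwise it is computed over the covered samples.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    frame = _as_frame(features)
    X = _matrix(frame, subset)
    y = np.asarray(labels, dtype=int)
    _check_training_inputs(y, folds=2)

    n = len(y)
    classes = tuple(int(c) for c in np.unique(y))
    rng = np.random.default_rng(seed)
    trees: List[TreeModel] = []
    oob_votes: List[List[int]] = [[] for _ in range(n)]
    for i in range(n_trees):
        idx = rng.integers(0, n, size=n)
        clf = _fit_sklearn_tree(X[idx], y[idx], seed + i)
        tree = TreeModel(
            nodes=_TreeNodes.from_sklearn(clf),
            classes=tuple(int(c) for c in clf.classes_),
            feature_subset=tuple(subset),
            cv_folds=0,
            cv_accuracy=float("nan"),
            training_seed=seed + i,
        )
        trees.append(tree)
        out_of_bag = np.setdiff1d(np.arange(n), idx)
        if out_of_bag.size:
            preds = tree.predict(frame.iloc[out_of_bag])
            for j, p in zip(out_of_bag, preds):
                oob_votes[j].append(int(p))

    covered = [j for j in range(n) if oob_votes[j]]
    oob_accuracy = None
    if covered:
        votes = [
            _majority_vote(np.asarray([oob_votes[j]]), classes)[0] for j in covered
        ]
        oob_accuracy = float(np.mean(np.asarray(votes) == y[covered]))
    return EnsembleModel(
        trees=trees, classes=classes, oob_accuracy=oob_accuracy, training_seed=seed
    )


def predict(
    model: Union[TreeModel, EnsembleModel],
    features: Union[pd.DataFrame, Sequence[FeatureVector]],
) -> List[ClassificationRecord]:
    """Classify spheroids; one record per row, in input order."""
    frame = _as_frame(features)
    ids = (
        frame["spheroid_id"].astype(str).tolist()
        if "spheroid_id" in frame.columns
        else [str(i) for i in range(len(frame))]
    )
    preds = model.predict(frame)
    return [
        ClassificationRecord(spheroid_id=sid, predicted=int(p))
        for sid, p in zip(ids, preds)
    ]


def train_secondary_tree(
    features: Union[pd.DataFrame, Sequence[FeatureVector]],
    labels: Sequence[int],
    subset: Sequence[str] = DEFAULT_SECONDARY_SUBSET,
    folds: int = 5,
    seed: int = 0,
) -> TreeModel:
    """Train the group-1-vs-group-3 reclassification tree.

    Only group-1 and group-3 samples are used; the default subset holds the
    lumen/nuclei descriptors with the best 1-vs-3 discriminative power.
    """
    frame = _as_frame(features)
    y = np.asarray(labels, dtype=int)
    keep = np.isin(y, (1, 3))
    if keep.sum() < folds:
        raise ValueError("not enough group-1/group-3 samples for the secondary tree")
    return train_tree(
        frame[keep].reset_index(drop=True), y[keep], subset=subset, folds=folds, seed=seed
    )


def reclassify(
    records: Sequence[ClassificationRecord],
    features: Union[pd.DataFrame, Sequence[FeatureVector]],
    secondary: TreeModel,
) -> List[ClassificationRecord]:
    """Re-examine group-1/group-3 calls with the secondary tree.

    Group-2 records pass through untouched; for the rest the secondary
    tree's verdict replaces the primary one, and ``reclassified`` flags the
    records whose label changed.
    """
    if set(secondary.classes) != {1, 3}:
        raise ValueError(
            f"secondary model must be trained on groups 1 and 3 only; "
            f"got classes {secondary.classes}"
        )
    frame = _as_frame(features)
    if len(frame) != len(records):
        raise ValueError("records and features must align")
    out: List[ClassificationRecord] = []
    idx_13 = [i for i, r in enumerate(records) if r.predicted in (1, 3)]
    new_labels = (
        secondary.predict(frame.iloc[idx_13]) if idx_13 else np.empty(0, dtype=int)
    )
    relabel = dict(zip(idx_13, new_labels))
    for i, r in enumerate(records):
        if i in relabel:
            final = int(relabel[i])
            out.append(
                ClassificationRecord(
                    spheroid_id=r.spheroid_id,
                    predicted=r.predicted,
                    reclassified=final != r.predicted,
                    final=final,
                )
            )
        else:
            out.append(
                ClassificationRecord(
                    spheroid_id=r.spheroid_id, predicted=r.predicted
                )
            )
    return out


def records_table(
    records: Sequence[ClassificationRecord],
    features: Optional[Union[pd.DataFrame, Sequence[FeatureVector]]] = None,
) -> pd.DataFrame:
    """Results table: id, predicted, reclassified, final (+ features)."""
    df = pd.DataFrame(
        {
            "spheroid_id": [r.spheroid_id for r in records],
            "predicted": [r.predicted for r in records],
            "reclassified": [r.reclassified for r in records],
            "final": [r.final for r in records],
        }
    )
    if features is not None:
        feat = _as_frame(features).reset_index(drop=True)
        feat = feat.drop(columns=[c for c in ("spheroid_id",) if c in feat.columns])
        df = pd.concat([df, feat], axis=1)
    return df


def feature_importance(
    features: Union[pd.DataFrame, Sequence[FeatureVector]],
    labels: Sequence[int],
    subset: Sequence[str] = FEATURE_NAMES,
    n_trees: int = 50,
    seed: int = 0,
) -> List[Tuple[str, float]]:
    """Impurity-decrease importance per feature over a bagged ensemble.

    Scores are normalised to sum to 1 and returned in descending order,
    ties broken alphabetically; they guide the choice of the training
    subset.
    """
    frame = _as_frame(features)
    X = _matrix(frame, subset)
    y = np.asarray(labels, dtype=int)
    _check_training_inputs(y, folds=2)
    rng = np.random.default_rng(seed)
    n = len(y)
    total = np.zeros(len(subset))
    for i in range(n_trees):
        idx = rng.integers(0, n, size=n)
        clf = _fit_sklearn_tree(X[idx], y[idx], seed + i)
        total += clf.feature_importances_
    s = total.sum()
    scores = total / s if s > 0 else np.full(len(subset), 1.0 / len(subset))
    ranked = sorted(zip(subset, scores), key=lambda kv: (-kv[1], kv[0]))
    return [(name, float(score)) for name, score in ranked]
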