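"""Local-per-node hierarchical classification with linear SVMs.

A binary classifier is trained for every node of the class hierarchy; the
training set for a node depends on the *policy*:

``inclusive``
    Positives are every point whose label falls in the node's subtree;
    negatives are every other labelled point in the dataset.
``sibling``
    Same positives, but negatives are restricted to points under the node's
    *parent* that are outside the node's subtree — the look-alike classes.
    Sibling sets are always subsets of inclusive sets, so sibling training
    is faster but pits the classifier against its hardest confusers (for a
    kelp node these are the other macroalgae, e.g. *Scytothalia*-like taxa).
``flat``
    Ignores the hierarchy: one multi-class one-vs-all SVM over all leaf
    labels.

All SVMs are linear, with the regularisation constant C selected by
stratified k-fold cross-validation (3 folds by default) on mean fold
accuracy, ties broken toward the smallest C, then refit on the full
training data.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .annotations import AnnotationTable, HierarchyTree
from .errors import (
    CompatibilityError,
    ConfigurationError,
    PolicyError,
    StratificationError,
    TrainingError,
)
from .features import FeatureMatrix

__all__ = [
    "TrainingPolicy",
    "TrainConfig",
    "NodeModel",
    "FlatModel",
    "HierModel",
    "PredictionRecord",
    "build_node_training_set",
    "train_linear_svm",
    "train_hierarchical",
    "train_flat",
    "predict_node",
    "predict_flat",
    "predict_hierarchical",
    "evaluation_mask",
    "save_model",
    "load_model",
]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class TrainingPolicy:
    """Which training-set policy to apply, and (for binary policies) where."""

    kind: str
    target_node: str | None = None

    def __post_init__(self):
        if self.kind not in ("flat", "inclusive", "sibling"):
            raise ConfigurationError(f"unknown policy kind {self.kind!r}")
        if self.kind == "flat" and self.target_node is not None:
            raise ConfigurationError("flat policy takes no target node")
        if self.kind != "flat" and self.target_node is None:
            raise ConfigurationError(f"{self.kind} policy requires a target node")


@dataclass(frozen=True)
class TrainConfig:
    """SVM training configuration.

    ``C_grid`` is the regularisation grid searched by ``n_folds``-fold
    stratified cross-validation; ``class_weighting='balanced'`` reweights
    classes inversely to frequency (off by default).
    """

    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    n_folds: int = 3
    seed: int = 0
    class_weighting: str = "none"
    max_iter: int = 5000

    def __post_init__(self):
        if self.n_folds < 2:
            raise ConfigurationError("n_folds must be at least 2")
        if not self.C_grid or any(c <= 0 for c in self.C_grid):
            raise ConfigurationError("C_grid must be non-empty and positive")
        if self.class_weighting not in ("none", "balanced"):
            raise ConfigurationError(f"unknown class_weighting {self.class_weighting!r}")


@dataclass
class NodeModel:
    """Fitted one-vs-all linear SVM for one hierarchy node (or flat head).

    ``coef`` has one row per class in ``classes_`` order (a single row for
    binary problems, per liblinear convention); decision scores are
    ``X @ coef.T + intercept``.
    """

    node_id: str
    policy_kind: str
    classes_: list
    coef: np.ndarray
    intercept: np.ndarray
    best_C: float
    fold_scores: dict[float, list[float]]
    extractor_id: str
    n_pos: int = 0
    n_neg: int = 0

    @property
    def dim(self) -> int:
        return self.coef.shape[1]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        scores = X @ self.coef.T + self.intercept
        return scores


FlatModel = NodeModel  # a flat model is a one-vs-all head over leaf labels


@dataclass
class HierModel:
    """Per-node binary classifiers plus the hierarchy and policy used."""

    tree: HierarchyTree
    node_models: dict[str, NodeModel]
    policy_kind: str
    config: TrainConfig
    extractor_id: str
    skipped: dict[str, str] = field(default_factory=dict)


@dataclass
class PredictionRecord:
    """Prediction for one feature row.

    Flat predictions carry a single ``label``; hierarchical predictions
    carry the root-to-node ``node_path`` actually accepted, plus per-node
    decision scores.
    """

    index: int
    label: str | None = None
    node_path: tuple[str, ...] = ()
    node_scores: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Training-set construction
# ---------------------------------------------------------------------------

def build_node_training_set(
    table: AnnotationTable,
    tree: HierarchyTree,
    policy: TrainingPolicy,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Row indices and binary labels for one node under a binary policy.

    Returns ``(indices, y, info)`` where ``y[i] == 1`` marks a positive
    (label inside the target subtree) and ``info`` reports how many rows
    carried labels absent from the hierarchy (excluded with a warning count
    rather than silently dropped).
    """
    if policy.kind == "flat":
        raise PolicyError("flat policy has no per-node training set")
    target = policy.target_node
    if target == tree.root_id:
        raise PolicyError("cannot train a binary node at the root: no negatives exist")
    pos_labels = tree.subtree_labels(target)
    all_labels = tree.all_labels()
    labels = table.labels
    assigned = np.isin(labels, list(all_labels))
    positive = np.isin(labels, list(pos_labels))
    if policy.kind == "inclusive":
        negative = assigned & ~positive
    else:  # sibling
        parent = tree.parent(target)
        sib_labels = tree.subtree_labels(parent) - pos_labels
        negative = np.isin(labels, list(sib_labels))
    keep = positive | negative
    indices = np.flatnonzero(keep)
    y = positive[indices].astype(np.int64)
    info = {
        "n_pos": int(y.sum()),
        "n_neg": int(len(y) - y.sum()),
        "n_unassigned": int((~assigned).sum()),
    }
    return indices, y, info


def evaluation_mask(
    table: AnnotationTable,
    tree: HierarchyTree,
    policy_kind: str,
    target_node: str,
) -> np.ndarray:
    """Which test rows a node-level evaluation scores.

    Inclusive models are scored on every test row; sibling models on the
    rows whose true label lies in the parent's subtree (the population the
    classifier was trained to discriminate within).
    """
    labels = table.labels
    if policy_kind == "inclusive":
        return np.isin(labels, list(tree.all_labels()))
    if policy_kind == "sibling":
        parent = tree.parent(target_node)
        return np.isin(labels, list(tree.subtree_labels(parent)))
    raise PolicyError(f"no node-level evaluation population for {policy_kind!r}")


# ---------------------------------------------------------------------------
# SVM training
# ---------------------------------------------------------------------------

def _fit_svc(X, y, C, cfg: TrainConfig) -> LinearSVC:
    clf = LinearSVC(
        C=C,
        class_weight=None if cfg.class_weighting == "none" else "balanced",
        max_iter=cfg.max_iter,
        random_state=cfg.seed,
    )
    clf.fit(X, y)
    return clf


def train_linear_svm(
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig | None = None,
    *,
    node_id: str = "",
    policy_kind: str = "",
    extractor_id: str = "",
) -> NodeModel:
    """Cross-validated linear SVM (binary or one-vs-all multi-class).

    Mean accuracy over stratified ``cfg.n_folds`` folds is recorded for
    every C in the grid; the model is refit on all data at the best C, ties
    broken toward the smallest C. Deterministic given (data, config).
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise TrainingError(f"need at least 2 classes, got {classes.tolist()}")
    small = classes[counts < cfg.n_folds]
    if len(small):
        raise StratificationError(
            f"classes with fewer than {cfg.n_folds} samples: {small.tolist()}"
        )
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    folds = list(skf.split(X, y))
    fold_scores: dict[float, list[float]] = {}
    for C in cfg.C_grid:
        scores = []
        for tr, te in folds:
            clf = _fit_svc(X[tr], y[tr], C, cfg)
            scores.append(float(np.mean(clf.predict(X[te]) == y[te])))
        fold_scores[float(C)] = scores
    means = {C: float(np.mean(s)) for C, s in fold_scores.items()}
    # ties toward the smallest C: iterate the grid in ascending order
    best_C = min(sorted(means), key=lambda C: (-means[C], C))
    clf = _fit_svc(X, y, best_C, cfg)
    n_pos = int(counts[-1]) if set(classes.tolist()) == {0, 1} else 0
    n_neg = int(counts[0]) if set(classes.tolist()) == {0, 1} else 0
    return NodeModel(
        node_id=node_id,
        policy_kind=policy_kind,
        classes_=clf.classes_.tolist(),
        coef=np.atleast_2d(clf.coef_.copy()),
        intercept=np.atleast_1d(clf.intercept_.copy()),
        best_C=float(best_C),
        fold_scores=fold_scores,
        extractor_id=extractor_id,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def train_hierarchical(
    table: AnnotationTable,
    features: FeatureMatrix,
    tree: HierarchyTree,
    policy_kind: str,
    cfg: TrainConfig | None = None,
) -> HierModel:
    """Train one binary classifier per non-root hierarchy node.

    Nodes whose training set lacks a class, or whose smaller class has
    fewer samples than the fold count, are skipped and listed in
    ``HierModel.skipped`` with the reason.
    """
    cfg = cfg or TrainConfig()
    if policy_kind not in ("inclusive", "sibling"):
        raise ConfigurationError(f"hierarchical policy must be inclusive/sibling, got {policy_kind!r}")
    if features.n != len(table):
        raise CompatibilityError(
            f"feature rows ({features.n}) != annotation rows ({len(table)})"
        )
    node_models: dict[str, NodeModel] = {}
    skipped: dict[str, str] = {}
    for node_id in tree.iter_nonroot():
        policy = TrainingPolicy(policy_kind, node_id)
        idx, y, info = build_node_training_set(table, tree, policy)
        if info["n_pos"] == 0 or info["n_neg"] == 0:
            skipped[node_id] = (
                f"insufficient data: {info['n_pos']} positives, {info['n_neg']} negatives"
            )
            continue
        try:
            node_models[node_id] = train_linear_svm(
                features.rows(idx), y, cfg,
                node_id=node_id, policy_kind=policy_kind,
                extractor_id=features.extractor_id,
            )
        except TrainingError as exc:
            skipped[node_id] = str(exc)
    return HierModel(
        tree=tree,
        node_models=node_models,
        policy_kind=policy_kind,
        config=cfg,
        extractor_id=features.extractor_id,
        skipped=skipped,
    )


def train_flat(
    table: AnnotationTable,
    features: FeatureMatrix,
    cfg: TrainConfig | None = None,
) -> FlatModel:
    """One-vs-all linear SVM over all leaf labels, hierarchy ignored.

    Prediction is the argmax decision score; exact ties resolve to the
    lexicographically first label (classes are kept sorted).
    """
    if features.n != len(table):
        raise CompatibilityError(
            f"feature rows ({features.n}) != annotation rows ({len(table)})"
        )
    return train_linear_svm(
        features.values, table.labels, cfg,
        node_id="__flat__", policy_kind="flat",
        extractor_id=features.extractor_id,
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def _check_features(model: NodeModel, X: np.ndarray, extractor_id: str | None) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.dim:
        raise CompatibilityError(
            f"feature dim {X.shape[1] if X.ndim == 2 else '?'} != model dim {model.dim}"
        )
    if extractor_id is not None and model.extractor_id and extractor_id != model.extractor_id:
        raise CompatibilityError(
            f"features from {extractor_id!r}, model trained on {model.extractor_id!r}"
        )
    return X


def predict_node(
    model: NodeModel, X: np.ndarray, extractor_id: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Binary node prediction: positive iff decision score >= 0.

    A score of exactly 0 counts as positive (documented tie rule). Returns
    ``(labels01, scores)``.
    """
    X = _check_features(model, X, extractor_id)
    if X.shape[0] == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    scores = model.decision_scores(X)[:, 0]
    return (scores >= 0.0).astype(np.int64), scores


def predict_flat(
    model: FlatModel, X: np.ndarray, extractor_id: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Flat multi-class prediction: argmax score, ties to first label."""
    X = _check_features(model, X, extractor_id)
    if X.shape[0] == 0:
        return np.empty(0, dtype=object), np.empty((0, len(model.classes_)))
    scores = model.decision_scores(X)
    labels = np.asarray(model.classes_, dtype=object)[np.argmax(scores, axis=1)]
    return labels, scores


def predict_hierarchical(
    hm: HierModel,
    X: np.ndarray,
    mode: str = "top_down",
    target_node: str | None = None,
    extractor_id: str | None = None,
) -> list[PredictionRecord]:
    """Hierarchical prediction over feature rows.

    ``node_only`` applies a single target node's binary classifier to every
    row (the node-level evaluation mode); the record's path is the node's
    root path when accepted, its parent's path when rejected.

    ``top_down`` descends from the root: at each level the child classifiers
    are evaluated and the highest-scoring *accepting* child (score >= 0) is
    followed; descent stops at the deepest accepting node, or at the last
    modelled ancestor when an intermediate node has no model. Predictions
    are therefore hierarchy-consistent: every ancestor of the predicted
    node accepted the sample.
    """
    X = np.asarray(X, dtype=np.float64)
    if extractor_id is not None and extractor_id != hm.extractor_id:
        raise CompatibilityError(
            f"features from {extractor_id!r}, model trained on {hm.extractor_id!r}"
        )

    def root_path(node_id: str) -> tuple[str, ...]:
        path = []
        cur: str | None = node_id
        while cur is not None:
            path.append(cur)
            cur = hm.tree.parent(cur)
        return tuple(reversed(path))

    if mode == "node_only":
        if target_node is None:
            raise ConfigurationError("node_only mode requires target_node")
        model = hm.node_models[target_node]
        y01, scores = predict_node(model, X)
        accepted_path = root_path(target_node)
        rejected_path = accepted_path[:-1]
        return [
            PredictionRecord(
                index=i,
                node_path=accepted_path if y01[i] else rejected_path,
                node_scores={target_node: float(scores[i])},
            )
            for i in range(X.shape[0])
        ]

    if mode != "top_down":
        raise ConfigurationError(f"unknown prediction mode {mode!r}")

    # Vectorised per-node scores, then a per-row descent.
    scores_by_node = {
        nid: m.decision_scores(X)[:, 0] for nid, m in hm.node_models.items()
    }
    records = []
    for i in range(X.shape[0]):
        path = [hm.tree.root_id]
        node_scores: dict[str, float] = {}
        cur = hm.tree.root_id
        while True:
            modelled = [c for c in hm.tree.node(cur).children if c in scores_by_node]
            if not modelled:
                break
            child_scores = {c: float(scores_by_node[c][i]) for c in modelled}
            node_scores.update(child_scores)
            accepting = [c for c in modelled if child_scores[c] >= 0.0]
            if not accepting:
                break
            cur = max(accepting, key=lambda c: (child_scores[c], c))
            path.append(cur)
        records.append(
            PredictionRecord(index=i, node_path=tuple(path), node_scores=node_scores)
        )
    return records


# ---------------------------------------------------------------------------
# Model persistence: one zip archive, plain arrays + JSON manifest
# ---------------------------------------------------------------------------

def _node_manifest(m: NodeModel) -> dict:
    return {
        "node_id": m.node_id,
        "policy_kind": m.policy_kind,
        "classes": m.classes_,
        "best_C": m.best_C,
        "fold_scores": {str(k): v for k, v in m.fold_scores.items()},
        "extractor_id": m.extractor_id,
        "n_pos": m.n_pos,
        "n_neg": m.n_neg,
    }


def save_model(model: HierModel | FlatModel, path: str | Path) -> None:
    """Write a model to a single zip archive (arrays + JSON manifest)."""
    is_hier = isinstance(model, HierModel)
    with zipfile.ZipFile(path, "w") as zf:
        if is_hier:
            manifest = {
                "kind": "hierarchical",
                "policy_kind": model.policy_kind,
                "extractor_id": model.extractor_id,
                "config": {
                    "C_grid": list(model.config.C_grid),
                    "n_folds": model.config.n_folds,
                    "seed": model.config.seed,
                    "class_weighting": model.config.class_weighting,
                    "max_iter": model.config.max_iter,
                },
                "skipped": model.skipped,
                "nodes": {nid: _node_manifest(m) for nid, m in model.node_models.items()},
            }
            zf.writestr("hierarchy.json", json.dumps(model.tree.to_json(), indent=2))
            arrays = {}
            for nid, m in model.node_models.items():
                arrays[f"coef_{nid}"] = m.coef
                arrays[f"intercept_{nid}"] = m.intercept
        else:
            manifest = {"kind": "flat", "node": _node_manifest(model)}
            arrays = {"coef": model.coef, "intercept": model.intercept}
        zf.writestr("manifest.json", json.dumps(manifest, indent=2))
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        zf.writestr("weights.npz", buf.getvalue())


def _node_from_manifest(d: Mapping, coef: np.ndarray, intercept: np.ndarray) -> NodeModel:
    return NodeModel(
        node_id=d["node_id"],
        policy_kind=d["policy_kind"],
        classes_=d["classes"],
        coef=coef,
        intercept=intercept,
        best_C=d["best_C"],
        fold_scores={float(k): v for k, v in d["fold_scores"].items()},
        extractor_id=d["extractor_id"],
        n_pos=d.get("n_pos", 0),
        n_neg=d.get("n_neg", 0),
    )


def load_model(path: str | Path) -> HierModel | FlatModel:
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        arrays = np.load(io.BytesIO(zf.read("weights.npz")))
        if manifest["kind"] == "flat":
            return _node_from_manifest(manifest["node"], arrays["coef"], arrays["intercept"])
        tree = HierarchyTree.from_json(json.loads(zf.read("hierarchy.json")))
        cfgd = manifest["config"]
        cfg = TrainConfig(
            C_grid=tuple(cfgd["C_grid"]),
            n_folds=cfgd["n_folds"],
            seed=cfgd["seed"],
            class_weighting=cfgd["class_weighting"],
            max_iter=cfgd["max_iter"],
        )
        node_models = {
            nid: _node_from_manifest(d, arrays[f"coef_{nid}"], arrays[f"intercept_{nid}"])
            for nid, d in manifest["nodes"].items()
        }
        return HierModel(
            tree=tree,
            node_models=node_models,
            policy_kind=manifest["policy_kind"],
            config=cfg,
            extractor_id=manifest["extractor_id"],
            skipped=manifest.get("skipped", {}),
        )
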