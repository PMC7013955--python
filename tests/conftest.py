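"""Shared fixtures: toy hierarchy/table, and session-scoped trained pipelines.

The full synthetic-survey pipelines (generation -> enhancement -> patches ->
features -> split -> SVM training) are expensive relative to the rest of the
suite, so they are built once per session and shared by the evaluation,
coverage and acceptance tests.
"""

from __future__ import annotations

import pytest

from kelpcover.annotations import (
    AnnotationTable,
    HierarchyNode,
    HierarchyTree,
    PointAnnotation,
    SplitSpec,
    make_split,
)
from kelpcover.features import ExtractorSpec, FeatureMatrix
from kelpcover.hierclf import TrainConfig, train_flat, train_hierarchical
from kelpcover.pipeline import features_from_images
from kelpcover.synthetic import SurveySpec, iter_survey


@pytest.fixture()
def toy_tree() -> HierarchyTree:
    """Kelp-path hierarchy: macroalgae = {kelp} + {scytothalia, turf}."""
    return HierarchyTree(
        [
            HierarchyNode("1", "benthos"),
            HierarchyNode("1.1", "macroalgae", "1"),
            HierarchyNode("1.1.1", "kelp", "1.1", leaf_labels={"kelp"}),
            HierarchyNode("1.1.2", "other macroalgae", "1.1", leaf_labels={"scytothalia", "turf"}),
            HierarchyNode("1.2", "non-macroalgae", "1", leaf_labels={"coral", "sand"}),
        ]
    )


@pytest.fixture()
def toy_table() -> AnnotationTable:
    """4 kelp, 3 scytothalia, 2 coral, 3 sand points."""
    labels = ["kelp"] * 4 + ["scytothalia"] * 3 + ["coral"] * 2 + ["sand"] * 3
    points = [
        PointAnnotation(f"im{i % 3}", x=i, y=0, label=lab, site="s1", year=2013)
        for i, lab in enumerate(labels)
    ]
    return AnnotationTable.from_points(points)


def random_tree_and_table(rng):
    """Random 3-level hierarchy + table; some table labels are unassigned."""
    n_mid = rng.integers(2, 4)
    nodes = [HierarchyNode("r", "root")]
    labels = []
    for i in range(n_mid):
        mid = f"m{i}"
        nodes.append(HierarchyNode(mid, mid, "r"))
        for j in range(rng.integers(1, 4)):
            leaf = f"m{i}l{j}"
            lab = f"lab_{i}_{j}"
            labels.append(lab)
            nodes.append(HierarchyNode(leaf, leaf, mid, leaf_labels={lab}))
    tree = HierarchyTree(nodes)
    pool = labels + ["stray1", "stray2"]
    points = [
        PointAnnotation("im0", x=k, y=0, label=pool[rng.integers(len(pool))])
        for k in range(rng.integers(10, 40))
    ]
    return tree, AnnotationTable.from_points(points)


def build_survey(spec: SurveySpec):
    """Materialise a survey in memory: (table, images dict, scenes dict)."""
    points, images, scenes = [], {}, {}
    for scene, pts in iter_survey(spec):
        images[scene.image.image_id] = scene.image
        scenes[scene.image.image_id] = scene
        points.extend(pts)
    table = AnnotationTable.from_points(points, provenance=f"synthetic(seed={spec.seed})")
    return table, images, scenes


def split_features(table, features, split_spec):
    """Image-level split of a table together with its aligned features."""
    train_tab, test_tab = make_split(table, split_spec)
    df = table.df
    tr_idx = df.index[df["image_id"].isin(train_tab.df["image_id"])].to_numpy()
    te_idx = df.index[df["image_id"].isin(test_tab.df["image_id"])].to_numpy()
    ftr = FeatureMatrix(features.rows(tr_idx), features.extractor_id)
    fte = FeatureMatrix(features.rows(te_idx), features.extractor_id)
    return (train_tab, ftr), (test_tab, fte)


# Study conditions for the end-to-end recovery checks: a 200-image survey,
# 50 points per image, six classes with the kelp confuser at similarity 0.3.
SIBLING_SURVEY = SurveySpec(
    n_images=200,
    points_per_image=50,
    confuser_similarity=0.3,
    seed=2020,
)
# The long-tail variant adds 20 rare sprinkle classes for flat training.
FLAT_SURVEY = SurveySpec(
    n_images=200,
    points_per_image=50,
    confuser_similarity=0.3,
    n_rare_classes=20,
    rare_cover=0.002,
    seed=2020,
)
PATCH_SIZE = 32


@pytest.fixture(scope="session")
def sibling_pipeline():
    """Trained sibling hierarchy on the six-class survey + held-out split."""
    table, images, scenes = build_survey(SIBLING_SURVEY)
    features = features_from_images(
        table, images, ExtractorSpec("handcrafted"), patch_size=PATCH_SIZE
    )
    tree = SIBLING_SURVEY.hierarchy()
    (train_tab, ftr), (test_tab, fte) = split_features(
        table, features, SplitSpec(seed=SIBLING_SURVEY.seed)
    )
    model = train_hierarchical(train_tab, ftr, tree, "sibling", TrainConfig(seed=SIBLING_SURVEY.seed))
    return {
        "table": table,
        "scenes": scenes,
        "tree": tree,
        "train": (train_tab, ftr),
        "test": (test_tab, fte),
        "model": model,
    }


@pytest.fixture(scope="session")
def flat_pipeline():
    """Flat one-vs-all SVM on the 20-rare-class survey + held-out split."""
    table, images, _ = build_survey(FLAT_SURVEY)
    features = features_from_images(
        table, images, ExtractorSpec("handcrafted"), patch_size=PATCH_SIZE
    )
    (train_tab, ftr), (test_tab, fte) = split_features(
        table, features, SplitSpec(seed=FLAT_SURVEY.seed)
    )
    model = train_flat(train_tab, ftr, TrainConfig(seed=FLAT_SURVEY.seed))
    return {"table": table, "train": (train_tab, ftr), "test": (test_tab, fte), "model": model}
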