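"""End-to-end glue: enhancement -> patches -> features, and node evaluation.

These helpers wire the per-module operations into the standard survey
workflow so the CLI, the test-suite and downstream scripts share one code
path: read each image once, colour-stretch it whole, cut a patch around
every annotated point, and stack the extracted features in annotation-table
row order.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np

from .annotations import AnnotationTable
from .errors import ValidationError
from .evaluate import MetricsReport, confusion, metrics_report
from .features import ExtractorSpec, FeatureMatrix, extract_features
from .hierclf import HierModel, evaluation_mask, predict_node
from .preprocess import ImageRGB, StretchParams, batch_patches, color_stretch, load_image

__all__ = [
    "extract_survey_features",
    "features_from_images",
    "evaluate_node",
]


def features_from_images(
    table: AnnotationTable,
    images: Mapping[str, ImageRGB],
    extractor: ExtractorSpec,
    patch_size: int = 32,
    stretch: StretchParams | None = StretchParams(),
    pad: str = "reflect",
) -> FeatureMatrix:
    """Features for every annotation row, from in-memory images.

    ``images`` maps image_id to the raw image; enhancement (if any) is
    applied whole-image before patch extraction. Rows come out aligned to
    the table's row order.
    """
    df = table.df
    rows: list[np.ndarray | None] = [None] * len(df)
    for image_id, sub in df.groupby("image_id", sort=True):
        if image_id not in images:
            raise ValidationError(f"no image supplied for id {image_id!r}")
        img = images[image_id]
        if stretch is not None:
            img = color_stretch(img, stretch)
        pts = list(zip(sub["x"].tolist(), sub["y"].tolist()))
        patches = batch_patches(img, pts, size=patch_size, pad=pad)
        values = extract_features(patches, extractor).values
        for row_pos, feat in zip(sub.index.tolist(), values):
            rows[row_pos] = feat
    return FeatureMatrix(np.stack(rows), extractor.extractor_id)


def extract_survey_features(
    table: AnnotationTable,
    images_dir: str | Path,
    extractor: ExtractorSpec,
    patch_size: int = 32,
    stretch: StretchParams | None = StretchParams(),
    pad: str = "reflect",
) -> FeatureMatrix:
    """Same as :func:`features_from_images`, reading PNGs from a directory."""
    images_dir = Path(images_dir)
    df = table.df
    rows: list[np.ndarray | None] = [None] * len(df)
    for image_id, sub in df.groupby("image_id", sort=True):
        path = images_dir / f"{image_id}.png"
        if not path.exists():
            raise ValidationError(f"image file missing: {path}")
        img = load_image(path, image_id=str(image_id))
        if stretch is not None:
            img = color_stretch(img, stretch)
        pts = list(zip(sub["x"].tolist(), sub["y"].tolist()))
        patches = batch_patches(img, pts, size=patch_size, pad=pad)
        values = extract_features(patches, extractor).values
        for row_pos, feat in zip(sub.index.tolist(), values):
            rows[row_pos] = feat
    return FeatureMatrix(np.stack(rows), extractor.extractor_id)


def evaluate_node(
    model: HierModel,
    table: AnnotationTable,
    features: FeatureMatrix,
    target_node: str,
    focal_name: str = "kelp",
) -> MetricsReport:
    """Node-level binary evaluation under the model's policy convention.

    Inclusive models are scored over every test row; sibling models over
    the rows whose true label falls in the target's parent subtree. True
    and predicted labels are binarised to ``focal_name`` / ``non-<focal>``
    and the four criteria are reported with ``focal_name`` focal.
    """
    tree = model.tree
    mask = evaluation_mask(table, tree, model.policy_kind, target_node)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValidationError("no rows in the evaluation population")
    X = features.rows(idx)
    features.check_compatible(model.extractor_id, model.node_models[target_node].dim)
    y_pred, _ = predict_node(model.node_models[target_node], X)
    pos_labels = tree.subtree_labels(target_node)
    y_true = np.isin(table.labels[idx], list(pos_labels)).astype(int)
    neg_name = f"non-{focal_name}"
    to_name = np.array([neg_name, focal_name], dtype=object)
    cm = confusion(to_name[y_true], to_name[y_pred])
    return metrics_report(cm, focal=focal_name)
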