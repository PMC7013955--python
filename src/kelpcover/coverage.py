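"""Percent-cover estimation and expert-vs-estimated agreement.

The ecological endpoint of a point-annotated survey is *percent cover*: the
fraction of annotated points in an image that belong to a focal taxon (here
kelp). Expert cover aggregates the hand labels; estimated cover aggregates
a classifier's predictions at the very same pixel locations, so the two are
directly comparable per image. Agreement is quantified by ordinary least
squares of estimated cover on expert cover (slope, intercept, R² and a 95%
slope confidence interval), per site/year group and pooled, and by grouped
mean-cover tables in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import AnnotationTable, HierarchyTree
from .errors import ValidationError
from .hierclf import PredictionRecord

__all__ = [
    "CoverageRecord",
    "CoverageRegression",
    "image_coverage",
    "coverage_table",
    "regress_coverage",
    "aggregate_cover",
    "records_to_frame",
    "plot_coverage",
]

#: grouping key of the pooled (all-records) regression / aggregate row.
POOLED = "__all__"


@dataclass(frozen=True)
class CoverageRecord:
    """Expert vs estimated cover of the focal class for one image."""

    image_id: str
    site: str
    year: int
    n_points: int
    expert_cover: float
    estimated_cover: float


@dataclass(frozen=True)
class CoverageRegression:
    """OLS agreement of estimated (response) on expert (predictor) cover."""

    group: str
    slope: float
    intercept: float
    r_squared: float
    n_images: int
    slope_ci95: tuple[float, float]


def image_coverage(labels: Sequence[str], focal_labels: Iterable[str]) -> float:
    """Fraction of an image's points carrying a focal-class label."""
    labels = list(labels)
    if not labels:
        raise ValidationError("no points: cover undefined")
    focal = set(focal_labels)
    return sum(1 for lab in labels if lab in focal) / len(labels)


def _record_is_focal(record: PredictionRecord, focal_node: str, focal_labels: frozenset[str]) -> bool:
    if record.label is not None:
        return record.label in focal_labels
    return focal_node in record.node_path


def coverage_table(
    expert: AnnotationTable,
    predicted: Sequence[PredictionRecord],
    tree: HierarchyTree,
    focal_node: str,
) -> list[CoverageRecord]:
    """Per-image expert and estimated cover of ``focal_node``.

    Both covers are computed over the identical point set: the rows of
    ``expert``, with ``predicted[i]`` the prediction for row
    ``predicted[i].index`` of that table. Every row must be predicted
    exactly once.
    """
    focal_labels = tree.subtree_labels(focal_node)
    n = len(expert)
    seen = np.zeros(n, dtype=bool)
    est_focal = np.zeros(n, dtype=bool)
    for rec in predicted:
        if not (0 <= rec.index < n):
            raise ValidationError(f"prediction index {rec.index} outside table of {n} rows")
        if seen[rec.index]:
            raise ValidationError(f"row {rec.index} predicted twice")
        seen[rec.index] = True
        est_focal[rec.index] = _record_is_focal(rec, focal_node, focal_labels)
    if not seen.all():
        missing_rows = np.flatnonzero(~seen)
        missing_images = sorted(set(expert.image_ids[missing_rows]))
        raise ValidationError(
            f"rows without predictions for images: {missing_images[:10]}"
        )
    df = expert.df.assign(
        _expert=np.isin(expert.labels, list(focal_labels)),
        _est=est_focal,
    )
    records = []
    for image_id, sub in df.groupby("image_id", sort=True):
        records.append(
            CoverageRecord(
                image_id=str(image_id),
                site=str(sub["site"].iloc[0]),
                year=int(sub["year"].iloc[0]),
                n_points=len(sub),
                expert_cover=float(sub["_expert"].mean()),
                estimated_cover=float(sub["_est"].mean()),
            )
        )
    return records


def records_to_frame(records: Sequence[CoverageRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def _regress(group: str, expert: np.ndarray, est: np.ndarray) -> CoverageRegression:
    if len(expert) < 3:
        raise ValidationError(f"group {group!r}: need at least 3 images, got {len(expert)}")
    if np.ptp(expert) == 0.0:
        raise ValidationError(f"group {group!r}: expert covers all equal; fit degenerate")
    res = stats.linregress(expert, est)
    tcrit = stats.t.ppf(0.975, df=len(expert) - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    return CoverageRegression(
        group=group,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_images=len(expert),
        slope_ci95=(float(ci[0]), float(ci[1])),
    )


def regress_coverage(
    records: Sequence[CoverageRecord],
    group_by: str | None = None,
) -> list[CoverageRegression]:
    """Per-group and pooled OLS of estimated cover on expert cover.

    ``group_by`` is ``"site"``, ``"year"`` or None (pooled only). The pooled
    fit (group ``"__all__"``) always comes first.
    """
    df = records_to_frame(records)
    if df.empty:
        raise ValidationError("no coverage records")
    out = [_regress(POOLED, df["expert_cover"].to_numpy(), df["estimated_cover"].to_numpy())]
    if group_by is not None:
        if group_by not in ("site", "year"):
            raise ValidationError(f"unknown grouping {group_by!r}")
        for key, sub in df.groupby(group_by, sort=True):
            out.append(
                _regress(str(key), sub["expert_cover"].to_numpy(), sub["estimated_cover"].to_numpy())
            )
    return out


def aggregate_cover(
    records: Sequence[CoverageRecord],
    by: Sequence[str] = ("site",),
    point_weighted: bool = False,
) -> pd.DataFrame:
    """Group means of expert and estimated cover, in percent.

    Per-image covers are averaged unweighted over images by default
    (``point_weighted=True`` weights each image by its point count). A
    pooled row (group ``"__all__"``) is appended.
    """
    df = records_to_frame(records)
    if df.empty:
        raise ValidationError("no coverage records")
    for key in by:
        if key not in ("site", "year"):
            raise ValidationError(f"unknown grouping {key!r}")

    def _mean(sub: pd.DataFrame) -> pd.Series:
        w = sub["n_points"].to_numpy(dtype=float) if point_weighted else None
        return pd.Series(
            {
                "n_images": len(sub),
                "expert_pct": 100.0 * np.average(sub["expert_cover"], weights=w),
                "estimated_pct": 100.0 * np.average(sub["estimated_cover"], weights=w),
            }
        )

    rows = []
    for key, sub in df.groupby(list(by), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        rows.append({**dict(zip(by, key)), **_mean(sub)})
    pooled = {**{k: POOLED for k in by}, **_mean(df)}
    rows.append(pooled)
    out = pd.DataFrame(rows)
    out["n_images"] = out["n_images"].astype(int)
    return out


def plot_coverage(
    records: Sequence[CoverageRecord],
    path: str,
    group_by: str | None = "site",
) -> None:
    """Scatter of estimated vs expert cover with the OLS line per panel."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = records_to_frame(records)
    groups = [POOLED]
    if group_by:
        groups += sorted(df[group_by].astype(str).unique())
    ncols = min(3, len(groups))
    nrows = int(np.ceil(len(groups) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 4 * nrows), squeeze=False)
    for ax, group in zip(axes.ravel(), groups):
        sub = df if group == POOLED else df[df[group_by].astype(str) == group]
        x = sub["expert_cover"].to_numpy()
        y = sub["estimated_cover"].to_numpy()
        ax.scatter(x, y, s=10, alpha=0.6)
        ax.plot([0, 1], [0, 1], "g--", lw=1, label="perfect")
        title = f"{group} (n={len(sub)})"
        if len(x) >= 3 and np.ptp(x) > 0:
            reg = _regress(group, x, y)
            xs = np.linspace(0, 1, 10)
            ax.plot(xs, reg.intercept + reg.slope * xs, "b-", lw=1.5, label="OLS")
            title += f"  $R^2$={reg.r_squared:.2f}"
        ax.set_title(title)
        ax.set_xlabel("expert cover")
        ax.set_ylabel("estimated cover")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
    for ax in axes.ravel()[len(groups):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
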