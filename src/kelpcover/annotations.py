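"""Point-annotation tables, the class hierarchy, dataset summaries and splits.

Benthic survey programs annotate each seafloor image at a set of randomly
placed pixels (CPCe-style point count, typically up to 50 points per image);
each point carries a taxon or substrate label plus site/year metadata. This
module is the data model for those tables and for the rooted class hierarchy
(CATAMI-style) that drives local-per-node classifier training.

Coordinates are 0-based with ``x`` the pixel column and ``y`` the pixel row,
origin at the top-left corner of the image.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, HierarchyLookupError, ValidationError

__all__ = [
    "ANNOTATION_COLUMNS",
    "HierarchyNode",
    "HierarchyTree",
    "PointAnnotation",
    "AnnotationTable",
    "DatasetSummary",
    "SplitSpec",
    "load_annotations",
    "save_annotations",
    "summarize",
    "make_split",
]

#: Canonical CSV header for annotation tables.
ANNOTATION_COLUMNS = ("image_id", "x", "y", "label", "site", "year", "depth_m")


# ---------------------------------------------------------------------------
# Hierarchy
# ---------------------------------------------------------------------------

@dataclass
class HierarchyNode:
    """One node of the class hierarchy.

    ``leaf_labels`` are the annotation label strings mapped directly to this
    node (a node may hold several labels, e.g. an "other macroalgae" node
    holding every non-kelp algal label).
    """

    node_id: str
    name: str
    parent_id: str | None = None
    children: list[str] = field(default_factory=list)
    leaf_labels: set[str] = field(default_factory=set)


class HierarchyTree:
    """Rooted class tree mapping annotation labels to taxonomy nodes.

    Invariants enforced at construction: unique node ids, exactly one root,
    no cycles, every label mapped to exactly one node.
    """

    def __init__(self, nodes: Iterable[HierarchyNode]):
        self.nodes: dict[str, HierarchyNode] = {}
        root = None
        for node in nodes:
            if node.node_id in self.nodes:
                raise ValidationError(f"duplicate node id {node.node_id!r}")
            self.nodes[node.node_id] = node
        for node in self.nodes.values():
            if node.parent_id is None:
                if root is not None:
                    raise ValidationError(
                        f"multiple roots: {root!r} and {node.node_id!r}"
                    )
                root = node.node_id
            elif node.parent_id not in self.nodes:
                raise ValidationError(
                    f"node {node.node_id!r} has unknown parent {node.parent_id!r}"
                )
        if root is None:
            raise ValidationError("hierarchy has no root node")
        self.root_id: str = root
        # rebuild children lists from parent pointers (the authoritative edge set)
        for node in self.nodes.values():
            node.children = []
        for node in self.nodes.values():
            if node.parent_id is not None:
                self.nodes[node.parent_id].children.append(node.node_id)
        for node in self.nodes.values():
            node.children.sort()
        self._check_acyclic()
        self._label_to_node: dict[str, str] = {}
        for node in self.nodes.values():
            for label in node.leaf_labels:
                if label in self._label_to_node:
                    raise ValidationError(
                        f"label {label!r} mapped to both "
                        f"{self._label_to_node[label]!r} and {node.node_id!r}"
                    )
                self._label_to_node[label] = node.node_id

    def _check_acyclic(self) -> None:
        for start in self.nodes:
            seen = set()
            cur: str | None = start
            while cur is not None:
                if cur in seen:
                    raise ValidationError(f"cycle through node {start!r}")
                seen.add(cur)
                cur = self.nodes[cur].parent_id

    # -- queries ------------------------------------------------------------

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def node(self, node_id: str) -> HierarchyNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise HierarchyLookupError(f"unknown node id {node_id!r}") from None

    def parent(self, node_id: str) -> str | None:
        return self.node(node_id).parent_id

    def node_of_label(self, label: str) -> str | None:
        """Node id a label is mapped to, or None for unassigned labels."""
        return self._label_to_node.get(label)

    def subtree_labels(self, node_id: str) -> frozenset[str]:
        """Union of leaf labels over ``node_id`` and all its descendants."""
        node = self.node(node_id)
        labels = set(node.leaf_labels)
        for child in node.children:
            labels |= self.subtree_labels(child)
        return frozenset(labels)

    def all_labels(self) -> frozenset[str]:
        return self.subtree_labels(self.root_id)

    def iter_nonroot(self) -> Iterable[str]:
        return (nid for nid in sorted(self.nodes) if nid != self.root_id)

    # -- JSON round trip ----------------------------------------------------

    def to_json(self) -> dict:
        return {
            "root": self.root_id,
            "nodes": [
                {
                    "id": n.node_id,
                    "name": n.name,
                    "parent": n.parent_id,
                    "leaf_labels": sorted(n.leaf_labels),
                }
                for n in (self.nodes[k] for k in sorted(self.nodes))
            ],
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "HierarchyTree":
        nodes = [
            HierarchyNode(
                node_id=d["id"],
                name=d.get("name", d["id"]),
                parent_id=d.get("parent"),
                leaf_labels=set(d.get("leaf_labels", ())),
            )
            for d in obj["nodes"]
        ]
        tree = cls(nodes)
        if obj.get("root") not in (None, tree.root_id):
            raise ValidationError(
                f"declared root {obj['root']!r} is not the parentless node"
            )
        return tree

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "HierarchyTree":
        return cls.from_json(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PointAnnotation:
    """A single labelled pixel of a survey image."""

    image_id: str
    x: int
    y: int
    label: str
    site: str = ""
    year: int = 0
    depth_m: float | None = None


class AnnotationTable:
    """Ordered table of labelled points; the unit of training and coverage.

    Row order is stable and is the join key to a :class:`FeatureMatrix`.
    ``(image_id, x, y)`` triples are unique.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = ""):
        missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
        if missing:
            raise ConfigurationError(f"missing annotation columns: {missing}")
        df = df.loc[:, list(ANNOTATION_COLUMNS)].reset_index(drop=True)
        df["image_id"] = df["image_id"].astype(str)
        df["label"] = df["label"].astype(str)
        df["site"] = df["site"].astype(str)
        df["x"] = df["x"].astype(np.int64)
        df["y"] = df["y"].astype(np.int64)
        df["year"] = df["year"].astype(np.int64)
        if (df["label"] == "").any():
            bad = df.index[df["label"] == ""].tolist()
            raise ValidationError(f"empty labels at rows {bad[:10]}")
        dup = df.duplicated(subset=["image_id", "x", "y"], keep=False)
        if dup.any():
            dups = (
                df.loc[dup, ["image_id", "x", "y"]]
                .drop_duplicates()
                .itertuples(index=False, name=None)
            )
            raise ValidationError(
                "duplicate (image_id, x, y) triples: " + ", ".join(map(str, list(dups)[:10]))
            )
        self._df = df
        self.provenance = provenance

    # -- container protocol -------------------------------------------------

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        return isinstance(other, AnnotationTable) and self._df.equals(other._df)

    @property
    def df(self) -> pd.DataFrame:
        """Underlying DataFrame (treat as read-only)."""
        return self._df

    def row(self, i: int) -> PointAnnotation:
        r = self._df.iloc[i]
        depth = None if pd.isna(r["depth_m"]) else float(r["depth_m"])
        return PointAnnotation(
            r["image_id"], int(r["x"]), int(r["y"]), r["label"], r["site"],
            int(r["year"]), depth,
        )

    @property
    def labels(self) -> np.ndarray:
        return self._df["label"].to_numpy()

    @property
    def image_ids(self) -> np.ndarray:
        return self._df["image_id"].to_numpy()

    def select_rows(self, index: Sequence[int] | np.ndarray) -> "AnnotationTable":
        """Sub-table with the given row positions, preserving their order."""
        sub = self._df.iloc[np.asarray(index, dtype=np.intp)]
        return AnnotationTable(sub, provenance=self.provenance)

    @classmethod
    def from_points(cls, points: Iterable[PointAnnotation], provenance: str = "") -> "AnnotationTable":
        rows = [
            (p.image_id, p.x, p.y, p.label, p.site, p.year,
             np.nan if p.depth_m is None else p.depth_m)
            for p in points
        ]
        df = pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS))
        return cls(df, provenance=provenance)


def load_annotations(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> AnnotationTable:
    """Read an annotation CSV into an :class:`AnnotationTable`.

    Parameters
    ----------
    path
        CSV file with the canonical header ``image_id,x,y,label,site,year,depth_m``.
    dialect
        Optional mapping from canonical column name to the file's column name,
        for foreign exports (e.g. ``{"image_id": "Image Name"}``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"image_id": str, "label": str, "site": str})
    if dialect:
        rename = {src: canon for canon, src in dialect.items() if src in df.columns}
        missing_src = [src for src in dialect.values() if src not in df.columns]
        if missing_src:
            raise ConfigurationError(
                f"dialect columns absent from {path.name}: {missing_src}"
            )
        df = df.rename(columns=rename)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path.name}: missing columns {missing}")
    bad = df.index[df["label"].isna() | (df["label"].astype(str) == "")]
    if len(bad):
        # +2: header line plus 1-based numbering
        lines = [int(i) + 2 for i in bad[:10]]
        raise ValidationError(f"{path.name}: empty labels on lines {lines}")
    return AnnotationTable(df, provenance=str(path))


def save_annotations(table: AnnotationTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DatasetSummary:
    """Counts for one group of annotations (e.g. a site or a survey year)."""

    group_key: tuple
    n_points: int
    n_images: int
    n_classes: int
    class_counts: Mapping[str, int]


#: group_key of the grand-total summary row.
TOTAL_KEY = ("__all__",)


def summarize(table: AnnotationTable, group_by: Sequence[str] = ()) -> list[DatasetSummary]:
    """Per-group point/image/class counts plus a grand-total summary.

    ``group_by`` names annotation fields (``site``, ``year`` ...). The total
    row uses ``group_key == ("__all__",)`` and always comes last. An empty
    table yields just the zero total.
    """
    for key in group_by:
        if key not in ANNOTATION_COLUMNS:
            raise ConfigurationError(f"unknown group key {key!r}")
    df = table.df

    def _summary(key: tuple, sub: pd.DataFrame) -> DatasetSummary:
        counts = sub["label"].value_counts().to_dict()
        return DatasetSummary(
            group_key=key,
            n_points=len(sub),
            n_images=sub["image_id"].nunique(),
            n_classes=len(counts),
            class_counts=counts,
        )

    out: list[DatasetSummary] = []
    if group_by and len(df):
        for key, sub in df.groupby(list(group_by), sort=True):
            if not isinstance(key, tuple):
                key = (key,)
            out.append(_summary(key, sub))
    out.append(_summary(TOTAL_KEY, df))
    return out


def summaries_to_frame(summaries: Sequence[DatasetSummary]) -> pd.DataFrame:
    """Flatten summaries to a DataFrame for CSV export."""
    return pd.DataFrame(
        [
            {
                "group": "/".join(map(str, s.group_key)),
                "n_points": s.n_points,
                "n_images": s.n_images,
                "n_classes": s.n_classes,
            }
            for s in summaries
        ]
    )


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """How to split a table into train and test halves.

    ``per_location_fraction`` draws ``floor(train_fraction * n_images)``
    whole images per site into the training set (image-level, never
    point-level, so points of one image never straddle the split).
    ``by_year`` assigns whole survey years to each half.
    """

    strategy: str = "per_location_fraction"
    train_fraction: float = 0.7
    train_years: frozenset[int] = frozenset()
    test_years: frozenset[int] = frozenset()
    seed: int = 0

    def __post_init__(self):
        if self.strategy not in ("per_location_fraction", "by_year"):
            raise ConfigurationError(f"unknown split strategy {self.strategy!r}")
        if self.strategy == "per_location_fraction" and not (0.0 < self.train_fraction < 1.0):
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if self.strategy == "by_year":
            overlap = set(self.train_years) & set(self.test_years)
            if overlap:
                raise ConfigurationError(f"years in both halves: {sorted(overlap)}")
            if not self.train_years or not self.test_years:
                raise ConfigurationError("by_year needs non-empty year sets")


def make_split(table: AnnotationTable, spec: SplitSpec) -> tuple[AnnotationTable, AnnotationTable]:
    """Partition a table into (train, test) at the image level.

    Deterministic for a fixed ``spec.seed``. A site holding a single image
    sends that image to the training set with a warning.
    """
    df = table.df
    if spec.strategy == "by_year":
        years = set(df["year"].unique())
        unassigned = years - set(spec.train_years) - set(spec.test_years)
        if unassigned:
            raise ConfigurationError(f"years not assigned to a half: {sorted(unassigned)}")
        train_mask = df["year"].isin(list(spec.train_years)).to_numpy()
    else:
        rng = np.random.default_rng(spec.seed)
        train_images: set[str] = set()
        for site in sorted(df["site"].unique()):
            imgs = np.sort(df.loc[df["site"] == site, "image_id"].unique())
            n_train = int(np.floor(spec.train_fraction * len(imgs)))
            if len(imgs) == 1:
                warnings.warn(
                    f"site {site!r} has a single image; assigned to train",
                    stacklevel=2,
                )
                n_train = 1
            chosen = rng.choice(imgs, size=n_train, replace=False)
            train_images.update(chosen.tolist())
        train_mask = df["image_id"].isin(train_images).to_numpy()

    train = AnnotationTable(df[train_mask], provenance=table.provenance)
    test = AnnotationTable(df[~train_mask], provenance=table.provenance)
    return train, test
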