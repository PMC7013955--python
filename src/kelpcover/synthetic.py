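"""Synthetic benthic surveys with exact per-pixel ground truth.

Real AUV benthic surveys cannot be redistributed with a software package,
so every pipeline stage here is exercised on generated scenes instead: each
scene is a textured multi-class image plus a per-pixel class map, rendered
from a seeded spec. Classes claim pixels through smoothed random fields
(anisotropic for blade/frond macroalgae, fine-grained for turf and
substrate), so regions are contiguous blobs of controlled size and the
realized cover of every class is known exactly from the class map.

The generator deliberately emulates the statistical structure of a point-
annotated survey rather than its photographic appearance: a dominant focal
class (kelp), a visually similar confuser (a *Scytothalia*-like brown
alga whose colour and texture interpolate toward kelp's as
``confuser_similarity`` goes to 1), substrate classes, optional long-tail
rare classes, per-image cover variation, an illumination gradient, and ~50
uniformly random annotated points per image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .annotations import (
    AnnotationTable,
    HierarchyNode,
    HierarchyTree,
    PointAnnotation,
)
from .errors import ConfigurationError
from .preprocess import ImageRGB, save_image

__all__ = [
    "ClassSpec",
    "SceneSpec",
    "SyntheticScene",
    "SurveySpec",
    "default_hierarchy",
    "default_palette",
    "render_scene",
    "sample_points",
    "iter_survey",
    "generate_survey",
]

# Base colours (RGB in [0,1]) chosen for plausible separations: kelp a
# golden brown, the confuser's *distinct* endpoint a paler olive, turf a
# dark red mat, substrate light; similarity morphs the confuser toward kelp.
_KELP_COLOR = (0.36, 0.30, 0.10)
_CONFUSER_DISTINCT_COLOR = (0.62, 0.52, 0.16)
_PALETTE = {
    "turf": ((0.28, 0.10, 0.12), "turf", 2.0, 0.05),
    "coral": ((0.72, 0.52, 0.50), "grain", 3.0, 0.05),
    "rock": ((0.45, 0.44, 0.42), "grain", 5.0, 0.04),
    "sand": ((0.76, 0.72, 0.58), "grain", 1.5, 0.03),
}


@dataclass(frozen=True)
class ClassSpec:
    """One class of the scene palette.

    ``cover`` is the target pixel fraction; exactly one class (the
    substrate) uses ``cover=None`` and receives the remainder. ``texture``
    is one of blade / frond / turf / grain; blade and frond render as
    elongated anisotropic regions.
    """

    name: str
    color: tuple[float, float, float]
    texture: str = "grain"
    texture_scale: float = 4.0
    noise_sd: float = 0.04
    cover: float | None = None

    def __post_init__(self):
        if self.texture not in ("blade", "frond", "turf", "grain"):
            raise ConfigurationError(f"unknown texture {self.texture!r}")
        if self.cover is not None and not (0.0 <= self.cover <= 1.0):
            raise ConfigurationError(f"cover {self.cover} outside [0, 1]")


@dataclass(frozen=True)
class SceneSpec:
    """Everything needed to render one scene deterministically."""

    width: int = 192
    height: int = 192
    classes: tuple[ClassSpec, ...] = ()
    illumination_amplitude: float = 0.15
    seed: int = 0

    def __post_init__(self):
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ConfigurationError("palette names must be unique")
        substrates = [c for c in self.classes if c.cover is None]
        if len(substrates) != 1:
            raise ConfigurationError("exactly one class must have cover=None (substrate)")
        total = sum(c.cover for c in self.classes if c.cover is not None)
        if total > 1.0 + 1e-9:
            raise ConfigurationError(f"target covers sum to {total:.3f} > 1")


@dataclass
class SyntheticScene:
    """Rendered image + per-pixel integer class map + exact covers."""

    image: ImageRGB
    class_map: np.ndarray  # H x W int, index into class_names
    class_names: list[str]
    realized_cover: dict[str, float]
    seed: int

    def label_at(self, x: int, y: int) -> str:
        return self.class_names[self.class_map[y, x]]


def default_palette(
    kelp_cover: float = 0.4,
    confuser_similarity: float = 0.3,
    n_rare: int = 0,
    rare_cover: float = 0.0015,
) -> tuple[ClassSpec, ...]:
    """The six-class benthic palette plus an optional rare-class long tail.

    ``confuser_similarity`` in [0, 1] linearly interpolates the confuser's
    colour, texture kind and scale from a clearly distinct brown alga (0)
    to an exact visual twin of kelp (1). Rare classes are small sand-toned
    sprinkles, individually near-invisible, emulating the long tail of
    scarce taxa in real label inventories.
    """
    if not (0.0 <= confuser_similarity <= 1.0):
        raise ConfigurationError("confuser_similarity must lie in [0, 1]")
    s = confuser_similarity
    conf_color = tuple(
        (1 - s) * d + s * k for d, k in zip(_CONFUSER_DISTINCT_COLOR, _KELP_COLOR)
    )
    conf_scale = (1 - s) * 5.0 + s * 8.0
    conf_noise = (1 - s) * 0.07 + s * 0.05
    classes = [
        ClassSpec("kelp", _KELP_COLOR, "blade", 8.0, 0.05, kelp_cover),
        ClassSpec(
            "scytothalia", conf_color, "frond" if s < 0.5 else "blade",
            conf_scale, conf_noise, 0.12,
        ),
        ClassSpec("turf", *_PALETTE["turf"], cover=0.06),
        ClassSpec("coral", *_PALETTE["coral"], cover=0.04),
        ClassSpec("rock", *_PALETTE["rock"], cover=0.06),
    ]
    rng = np.random.default_rng(12345)  # fixed: rare palette is part of the spec
    sand = np.array(_PALETTE["sand"][0])
    for i in range(n_rare):
        color = tuple(np.clip(sand + rng.uniform(-0.08, 0.08, size=3), 0, 1))
        classes.append(
            ClassSpec(f"rare{i:02d}", color, "grain", 1.2, 0.03, rare_cover)
        )
    classes.append(ClassSpec("sand", *_PALETTE["sand"], cover=None))
    return tuple(classes)


def default_hierarchy(rare_labels: Sequence[str] = ()) -> HierarchyTree:
    """CATAMI-style tree for the default palette.

    Kelp sits alone under the macroalgae node; the confuser and turf form
    its sibling "other macroalgae" node; everything else (biota and
    substrate, plus any rare labels) hangs under non-macroalgae.
    """
    return HierarchyTree(
        [
            HierarchyNode("1", "benthos"),
            HierarchyNode("1.1", "macroalgae", "1"),
            HierarchyNode("1.1.1", "kelp", "1.1", leaf_labels={"kelp"}),
            HierarchyNode(
                "1.1.2", "other macroalgae", "1.1",
                leaf_labels={"scytothalia", "turf"},
            ),
            HierarchyNode(
                "1.2", "non-macroalgae", "1",
                leaf_labels={"coral", "rock", "sand", *rare_labels},
            ),
        ]
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _smooth_field(rng: np.random.Generator, h: int, w: int, spec: ClassSpec) -> np.ndarray:
    """Smoothed noise field whose top quantile forms this class's regions."""
    noise = rng.standard_normal((h, w))
    scale = max(spec.texture_scale, 1.0)
    if spec.texture in ("blade", "frond"):
        elong = 4.0 if spec.texture == "blade" else 2.5
        sigmas = (scale, scale * elong)
        if rng.random() < 0.5:
            sigmas = sigmas[::-1]
        fld = ndimage.gaussian_filter(noise, sigma=sigmas)
    else:
        fld = ndimage.gaussian_filter(noise, sigma=scale)
    return fld


def _texture_layer(rng: np.random.Generator, h: int, w: int, spec: ClassSpec) -> np.ndarray:
    """Zero-mean within-class intensity texture."""
    noise = rng.standard_normal((h, w))
    tex = ndimage.gaussian_filter(noise, sigma=max(spec.texture_scale / 3.0, 0.5))
    sd = tex.std()
    if sd > 0:
        tex = tex / sd
    if spec.texture in ("blade", "frond"):
        theta = rng.uniform(0, np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        proj = xx * np.cos(theta) + yy * np.sin(theta)
        stripes = np.sin(2 * np.pi * proj / (2.0 * spec.texture_scale) + rng.uniform(0, 2 * np.pi))
        tex = 0.7 * tex + 0.5 * stripes
    return spec.noise_sd * tex


def render_scene(spec: SceneSpec) -> SyntheticScene:
    """Render a scene; bit-deterministic for a fixed ``spec.seed``.

    Each non-substrate class claims its target number of pixels from the
    still-unclaimed pool, taking those where its smoothed random field is
    highest — contiguous blobs whose realized cover matches the target to
    within one pixel. Classes are placed in palette order.
    """
    if not spec.classes:
        raise ConfigurationError("empty palette")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    names = [c.name for c in spec.classes]
    substrate_idx = next(i for i, c in enumerate(spec.classes) if c.cover is None)
    class_map = np.full((h, w), substrate_idx, dtype=np.int64)
    unclaimed = np.ones((h, w), dtype=bool)
    for i, cls in enumerate(spec.classes):
        if cls.cover is None:
            continue
        n_target = int(round(cls.cover * h * w))
        if n_target == 0:
            continue
        if n_target > unclaimed.sum():
            raise ConfigurationError(
                f"class {cls.name!r}: {n_target} pixels requested, "
                f"{int(unclaimed.sum())} unclaimed remain"
            )
        fld = _smooth_field(rng, h, w, cls)
        fld = np.where(unclaimed, fld, -np.inf)
        flat_idx = np.argpartition(fld.ravel(), -n_target)[-n_target:]
        class_map.ravel()[flat_idx] = i
        unclaimed.ravel()[flat_idx] = False

    img = np.empty((h, w, 3))
    colors = np.array([c.color for c in spec.classes])
    img[:] = colors[class_map]
    for i, cls in enumerate(spec.classes):
        mask = class_map == i
        if not mask.any():
            # burn the rng the same amount regardless, for per-class determinism
            _ = _texture_layer(rng, h, w, cls)
            continue
        tex = _texture_layer(rng, h, w, cls)
        img[mask] += tex[mask, None]

    # multiplicative illumination ramp along a random direction
    amp = spec.illumination_amplitude
    if amp > 0:
        theta = rng.uniform(0, 2 * np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        proj = (xx / max(w - 1, 1)) * np.cos(theta) + (yy / max(h - 1, 1)) * np.sin(theta)
        proj = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-12)
        img *= (1.0 - amp + 2.0 * amp * proj)[:, :, None]
    img = np.clip(img, 0.0, 1.0)

    realized = {
        name: float((class_map == i).mean()) for i, name in enumerate(names)
    }
    return SyntheticScene(
        image=ImageRGB(img, image_id=f"scene{spec.seed:08d}"),
        class_map=class_map,
        class_names=names,
        realized_cover=realized,
        seed=spec.seed,
    )


# ---------------------------------------------------------------------------
# Point sampling
# ---------------------------------------------------------------------------

def sample_points(
    scene: SyntheticScene,
    k: int,
    seed: int,
    site: str = "",
    year: int = 0,
    depth_m: float | None = None,
    expert_error_rate: float = 0.0,
    boundary_radius: int = 2,
) -> list[PointAnnotation]:
    """CPCe-style random point annotation of a scene.

    ``k`` distinct pixel positions are drawn uniformly; each point's label
    is read off the class map. With ``expert_error_rate > 0``, a point
    lying within ``boundary_radius`` pixels of a class edge is, with that
    probability, relabelled to the neighbouring class — emulating expert
    misclassification at ambiguous class boundaries.
    """
    h, w = scene.class_map.shape
    if k > h * w:
        raise ConfigurationError(f"k={k} exceeds pixel count {h * w}")
    rng = np.random.default_rng(seed)
    flat = rng.choice(h * w, size=k, replace=False)
    ys, xs = np.unravel_index(flat, (h, w))
    points = []
    for x, y in zip(xs, ys):
        label = scene.label_at(int(x), int(y))
        if expert_error_rate > 0.0:
            r = boundary_radius
            win = scene.class_map[
                max(0, y - r) : y + r + 1, max(0, x - r) : x + r + 1
            ]
            others = win[win != scene.class_map[y, x]]
            if others.size and rng.random() < expert_error_rate:
                vals, cnts = np.unique(others, return_counts=True)
                label = scene.class_names[int(vals[np.argmax(cnts)])]
        points.append(
            PointAnnotation(
                image_id=scene.image.image_id,
                x=int(x),
                y=int(y),
                label=label,
                site=site,
                year=year,
                depth_m=depth_m,
            )
        )
    return points


# ---------------------------------------------------------------------------
# Whole surveys
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SurveySpec:
    """A multi-image survey: scenes, sites/years, and point annotation.

    Per-image kelp cover is drawn uniformly from ``kelp_cover_range``,
    giving the between-image cover variation a regression of estimated on
    expert cover needs. Everything downstream derives from ``seed``.
    """

    n_images: int = 50
    points_per_image: int = 50
    sites: tuple[str, ...] = ("north15", "south15")
    years: tuple[int, ...] = (2013,)
    width: int = 192
    height: int = 192
    kelp_cover_range: tuple[float, float] = (0.05, 0.65)
    confuser_similarity: float = 0.3
    n_rare_classes: int = 0
    rare_cover: float = 0.0015
    illumination_amplitude: float = 0.15
    expert_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_images < 1 or self.points_per_image < 1:
            raise ConfigurationError("n_images and points_per_image must be >= 1")
        lo, hi = self.kelp_cover_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError("kelp_cover_range must be ordered within [0, 1]")

    def hierarchy(self) -> HierarchyTree:
        rare = [f"rare{i:02d}" for i in range(self.n_rare_classes)]
        return default_hierarchy(rare)


def iter_survey(spec: SurveySpec) -> Iterator[tuple[SyntheticScene, list[PointAnnotation]]]:
    """Yield (scene, points) per image, a pure function of ``spec.seed``."""
    master = np.random.default_rng(spec.seed)
    combos = [(s, y) for y in spec.years for s in spec.sites]
    for i in range(spec.n_images):
        scene_seed = int(master.integers(0, 2**31 - 1))
        point_seed = int(master.integers(0, 2**31 - 1))
        kelp_cover = float(master.uniform(*spec.kelp_cover_range))
        site, year = combos[i % len(combos)]
        palette = default_palette(
            kelp_cover=kelp_cover,
            confuser_similarity=spec.confuser_similarity,
            n_rare=spec.n_rare_classes,
            rare_cover=spec.rare_cover,
        )
        scene = render_scene(
            SceneSpec(
                width=spec.width,
                height=spec.height,
                classes=palette,
                illumination_amplitude=spec.illumination_amplitude,
                seed=scene_seed,
            )
        )
        scene.image.image_id = f"img{i:04d}"
        points = sample_points(
            scene,
            spec.points_per_image,
            seed=point_seed,
            site=site,
            year=year,
            depth_m=15.0,
            expert_error_rate=spec.expert_error_rate,
        )
        yield scene, points


def generate_survey(spec: SurveySpec, out_dir: str | Path) -> dict:
    """Write a full survey to disk and return its manifest.

    Outputs: ``images/<image_id>.png``, ``annotations.csv`` (canonical
    dialect), ``hierarchy.json``, ``truth.csv`` with exact per-image covers
    (``image_id,class,true_cover``), and ``manifest.json``.
    """
    out_dir = Path(out_dir)
    images_dir = out_dir / "images"
    images_dir.mkdir(parents=True, exist_ok=True)
    all_points: list[PointAnnotation] = []
    truth_rows = []
    image_files = []
    for scene, points in iter_survey(spec):
        path = images_dir / f"{scene.image.image_id}.png"
        save_image(scene.image, path)
        image_files.append(path.name)
        all_points.extend(points)
        for cls, cover in sorted(scene.realized_cover.items()):
            truth_rows.append(
                {"image_id": scene.image.image_id, "class": cls, "true_cover": cover}
            )
    table = AnnotationTable.from_points(all_points, provenance=f"synthetic(seed={spec.seed})")
    table.df.to_csv(out_dir / "annotations.csv", index=False)
    spec.hierarchy().save(out_dir / "hierarchy.json")
    pd.DataFrame(truth_rows).to_csv(out_dir / "truth.csv", index=False)
    manifest = {
        "seed": spec.seed,
        "n_images": spec.n_images,
        "points_per_image": spec.points_per_image,
        "sites": list(spec.sites),
        "years": list(spec.years),
        "confuser_similarity": spec.confuser_similarity,
        "n_rare_classes": spec.n_rare_classes,
        "images": image_files,
        "annotations": "annotations.csv",
        "hierarchy": "hierarchy.json",
        "truth": "truth.csv",
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
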