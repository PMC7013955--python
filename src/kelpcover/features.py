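"""Fixed-length feature vectors from image patches.

The reference pathway mirrors deep-residual-feature (DRF) extraction: a
pretrained residual network is run up to its last convolutional block, whose
7 x 7 x 2048 activation grid is collapsed channel-wise by a global max pool
into a 2048-dimensional vector. The pooling step, :func:`global_max_pool`,
is implemented here and is what makes the tap point usable as a feature;
the backbone itself is a plug-in (any callable patch -> activation grid),
so no network weights are ever required to test or run the pipeline.

Two download-free extractors are provided for the full pipeline:

``handcrafted``
    A deterministic colour/texture descriptor (per-channel moments and
    percentiles, oriented gradient-energy histogram, band-pass texture
    energies, over the full patch and its centre crop). 52 dimensions.
``random_projection``
    A seeded Gaussian projection of the flattened pixels; useful as a
    structure-free control.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .errors import CompatibilityError, ConfigurationError, ExtractorUnavailableError
from .preprocess import Patch

__all__ = [
    "ActivationGrid",
    "FeatureMatrix",
    "ExtractorSpec",
    "global_max_pool",
    "handcrafted_descriptor",
    "extract_features",
    "l2_normalize",
    "save_features",
    "load_features",
    "HANDCRAFTED_DIM",
]


@dataclass
class ActivationGrid:
    """h x w x C activation array from a convolutional block."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3 or 0 in v.shape:
            raise ConfigurationError(f"expected non-empty h x w x C grid, got {v.shape}")
        if not np.isfinite(v).all():
            raise ConfigurationError("activation grid contains non-finite values")
        self.values = v


@dataclass
class FeatureMatrix:
    """N x D feature array, rows aligned to an AnnotationTable's row order."""

    values: np.ndarray
    extractor_id: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ConfigurationError(f"feature matrix must be 2-D, got {self.values.ndim}-D")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def rows(self, index) -> np.ndarray:
        return self.values[np.asarray(index, dtype=np.intp)]

    def check_compatible(self, extractor_id: str, dim: int) -> None:
        if self.extractor_id != extractor_id:
            raise CompatibilityError(
                f"feature extractor {self.extractor_id!r} != model extractor {extractor_id!r}"
            )
        if self.dim != dim:
            raise CompatibilityError(f"feature dim {self.dim} != model dim {dim}")


def global_max_pool(grid: ActivationGrid) -> np.ndarray:
    """Channel-wise global max pool: ``out[c] = max_{i,j} grid[i, j, c]``.

    This is the reduction that turns a 7 x 7 x 2048 final-block activation
    into the 2048-D deep residual feature vector; it is invariant to any
    permutation of spatial positions.
    """
    return grid.values.max(axis=(0, 1))


# ---------------------------------------------------------------------------
# Extractors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtractorSpec:
    """Which extractor to run and with what parameters.

    ``backbone_fn`` (backbone kind) maps a patch pixel array to an
    :class:`ActivationGrid`; supplying a pretrained network forward pass
    here reproduces the DRF pathway exactly.
    """

    kind: str = "handcrafted"
    dim: int = 64
    seed: int = 0
    backbone_fn: Callable[[np.ndarray], ActivationGrid] | None = field(
        default=None, compare=False
    )

    def __post_init__(self):
        if self.kind not in ("backbone", "handcrafted", "random_projection"):
            raise ConfigurationError(f"unknown extractor kind {self.kind!r}")
        if self.dim <= 0:
            raise ConfigurationError("dim must be positive")

    @property
    def extractor_id(self) -> str:
        if self.kind == "handcrafted":
            return "handcrafted-v1"
        if self.kind == "random_projection":
            return f"randproj(dim={self.dim},seed={self.seed})"
        return "backbone"


_N_ORIENT = 8
_TEXTURE_SIGMAS = (1.0, 2.0, 4.0)
#: dimensionality of the handcrafted descriptor (two windows x 26 stats)
HANDCRAFTED_DIM = 2 * (15 + _N_ORIENT + len(_TEXTURE_SIGMAS))


def _window_stats(window: np.ndarray) -> np.ndarray:
    """26 colour/texture statistics of one window (H x W x 3)."""
    stats = []
    for c in range(3):
        ch = window[:, :, c]
        stats.extend([
            ch.mean(),
            ch.std(),
            np.percentile(ch, 10.0),
            np.percentile(ch, 50.0),
            np.percentile(ch, 90.0),
        ])
    gray = window.mean(axis=2)
    gy, gx = np.gradient(gray)
    mag = np.hypot(gx, gy)
    orient = np.arctan2(gy, gx) % np.pi
    bins = np.clip((orient / np.pi * _N_ORIENT).astype(int), 0, _N_ORIENT - 1)
    hist = np.bincount(bins.ravel(), weights=mag.ravel(), minlength=_N_ORIENT)
    hist = hist / (hist.sum() + 1e-12)
    stats.extend(hist.tolist())
    for sigma in _TEXTURE_SIGMAS:
        # band-pass energy: variance of the detail left after smoothing
        detail = gray - ndimage.gaussian_filter(gray, sigma)
        stats.append(float(np.sqrt((detail**2).mean())))
    return np.asarray(stats, dtype=np.float64)


def handcrafted_descriptor(pixels: np.ndarray) -> np.ndarray:
    """Deterministic 52-D colour/texture descriptor of a patch.

    Concatenates :func:`_window_stats` over the full patch and over its
    centre half-size crop; the centre window ties the descriptor to the
    annotated pixel's own class even when the patch straddles a boundary.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    h, w = pixels.shape[:2]
    qh, qw = h // 4, w // 4
    center = pixels[qh : h - qh, qw : w - qw]
    return np.concatenate([_window_stats(pixels), _window_stats(center)])


def _random_projection_matrix(n_in: int, dim: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.standard_normal((n_in, dim)) / np.sqrt(n_in)


def extract_features(patches: Sequence[Patch], spec: ExtractorSpec) -> FeatureMatrix:
    """Run an extractor over patches; row i corresponds to patch i.

    All extractors are pure functions of (patch, spec): repeated calls on
    identical inputs yield bit-identical matrices.
    """
    if len(patches) == 0:
        dim = {"handcrafted": HANDCRAFTED_DIM, "random_projection": spec.dim}.get(spec.kind, spec.dim)
        return FeatureMatrix(np.empty((0, dim)), spec.extractor_id)
    sizes = {p.pixels.shape for p in patches}
    if len(sizes) > 1:
        raise ConfigurationError(f"patches have mixed shapes: {sorted(sizes)}")

    if spec.kind == "handcrafted":
        rows = [handcrafted_descriptor(p.pixels) for p in patches]
    elif spec.kind == "random_projection":
        flat = np.stack([p.pixels.ravel() for p in patches])
        proj = _random_projection_matrix(flat.shape[1], spec.dim, spec.seed)
        rows = list(flat @ proj)
    else:  # backbone
        if spec.backbone_fn is None:
            raise ExtractorUnavailableError(
                "no backbone forward function supplied; pass ExtractorSpec(kind='backbone', "
                "backbone_fn=...) with a pretrained network, or use the download-free "
                "'handcrafted' or 'random_projection' extractors"
            )
        rows = [global_max_pool(spec.backbone_fn(p.pixels)) for p in patches]
    return FeatureMatrix(np.stack(rows), spec.extractor_id)


def l2_normalize(matrix: FeatureMatrix, enabled: bool = True) -> FeatureMatrix:
    """Scale each row to unit Euclidean norm (zero rows left untouched)."""
    if not enabled:
        return matrix
    norms = np.linalg.norm(matrix.values, axis=1, keepdims=True)
    norms[norms == 0.0] = 1.0
    return FeatureMatrix(matrix.values / norms, matrix.extractor_id)


# ---------------------------------------------------------------------------
# Persistence (HDF5)
# ---------------------------------------------------------------------------

def _config_hash(extractor_id: str, dim: int) -> str:
    payload = json.dumps({"extractor_id": extractor_id, "dim": dim}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_features(matrix: FeatureMatrix, path: str | Path, keys: np.ndarray | None = None) -> None:
    """Persist a feature matrix to HDF5.

    ``keys`` optionally stores the aligned (image_id, x, y) triples so a
    reloaded matrix can be verified against its annotation table.
    """
    import h5py

    with h5py.File(path, "w") as f:
        d = f.create_dataset("features", data=matrix.values)
        d.attrs["extractor_id"] = matrix.extractor_id
        d.attrs["dim"] = matrix.dim
        d.attrs["config_hash"] = _config_hash(matrix.extractor_id, matrix.dim)
        if keys is not None:
            f.create_dataset("keys", data=np.asarray(keys, dtype="S"))


def load_features(path: str | Path) -> FeatureMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        d = f["features"]
        matrix = FeatureMatrix(d[...], str(d.attrs["extractor_id"]))
        stored = str(d.attrs.get("config_hash", ""))
    if stored and stored != _config_hash(matrix.extractor_id, matrix.dim):
        raise CompatibilityError(f"{path}: config hash mismatch")
    return matrix
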