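"""Underwater image enhancement and labelled-pixel patch extraction.

Water absorbs red light first, so raw benthic photographs are blue-green
shifted and low-contrast. The enhancement here is a per-channel percentile
stretch: the mean of the darkest 1% of intensities is subtracted (negatives
clipped to zero) and the channel is rescaled by the bright-tail mean, which
restores colour balance without any physical attenuation model.

Classification operates on fixed-size square patches centred on each
annotated pixel (224 x 224 by default). For an even patch size S the source
pixel sits at patch index (S/2, S/2); the patch spans the half-open ranges
[c - S/2, c + S/2) in each axis. Points near the border are completed by
mirror padding (edge-inclusive, so a corner patch is mirror-symmetric about
the image corner) or by constant fill.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, CoordinateError

__all__ = [
    "ImageRGB",
    "StretchParams",
    "Patch",
    "load_image",
    "save_image",
    "color_stretch",
    "extract_patch",
    "batch_patches",
]


@dataclass
class ImageRGB:
    """An H x W x 3 float image with intensities in [0, 1]."""

    pixels: np.ndarray
    image_id: str = ""

    def __post_init__(self):
        self.pixels = _check_rgb(self.pixels)


def _check_rgb(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ConfigurationError(f"expected H x W x 3 image, got shape {pixels.shape}")
    if np.issubdtype(pixels.dtype, np.integer):
        pixels = pixels.astype(np.float64) / np.iinfo(pixels.dtype).max
    else:
        pixels = pixels.astype(np.float64)
    if not np.isfinite(pixels).all():
        raise ConfigurationError("image contains non-finite values")
    return pixels


def load_image(path: str | Path, image_id: str | None = None) -> ImageRGB:
    """Read a PNG/JPEG/TIFF image, scaled to [0, 1] floats."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return ImageRGB(arr, image_id=image_id or Path(path).stem)


def save_image(image: ImageRGB, path: str | Path) -> None:
    import imageio.v3 as iio

    arr = np.clip(np.round(image.pixels * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


# ---------------------------------------------------------------------------
# Colour stretch
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StretchParams:
    """Parameters of the per-channel percentile stretch.

    ``low_tail``/``high_tail`` are the tail fractions whose means define the
    dark reference L and bright reference H. ``high_mode`` selects the
    reading of the bright reference: ``"tail"`` (default) averages the top
    ``high_tail`` fraction of intensities; ``"all_but_low"`` averages every
    intensity above the bottom tail. Channels flatter than ``eps`` after
    subtraction are returned as all zeros.
    """

    low_tail: float = 0.01
    high_tail: float = 0.01
    high_mode: str = "tail"
    eps: float = 1e-6

    def __post_init__(self):
        for t in (self.low_tail, self.high_tail):
            if not (0.0 < t < 0.5):
                raise ConfigurationError("tail fractions must lie in (0, 0.5)")
        if self.high_mode not in ("tail", "all_but_low"):
            raise ConfigurationError(f"unknown high_mode {self.high_mode!r}")


def _channel_tails(channel: np.ndarray, params: StretchParams) -> tuple[float, float]:
    flat = np.sort(channel, axis=None)
    n = flat.size
    k_low = int(np.ceil(params.low_tail * n))
    low = float(flat[:k_low].mean())
    if params.high_mode == "tail":
        k_high = int(np.ceil(params.high_tail * n))
        high = float(flat[n - k_high:].mean())
    else:
        high = float(flat[k_low:].mean()) if k_low < n else low
    return low, high


def color_stretch(image: ImageRGB, params: StretchParams | None = None) -> ImageRGB:
    """Percentile contrast stretch, each colour channel independently.

    Per channel: ``out = clip((I - L) / (H - L), 0, 1)`` where L and H are
    the dark- and bright-tail means. Monotone non-decreasing in the input
    and invariant to per-channel affine rescaling.
    """
    params = params or StretchParams()
    px = image.pixels
    out = np.zeros_like(px)
    for c in range(3):
        channel = px[:, :, c]
        low, high = _channel_tails(channel, params)
        denom = high - low
        if denom < params.eps:
            continue  # degenerate (near-constant) channel -> zeros
        out[:, :, c] = np.clip((channel - low) / denom, 0.0, 1.0)
    return ImageRGB(out, image_id=image.image_id)


# ---------------------------------------------------------------------------
# Patch extraction
# ---------------------------------------------------------------------------

@dataclass
class Patch:
    """S x S x 3 crop centred on an annotated pixel."""

    pixels: np.ndarray
    image_id: str
    x: int
    y: int

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


def _check_patch_size(size: int) -> None:
    if not (isinstance(size, (int, np.integer)) and size > 0 and size % 2 == 0):
        raise ConfigurationError(f"patch size must be a positive even integer, got {size!r}")


def extract_patch(
    image: ImageRGB,
    x: int,
    y: int,
    size: int = 224,
    pad: str = "reflect",
    fill: float = 0.0,
) -> Patch:
    """Extract the size x size patch centred at labelled pixel (x, y).

    The patch spans rows ``[y - size/2, y + size/2)`` and columns
    ``[x - size/2, x + size/2)``; ``patch[size/2, size/2]`` equals
    ``image[y, x]``. Out-of-image pixels are mirror-padded (``pad="reflect"``,
    edge pixels included in the mirror) or constant-filled (``pad="constant"``).
    """
    _check_patch_size(size)
    px = image.pixels
    h, w = px.shape[:2]
    if not (0 <= x < w and 0 <= y < h):
        raise CoordinateError(
            f"point ({x}, {y}) outside image {image.image_id!r} of size {w} x {h}"
        )
    half = size // 2
    r0, r1 = y - half, y + half
    c0, c1 = x - half, x + half
    pad_top = max(0, -r0)
    pad_bottom = max(0, r1 - h)
    pad_left = max(0, -c0)
    pad_right = max(0, c1 - w)
    if pad_top or pad_bottom or pad_left or pad_right:
        widths = ((pad_top, pad_bottom), (pad_left, pad_right), (0, 0))
        if pad == "reflect":
            padded = np.pad(px, widths, mode="symmetric")
        elif pad == "constant":
            padded = np.pad(px, widths, mode="constant", constant_values=fill)
        else:
            raise ConfigurationError(f"unknown pad mode {pad!r}")
        out = padded[r0 + pad_top : r1 + pad_top, c0 + pad_left : c1 + pad_left]
    else:
        out = px[r0:r1, c0:c1]
    return Patch(np.ascontiguousarray(out), image.image_id, int(x), int(y))


def batch_patches(
    image: ImageRGB,
    points: list[tuple[int, int]],
    size: int = 224,
    pad: str = "reflect",
    fill: float = 0.0,
) -> list[Patch]:
    """`extract_patch` over a point list, order preserved.

    A coordinate error on any point is re-raised with the point's index.
    """
    patches = []
    for i, (x, y) in enumerate(points):
        try:
            patches.append(extract_patch(image, x, y, size=size, pad=pad, fill=fill))
        except CoordinateError as exc:
            raise CoordinateError(f"point {i}: {exc}") from exc
    return patches
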