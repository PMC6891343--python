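"""Leaf area from scaled RGB images.

Two paths to the projected blade area L_A (cm^2):

* the manual workflow — set a physical scale from a ruler in the image,
  outline the blade with a polygon, apply the shoelace formula — mirroring
  the usual ImageJ set-scale/polygon routine;
* an automatic path that segments the blade by a greenness index, keeps the
  largest connected component and fills interior holes.

Pixel convention: 0-based, origin top-left, x = column, y = row; polygon
vertices are pixel centers. Only planar (projected) area is computed; leaf
curvature is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage
from shapely.geometry import Polygon
from skimage.filters import threshold_otsu

from .errors import DomainError, GeometryError, SegmentationError

__all__ = [
    "LeafImage",
    "LeafMask",
    "calibrate_scale",
    "polygon_area",
    "segment_leaf",
    "mask_area",
    "load_image",
    "save_mask",
]


@dataclass
class LeafImage:
    """H x W x 3 8-bit raster with a physical scale (cm per pixel)."""

    pixels: np.ndarray
    cm_per_px: float
    outline: np.ndarray | None = None  # (N, 2) array of (x, y) pixel vertices

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise DomainError("pixels must be an H x W x 3 raster")
        if self.cm_per_px <= 0:
            raise DomainError("cm_per_px must be strictly positive")


@dataclass
class LeafMask:
    """Boolean foreground raster with the same physical scale as its image."""

    mask: np.ndarray
    cm_per_px: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise DomainError("mask must be 2-D")
        if self.cm_per_px <= 0:
            raise DomainError("cm_per_px must be strictly positive")


def calibrate_scale(pixel_length: float, real_length: float) -> float:
    """cm per pixel from a known length: real_length / pixel_length."""
    if pixel_length <= 0 or real_length <= 0:
        raise DomainError("pixel and real lengths must be strictly positive")
    return real_length / pixel_length


def polygon_area(outline, cm_per_px: float) -> float:
    """Area (cm^2) of a simple polygon outline by the shoelace formula.

    Orientation-independent (absolute value). Self-intersecting outlines
    are rejected — a bowtie traced around a leaf is an operator error, not
    a measurable blade.
    """
    if cm_per_px <= 0:
        raise DomainError("cm_per_px must be strictly positive")
    pts = np.asarray(outline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise GeometryError("outline must be an (N>=3) x 2 vertex list")
    if not np.all(np.isfinite(pts)):
        raise GeometryError("outline vertices must be finite")
    if not Polygon(pts).is_valid:
        raise GeometryError("outline is self-intersecting or degenerate")
    x, y = pts[:, 0], pts[:, 1]
    px_area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))
    return px_area * cm_per_px**2


def _greenness_index(pixels: np.ndarray, method: str) -> tuple[np.ndarray, bool]:
    """Index image and whether foreground is the high side of the threshold."""
    rgb = pixels.astype(float)
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    if method == "excess_green":
        return 2.0 * g - r - b, True
    if method == "otsu_green":
        # leaf darker than a light background in the green channel
        return g, False
    raise ValueError(f"unknown method {method!r}; expected 'excess_green' or 'otsu_green'")


def segment_leaf(
    image: LeafImage,
    method: str = "excess_green",
    min_component_px: int = 64,
) -> LeafMask:
    """Automatic blade segmentation.

    Thresholds a greenness index (excess-green 2G-R-B by default) with
    Otsu's method, keeps the largest 8-connected component and fills
    interior holes — leaves are simply connected, so specular highlights
    must not punch holes in the mask.
    """
    if image.pixels.size == 0:
        raise SegmentationError("empty raster")
    idx, fg_high = _greenness_index(image.pixels, method)
    if np.ptp(idx) == 0:
        raise SegmentationError("image has no contrast in the greenness index")
    thr = threshold_otsu(idx)
    fg = idx > thr if fg_high else idx < thr
    labels, n_labels = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n_labels == 0:
        raise SegmentationError("no foreground component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_labels + 1))
    largest = int(np.argmax(sizes)) + 1
    if sizes[largest - 1] < min_component_px:
        raise SegmentationError(
            f"largest component has {int(sizes[largest - 1])} px < {min_component_px}"
        )
    mask = ndimage.binary_fill_holes(labels == largest)
    return LeafMask(mask=mask, cm_per_px=image.cm_per_px)


def mask_area(mask: LeafMask) -> float:
    """Foreground pixel count times cm_per_px^2, in cm^2."""
    n = int(mask.mask.sum())
    if n == 0:
        raise SegmentationError("mask has no foreground pixels")
    return n * mask.cm_per_px**2


def load_image(path, cm_per_px: float) -> LeafImage:
    """Read a PNG/TIFF/JPEG file as an RGB LeafImage at a known scale."""
    with Image.open(path) as im:
        pixels = np.asarray(im.convert("RGB"))
    return LeafImage(pixels=pixels, cm_per_px=cm_per_px)


def save_mask(mask: LeafMask, path) -> None:
    """Write a mask as an 8-bit PNG (foreground 255, background 0)."""
    Image.fromarray(mask.mask.astype(np.uint8) * 255).save(path, format="PNG")
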