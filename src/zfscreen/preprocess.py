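"""Larva localization and square cropping.

Raw well images show a single dark larva (or chorionated / dead embryo) on a
bright background. The classifier expects the animal centered in a square
crop, so localization proceeds by classical morphology: a neighborhood
variance filter highlights object edges, the variance image is binarized with
Otsu's global threshold, two dilations close the outline, and the largest
8-connected component is taken to be the larva. Round objects (embryos still
in the chorion) are cropped by their tight bounding square; elongated larvae
by a square of side max(h, w) centered on the bounding box, clipped to the
image when the animal sits near a border.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

#: 8-connectivity structuring element shared by dilation and labeling.
_SQUARE3 = np.ones((3, 3), dtype=bool)


class NoObjectError(ValueError):
    """Raised when no foreground object can be separated from the background."""


@dataclass(frozen=True)
class LarvaRegion:
    """Bounding box and size of a detected larva.

    The box is 0-based and half-open: rows ``row_min .. row_max-1`` and
    columns ``col_min .. col_max-1`` are inside the region.
    """

    row_min: int
    col_min: int
    row_max: int
    col_max: int
    area: int

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("region area must be positive")
        if self.row_max <= self.row_min or self.col_max <= self.col_min:
            raise ValueError("empty bounding box")

    @property
    def height(self) -> int:
        return self.row_max - self.row_min

    @property
    def width(self) -> int:
        return self.col_max - self.col_min

    @property
    def aspect_ratio(self) -> float:
        """max(h, w) / min(h, w), always >= 1."""
        h, w = self.height, self.width
        return max(h, w) / min(h, w)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Collapse an RGB image to grayscale by the unweighted channel mean.

    Larvae are dark against a bright background in every channel, so no
    luminance weighting is needed for localization.
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    elif arr.ndim != 2:
        raise ValueError(f"expected 2-D or 3-D image, got shape {arr.shape}")
    return arr


def variance_filter(img: np.ndarray, radius: int = 2) -> np.ndarray:
    """Replace each pixel by the population variance of its neighborhood.

    The window is the (2*radius+1)^2 square around each pixel. A border ring
    of width ``radius`` (where the window would not fit) is set to 0, so only
    full-window responses survive.

    Parameters
    ----------
    img
        Grayscale image; RGB input is first collapsed by channel mean.
    radius
        Neighborhood radius in pixels, >= 1.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    gray = to_grayscale(img)
    # var = E[x^2] - E[x]^2 over the full window; uniform_filter computes the
    # exact full-window mean for interior pixels (mode only affects the ring
    # we zero out anyway).
    mean = ndimage.uniform_filter(gray, size=2 * radius + 1, mode="nearest")
    mean_sq = ndimage.uniform_filter(gray * gray, size=2 * radius + 1, mode="nearest")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    var[:radius, :] = 0.0
    var[-radius:, :] = 0.0
    var[:, :radius] = 0.0
    var[:, -radius:] = 0.0
    return var


def binarize(img: np.ndarray) -> np.ndarray:
    """Threshold a grayscale image into a foreground mask with Otsu's method.

    Returns a boolean mask, true where the intensity exceeds the threshold.
    A constant image has no separable object: the result is all-false and a
    warning is emitted.
    """
    gray = to_grayscale(img)
    if gray.size == 0:
        raise ValueError("empty image")
    lo, hi = gray.min(), gray.max()
    if lo == hi:
        warnings.warn("constant image: no object separable", stacklevel=2)
        return np.zeros(gray.shape, dtype=bool)
    thr = threshold_otsu(gray)
    mask = gray > thr
    if not mask.any():  # pragma: no cover - Otsu always leaves the max above
        mask = gray == hi
    return mask


def dilate(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Binary dilation with a 3x3 square element, applied ``iterations`` times."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if iterations == 0:
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=_SQUARE3, iterations=iterations)


def largest_component(mask: np.ndarray) -> LarvaRegion:
    """Bounding box and area of the largest 8-connected component.

    Ties on area are broken by the lexicographically smallest
    (row_min, col_min) so the result is deterministic.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoObjectError("empty mask: no object found")
    labels, n = ndimage.label(mask, structure=_SQUARE3)
    areas = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1)).astype(int)
    slices = ndimage.find_objects(labels)
    best = None
    best_key = None
    for area, sl in zip(areas, slices):
        key = (-area, sl[0].start, sl[1].start)
        if best_key is None or key < best_key:
            best_key = key
            best = (area, sl)
    area, (rs, cs) = best
    return LarvaRegion(rs.start, cs.start, rs.stop, cs.stop, int(area))


def square_crop(
    img: np.ndarray, region: LarvaRegion, circular_ratio_max: float = 1.2
) -> np.ndarray:
    """Crop the image to a square around the detected region.

    Near-circular regions (aspect ratio <= ``circular_ratio_max``, e.g. an
    embryo still inside its chorion) get their tight bounding square;
    elongated larvae get a square of side max(h, w) centered on the bounding
    box. A square that would exceed the image is clipped to a rectangle, so
    the crop always contains the full bounding box.
    """
    img = np.asarray(img)
    H, W = img.shape[:2]
    if not (0 <= region.row_min < region.row_max <= H and 0 <= region.col_min < region.col_max <= W):
        raise ValueError("region outside image bounds")
    side = max(region.height, region.width)
    if region.aspect_ratio <= circular_ratio_max:
        # tight bounding square: expand the smaller dimension symmetrically
        r0 = region.row_min - (side - region.height) // 2
        c0 = region.col_min - (side - region.width) // 2
    else:
        rc = (region.row_min + region.row_max) / 2.0
        cc = (region.col_min + region.col_max) / 2.0
        r0 = int(round(rc - side / 2.0))
        c0 = int(round(cc - side / 2.0))
    r1, c1 = r0 + side, c0 + side
    # never cut into the bbox while pulling the window back inside the image
    r0 = min(max(r0, 0), region.row_min)
    c0 = min(max(c0, 0), region.col_min)
    r1 = max(min(r1, H), region.row_max)
    c1 = max(min(c1, W), region.col_max)
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, H), min(c1, W)
    return img[r0:r1, c0:c1]


@dataclass(frozen=True)
class CropParams:
    """Knobs of the localization pipeline (all have sensible defaults)."""

    radius: int = 2
    dilations: int = 2
    circular_ratio_max: float = 1.2


def locate_and_crop(
    img: np.ndarray, params: CropParams | None = None
) -> np.ndarray:
    """Find the larva and return the square crop around it.

    Composition of :func:`variance_filter`, :func:`binarize`, two
    :func:`dilate` passes, :func:`largest_component` and
    :func:`square_crop`; deterministic for a fixed input.

    Raises
    ------
    NoObjectError
        If the image contains no separable foreground object.
    """
    p = params or CropParams()
    var = variance_filter(img, radius=p.radius)
    if var.max() == var.min():
        raise NoObjectError("blank image: no edges found")
    mask = binarize(var)
    mask = dilate(mask, iterations=p.dilations)
    region = largest_component(mask)
    return square_crop(img, region, circular_ratio_max=p.circular_ratio_max)


def locate_region(img: np.ndarray, params: CropParams | None = None) -> LarvaRegion:
    """Like :func:`locate_and_crop` but return the detected region only."""
    p = params or CropParams()
    var = variance_filter(img, radius=p.radius)
    if var.max() == var.min():
        raise NoObjectError("blank image: no edges found")
    mask = binarize(var)
    mask = dilate(mask, iterations=p.dilations)
    return largest_component(mask)
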