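"""Random subwindow sampling and TRGB patch encoding.

An image is described by a cloud of square subwindows drawn at random
positions with side lengths uniform between ``min_frac`` and ``max_frac`` of
the smaller image dimension. Each subwindow is resized bilinearly to a fixed
16x16 patch and standardized per RGB channel (subtract mean, divide by
population standard deviation — "TRGB"), giving a 768-attribute vector
(16*16*3) laid out channel-planar (all R, then G, then B) so spatial
neighbor indexing is well defined downstream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

PATCH_SIDE = 16
N_CHANNELS = 3
#: Attributes per patch vector: 16*16 pixels x 3 channels = 768.
N_ATTRIBUTES = PATCH_SIDE * PATCH_SIDE * N_CHANNELS


@dataclass(frozen=True)
class SubwindowSpec:
    """A square subwindow: top-left corner (row, col) and side length in px."""

    row: int
    col: int
    side: int

    def __post_init__(self) -> None:
        if self.side < 2:
            raise ValueError("subwindow side must be >= 2")
        if self.row < 0 or self.col < 0:
            raise ValueError("subwindow corner must be non-negative")


@dataclass(frozen=True)
class SamplerParams:
    """Subwindow sampling configuration.

    ``min_frac``/``max_frac`` bound the side length as a fraction of the
    smaller image dimension; ``n_subwindows`` defaults to the standard 1000
    per image.
    """

    n_subwindows: int = 1000
    min_frac: float = 0.5
    max_frac: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.min_frac <= self.max_frac <= 1):
            raise ValueError("require 0 <= min_frac <= max_frac <= 1")
        if self.n_subwindows < 1:
            raise ValueError("n_subwindows must be >= 1")


def image_rng(seed: int, image_id: int | str) -> np.random.Generator:
    """RNG substream for one image, derived from (global seed, image id).

    Using a per-image stream makes per-image subwindows independent of the
    order in which images are processed. String ids are hashed with CRC32.
    """
    if isinstance(image_id, str):
        image_id = zlib.crc32(image_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=(int(image_id),)))


def sample_subwindows(
    img: np.ndarray,
    params: SamplerParams,
    rng: np.random.Generator | None = None,
    image_id: int | str = 0,
) -> list[SubwindowSpec]:
    """Draw ``n_subwindows`` random square subwindows fully inside the image.

    Side lengths are uniform on [min_frac*m, max_frac*m] with
    m = min(H, W); positions are uniform among in-bounds placements.
    """
    img = np.asarray(img)
    H, W = img.shape[:2]
    m = min(H, W)
    lo = params.min_frac * m
    hi = params.max_frac * m
    if lo < 2 and hi < 2:
        raise ValueError(f"image too small: min side {lo:.1f} < 2 px")
    if rng is None:
        rng = image_rng(params.seed, image_id)
    sides_f = rng.uniform(lo, hi, size=params.n_subwindows)
    sides = np.maximum(np.floor(sides_f).astype(int), 2)
    sides = np.minimum(sides, m)
    rows = rng.integers(0, H - sides + 1)
    cols = rng.integers(0, W - sides + 1)
    return [
        SubwindowSpec(int(r), int(c), int(s))
        for r, c, s in zip(rows, cols, sides)
    ]


def _resize_coords(side: int) -> np.ndarray:
    """Source coordinates of the target pixel centers along one axis."""
    scale = side / PATCH_SIDE
    coords = (np.arange(PATCH_SIDE) + 0.5) * scale - 0.5
    return np.clip(coords, 0.0, side - 1.0)


def extract_patch(img: np.ndarray, spec: SubwindowSpec) -> np.ndarray:
    """Crop a subwindow and resize it bilinearly to a fixed square patch.

    A source window already at the patch size is returned unchanged (the
    resize is the identity there).
    """
    return extract_patches(img, [spec])[0]


def extract_patches(img: np.ndarray, specs: list[SubwindowSpec]) -> np.ndarray:
    """Vectorized :func:`extract_patch` for many subwindows of one image.

    Returns an array of shape (n, 16, 16, 3). All target pixel centers of all
    windows are interpolated in a single ``map_coordinates`` call per channel,
    which is what makes dense sampling (1000 windows/image) affordable.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim == 2:
        img = img[:, :, None].repeat(N_CHANNELS, axis=2)
    H, W = img.shape[:2]
    n = len(specs)
    rows = np.empty((n, PATCH_SIDE, PATCH_SIDE))
    cols = np.empty((n, PATCH_SIDE, PATCH_SIDE))
    for i, sp in enumerate(specs):
        if sp.row + sp.side > H or sp.col + sp.side > W:
            raise ValueError(f"subwindow {sp} outside image {H}x{W}")
        c = _resize_coords(sp.side)
        rows[i] = sp.row + c[:, None]
        cols[i] = sp.col + c[None, :]
    coords = np.stack([rows.ravel(), cols.ravel()])
    out = np.empty((n, PATCH_SIDE, PATCH_SIDE, img.shape[2]))
    for ch in range(img.shape[2]):
        vals = ndimage.map_coordinates(img[:, :, ch], coords, order=1, mode="nearest")
        out[:, :, :, ch] = vals.reshape(n, PATCH_SIDE, PATCH_SIDE)
    return out


def trgb_normalize(patch: np.ndarray) -> np.ndarray:
    """Standardize a 16x16x3 patch per channel and flatten channel-planar.

    Each channel is centered on its mean and scaled by its population
    standard deviation; a constant channel (std 0) maps to all zeros. The
    result is the 768-long attribute vector (all R pixels, then G, then B).
    """
    return trgb_normalize_many(patch[None])[0]


def trgb_normalize_many(patches: np.ndarray) -> np.ndarray:
    """Vectorized :func:`trgb_normalize`: (n, 16, 16, 3) -> (n, 768)."""
    p = np.asarray(patches, dtype=np.float64)
    mean = p.mean(axis=(1, 2), keepdims=True)
    std = p.std(axis=(1, 2), keepdims=True)  # population std
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (p - mean) / std
    z[np.broadcast_to(std == 0, z.shape)] = 0.0
    # channel-planar layout: (n, ch, row, col) flattened
    return z.transpose(0, 3, 1, 2).reshape(p.shape[0], -1)


def image_features(
    img: np.ndarray,
    params: SamplerParams,
    image_id: int | str = 0,
) -> np.ndarray:
    """Sample, extract and normalize: the (n_subwindows, 768) descriptor cloud."""
    specs = sample_subwindows(img, params, image_id=image_id)
    patches = extract_patches(img, specs)
    return trgb_normalize_many(patches)
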