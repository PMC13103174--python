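"""Background image synthesis and modality-preprocessing primitives.

Detector-style training data for burned-in text uses two kinds of
backgrounds: plain synthetic canvases (uniform grayscale with optional
shaded boxes) and real-modality rasters prepared by a handful of generic
array operations — percentile-clipped 8-bit min-max normalization for CT/MR
volumes, uniform axial slice sampling, side-by-side collages mimicking a
bone-scan viewer, and center cropping to strip physical edge markers from
chest X-rays. The operations here are plain numpy transforms so they run on
any array; tests exercise them on synthetic stand-ins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidRequestError, InvalidSizeError

__all__ = [
    "BackgroundImage",
    "make_synthetic_background",
    "minmax_to_8bit",
    "sample_axial_slices",
    "make_collage",
    "center_crop",
]

MIN_SIDE = 64


@dataclass
class BackgroundImage:
    """An 8-bit raster (H×W grayscale or H×W×3) with a modality tag."""

    pixels: np.ndarray
    modality_tag: str = "synthetic"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != np.uint8:
            raise InvalidSizeError("background pixels must be 8-bit (uint8)")
        if self.pixels.ndim not in (2, 3):
            raise InvalidSizeError("background must be 2-D or 3-channel")
        h, w = self.pixels.shape[:2]
        if h < 1 or w < 1:
            raise InvalidSizeError(f"background must be non-empty, got {w}×{h}")

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


def make_synthetic_background(width: int, height: int,
                              rng: np.random.Generator | int | None = None,
                              n_boxes: int = 0,
                              modality_tag: str = "synthetic") -> BackgroundImage:
    """Plain grayscale canvas with ``n_boxes`` filled rectangles in shades
    distinct from the base shade.

    Boxes are placed without mutual overlap (2 px gap) so each remains an
    identifiable component; placement is retried a bounded number of times
    and degrades to fewer attempts only via the retry budget, never silently
    overlapping. Deterministic under a fixed seed.
    """
    if width < MIN_SIDE or height < MIN_SIDE:
        raise InvalidSizeError(f"canvas must be at least {MIN_SIDE} px per side")
    if n_boxes < 0:
        raise InvalidSizeError("n_boxes must be non-negative")
    rng = np.random.default_rng(rng)
    base = int(rng.integers(0, 256))
    canvas = np.full((height, width), base, dtype=np.uint8)

    placed: list[tuple[int, int, int, int]] = []
    for _ in range(n_boxes):
        for _attempt in range(600):
            # shrink the size budget as placement attempts fail so a crowded
            # canvas still fits its box count
            divisor = 2 * 2 ** (_attempt // 200)
            bw = int(rng.integers(width // 16, max(width // divisor, width // 16 + 1)))
            bh = int(rng.integers(height // 16, max(height // divisor, height // 16 + 1)))
            x0 = int(rng.integers(0, width - bw))
            y0 = int(rng.integers(0, height - bh))
            box = (x0, y0, x0 + bw, y0 + bh)
            if all(box[2] + 2 <= p[0] or p[2] + 2 <= box[0]
                   or box[3] + 2 <= p[1] or p[3] + 2 <= box[1]
                   for p in placed):
                break
        else:
            raise InvalidSizeError(
                f"could not place {n_boxes} non-overlapping boxes on {width}×{height}")
        # shade at least 20 levels away from the base so the box is visible
        lo, hi = max(0, base - 20), min(255, base + 20)
        shade = int(rng.integers(0, 256 - (hi - lo)))
        if shade >= lo:
            shade += hi - lo
        canvas[box[1]:box[3], box[0]:box[2]] = shade
        placed.append(box)
    return BackgroundImage(canvas, modality_tag)


def minmax_to_8bit(array: np.ndarray,
                   rng: np.random.Generator | int | None = None,
                   low_percentile_max: float = 10.0) -> np.ndarray:
    """Min-max normalize an intensity array to 8-bit, clipping below a random
    low percentile.

    A percentile ``p`` is drawn uniformly in ``[0, low_percentile_max]``; the
    p-th percentile value becomes the new minimum, values below it are
    clipped, and ``[min, max]`` maps linearly onto ``[0, 255]``. A constant
    array (or one whose chosen minimum equals its maximum) maps to all zeros.
    """
    a = np.asarray(array, dtype=np.float64)
    if a.size == 0:
        raise InvalidRequestError("cannot normalize an empty array")
    rng = np.random.default_rng(rng)
    p = float(rng.uniform(0.0, low_percentile_max))
    lo = float(np.percentile(a, p))
    hi = float(a.max())
    if hi <= lo:
        return np.zeros(a.shape, dtype=np.uint8)
    scaled = (np.clip(a, lo, hi) - lo) / (hi - lo) * 255.0
    return np.rint(scaled).astype(np.uint8)


def sample_axial_slices(volume: np.ndarray, k: int) -> list[np.ndarray]:
    """Uniformly sample ``k`` axial (leading-axis) slices from a volume.

    Indices are ``linspace(0, depth-1, k)`` rounded half-down, inclusive of
    both endpoints; ``k = depth`` returns every slice exactly once.
    """
    vol = np.asarray(volume)
    if vol.ndim < 3:
        raise InvalidRequestError("volume must be 3-D")
    depth = vol.shape[0]
    if k < 1 or k > depth:
        raise InvalidRequestError(f"cannot sample {k} slices from depth {depth}")
    positions = np.linspace(0, depth - 1, k)
    indices = [int(np.ceil(x - 0.5)) for x in positions]  # round half down
    return [vol[i] for i in indices]


def make_collage(image: BackgroundImage,
                 rng: np.random.Generator | int | None = None,
                 flip_prob: float = 0.5) -> BackgroundImage:
    """Horizontal collage of 3–5 copies of the input, each independently
    intensity-inverted (``255 − v``) with probability ``flip_prob``.

    Mimics a bone-scan viewer showing several whole-body views side by side,
    with display-polarity variants.
    """
    rng = np.random.default_rng(rng)
    n = int(rng.integers(3, 6))
    tiles = []
    for _ in range(n):
        tile = image.pixels
        if rng.random() < flip_prob:
            tile = (255 - tile.astype(np.int16)).astype(np.uint8)
        tiles.append(tile)
    return BackgroundImage(np.concatenate(tiles, axis=1), image.modality_tag)


def center_crop(image: BackgroundImage, fraction: float) -> BackgroundImage:
    """Centered crop keeping ``fraction`` of each side (dimensions floored)."""
    if not 0.0 < fraction <= 1.0:
        raise InvalidSizeError(f"crop fraction must be in (0, 1], got {fraction}")
    h, w = image.pixels.shape[:2]
    nh, nw = int(h * fraction), int(w * fraction)
    if nh < 1 or nw < 1:
        raise InvalidSizeError("crop would produce an empty image")
    y0, x0 = (h - nh) // 2, (w - nw) // 2
    return BackgroundImage(image.pixels[y0:y0 + nh, x0:x0 + nw].copy(),
                           image.modality_tag)
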