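"""Image conditioning: block-max downsampling, square-root quantization and
beam-anchored quadrant extraction.

Raw detector frames are large (up to ~18 Mpixel) and span a huge dynamic
range.  Before a frame is shown to a model it is conditioned in a fixed
order:

1. ``maxpool_downsample`` - raw pixels are grouped into ``N x N`` blocks
   and each block is replaced by its maximum (preserves sharp Bragg peaks,
   unlike mean pooling);
2. ``sqrt_quantize`` - block values are replaced by the floor of their
   square root (approximate variance stabilization for counting noise);
3. ``extract_quadrants`` - four 512 x 512 sub-arrays are cut around the
   beam center, each flipped so that element (0, 0) sits at the beam
   center and the scattering angle grows with either index.

The same conditioning is applied to simulated and experimental frames.
Masked pixels carry a ``-1`` sentinel that survives pooling (a block that
is entirely masked stays ``-1``) and quantization; padding beyond the
detector edge is 0 (no signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeometryContext, GeometryError

__all__ = [
    "MASK_SENTINEL",
    "QUADRANT_ORDER",
    "ConditionedQuadrant",
    "maxpool_downsample",
    "sqrt_quantize",
    "extract_quadrants",
    "max_composite",
    "condition_image",
]

MASK_SENTINEL = -1
QUADRANT_ORDER = ("UL", "UR", "LL", "LR")
QUADRANT_SIZE = 512


@dataclass(frozen=True)
class ConditionedQuadrant:
    """A beam-anchored, conditioned 512 x 512 sub-array.

    ``pixels[0, 0]`` is the conditioned pixel adjacent to the beam center;
    radius grows with both indices.  ``quadrant_id`` is one of
    ``("UL", "UR", "LL", "LR")`` in array-memory convention (row 0 is
    "upper").
    """

    pixels: np.ndarray
    quadrant_id: str
    effective_pixel_mm: float
    geometry: GeometryContext | None = None

    def __post_init__(self) -> None:
        if self.pixels.shape != (QUADRANT_SIZE, QUADRANT_SIZE):
            raise ValueError("conditioned quadrant must be 512 x 512")
        if self.quadrant_id not in QUADRANT_ORDER:
            raise ValueError(f"unknown quadrant id {self.quadrant_id!r}")


def maxpool_downsample(raw: np.ndarray, n: int) -> np.ndarray:
    """Block-max downsample by ``n``: output dims are ``ceil(dims / n)``.

    Partial edge blocks reduce over the available pixels.  The ``-1`` mask
    sentinel acts as the minimum, so any unmasked pixel in a block wins and
    an all-masked block stays ``-1``.
    """
    if n <= 0:
        raise ValueError("downsample factor must be >= 1")
    raw = np.asarray(raw)
    if raw.ndim != 2 or raw.size == 0:
        raise ValueError("raw image must be a non-empty 2-D array")
    if n == 1:
        return raw.copy()
    h, w = raw.shape
    ph, pw = (-h) % n, (-w) % n
    # pad with the sentinel: it never beats a real pixel in a max and keeps
    # edge blocks equivalent to reducing over available pixels only
    padded = np.pad(raw, ((0, ph), (0, pw)), constant_values=MASK_SENTINEL)
    hb, wb = padded.shape[0] // n, padded.shape[1] // n
    return padded.reshape(hb, n, wb, n).max(axis=(1, 3))


def sqrt_quantize(x: np.ndarray) -> np.ndarray:
    """Replace each value by ``floor(sqrt(value))``, as an integer array.

    The ``-1`` mask sentinel passes through unchanged; any other negative
    value violates the contract.
    """
    x = np.asarray(x)
    neg = x < 0
    if np.any(neg & (x != MASK_SENTINEL)):
        raise ValueError("values must be >= 0 or the -1 mask sentinel")
    out = np.floor(np.sqrt(np.where(neg, 0, x).astype(float))).astype(np.int64)
    out[neg] = MASK_SENTINEL
    return out


def _anchor(block: np.ndarray, flip_slow: bool, flip_fast: bool) -> np.ndarray:
    if flip_slow:
        block = block[::-1, :]
    if flip_fast:
        block = block[:, ::-1]
    out = np.zeros((QUADRANT_SIZE, QUADRANT_SIZE), dtype=block.dtype)
    h = min(block.shape[0], QUADRANT_SIZE)
    w = min(block.shape[1], QUADRANT_SIZE)
    out[:h, :w] = block[:h, :w]
    return out


def extract_quadrants(ds_image: np.ndarray, geometry: GeometryContext,
                      margin_px: float = 64.0) -> list[ConditionedQuadrant]:
    """Cut four beam-anchored 512 x 512 quadrants from a downsampled image.

    The beam center (raw-pixel units in ``geometry``) is converted to the
    downsampled grid and rounded to the nearest block-pixel boundary; the
    four quadrants partition the image there, each flipped so its (0, 0)
    element touches the beam center.  Regions past the detector edge are
    zero-padded; regions beyond 512 elements are truncated.  A beam center
    off the detector face by more than ``margin_px`` (downsampled pixels)
    raises :class:`GeometryError`.
    """
    ds_image = np.asarray(ds_image)
    if ds_image.ndim != 2:
        raise ValueError("downsampled image must be 2-D")
    det = geometry.detector
    n = det.downsample
    cs = geometry.beam.center_slow_px / n
    cf = geometry.beam.center_fast_px / n
    h, w = ds_image.shape
    if not (-margin_px <= cs <= h + margin_px and -margin_px <= cf <= w + margin_px):
        raise GeometryError("beam center too far off the detector face")
    # split index: the beam center falls on the boundary between the last
    # "upper/left" pixel and the first "lower/right" pixel
    si = int(np.clip(round(cs), 0, h))
    fi = int(np.clip(round(cf), 0, w))
    eff = det.effective_pixel_mm
    blocks = {
        "UL": _anchor(ds_image[:si, :fi], True, True),
        "UR": _anchor(ds_image[:si, fi:], True, False),
        "LL": _anchor(ds_image[si:, :fi], False, True),
        "LR": _anchor(ds_image[si:, fi:], False, False),
    }
    return [ConditionedQuadrant(blocks[q], q, eff, geometry)
            for q in QUADRANT_ORDER]


def max_composite(images) -> np.ndarray:
    """Element-wise maximum across a set of equal-shape images."""
    images = [np.asarray(im) for im in images]
    if not images:
        raise ValueError("need at least one image")
    shape = images[0].shape
    if any(im.shape != shape for im in images):
        raise ValueError("all images must share a shape")
    out = images[0].copy()
    for im in images[1:]:
        np.maximum(out, im, out=out)
    return out


def condition_image(raw: np.ndarray, geometry: GeometryContext,
                    quadrants: int = 4) -> list[ConditionedQuadrant]:
    """Full conditioning pipeline: maxpool -> sqrt/floor -> quadrants.

    ``quadrants=1`` returns only the first (UL) quadrant, the fast path
    used for monitoring; ``quadrants=4`` returns all four.
    """
    if quadrants not in (1, 4):
        raise ValueError("quadrants must be 1 or 4")
    ds = maxpool_downsample(raw, geometry.detector.downsample)
    q = sqrt_quantize(ds)
    out = extract_quadrants(q, geometry)
    return out[:quadrants]
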