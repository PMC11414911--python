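"""Binary opening with square structuring elements and granulometric level maps.

Opening here acts on the WHITE pixel set (erosion then dilation), so the
black set — the structure — can only grow: K(f) ⊆ K(O_{S_i}(f)).  A white
pixel survives the opening by S_i iff some (i+1)x(i+1) all-white window
contains it; isolated white regions too small to hold such a window are
removed.  Pixels outside the image frame count as white, so the frame never
seals a structure by itself.

The family S_0 ⊆ S_1 ⊆ ... of squares is a granulometry: openings are
idempotent, anti-extensive on white, and monotone in the element index,
which makes K(O_{S_0}(f)) ⊆ K(O_{S_1}(f)) ⊆ ... a filtration (the vertical
axis of the bifiltration).  The position of the element's origin is
irrelevant: opening is invariant under translation of the structuring
element.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster import BinaryImage

__all__ = [
    "StructuringElement",
    "opening",
    "opening_level_map",
    "INF_LEVEL",
]

#: Sentinel for "never enters the filtration" (kept below 2**31).
INF_LEVEL: int = 2**31 - 1


@dataclass(frozen=True)
class StructuringElement:
    """The square structuring element S_i, an (i+1) x (i+1) window."""

    index: int

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("structuring element index must be >= 0")

    @property
    def side(self) -> int:
        return self.index + 1


def _opened_white(white: np.ndarray, k: int) -> np.ndarray:
    """White mask after opening with a k x k square; outside the frame is white.

    Erosion/dilation are run on an array padded with white, with an explicit
    anchor correction for even k (scipy centers footprints at floor(k/2), so
    the min-then-max composition is offset by one pixel per axis there).
    """
    if k == 1:
        return white
    h, w = white.shape
    pad = np.pad(white, k, constant_values=True).astype(np.uint8)
    eroded = ndimage.minimum_filter(pad, size=k, mode="nearest")
    dilated = ndimage.maximum_filter(eroded, size=k, mode="nearest")
    s = k + (0 if k % 2 else 1)
    return dilated[s : s + h, s : s + w].astype(bool)


def opening(f: BinaryImage, se: StructuringElement) -> BinaryImage:
    """O_{S_i}(f): morphological opening of the white set of ``f`` by ``se``.

    S_0 is the identity; the operation is idempotent, and the black set of
    the result contains K(f).
    """
    white = f.values.astype(bool)
    opened = _opened_white(white, se.side)
    return BinaryImage(opened.astype(np.uint8))


def opening_level_map(f: BinaryImage, max_i: int = 20) -> np.ndarray:
    """Per-pixel first opening index at which the pixel is black.

    Returns an int64 array L with ``L[p] = min{ i : p in K(O_{S_i}(f)) }``
    and :data:`INF_LEVEL` where the pixel is still white after S_max_i.  The
    sublevel set ``L <= i`` reproduces K(O_{S_i}(f)) bit-exactly — this is
    the vertical (opening) filtration of the bifiltration as a single
    integer-valued function.
    """
    if max_i < 0:
        raise ValueError("max_i must be >= 0")
    white = f.values.astype(bool)
    levels = np.full(f.shape, INF_LEVEL, dtype=np.int64)
    levels[~white] = 0
    remaining = white
    for i in range(1, max_i + 1):
        if not remaining.any():
            break
        opened = _opened_white(white, i + 1)
        newly_black = remaining & ~opened
        levels[newly_black] = i
        remaining = remaining & opened
    return levels
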