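"""Grayscale / binary raster handling with black-set semantics.

The analysis convention throughout the package: images are 2-D integer
arrays indexed ``(row, col)``, 0-based.  In a binary image the value 0 is
*black* and marks the structure of interest; the set of black pixels is the
cubical complex every topological computation works on.  Thresholding a
grayscale image at level ``t`` blackens every pixel with intensity <= t, so
black sets are nested as ``t`` grows (a sublevel-set filtration).

Fluorescence micrographs are bright-on-dark; they must be intensity-inverted
before thresholding so that the structure is dark.  :func:`load_grayscale`
exposes this via ``invert=True`` and the CLI defaults to inverting ``.tif``
input.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GrayscaleImage",
    "BinaryImage",
    "load_grayscale",
    "threshold",
    "black_set",
]

#: ITU-R BT.601 luma weights used for RGB -> gray conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class GrayscaleImage:
    """An 8-bit grayscale image ``g : P -> {0, ..., 255}``."""

    values: np.ndarray  # 2-D uint8

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.size == 0:
            raise ValueError(f"expected a non-empty 2-D array, got shape {v.shape}")
        if v.dtype != np.uint8:
            if np.any((v < 0) | (v > 255)):
                raise ValueError("grayscale values must lie in [0, 255]")
            v = v.astype(np.uint8)
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def inverted(self) -> "GrayscaleImage":
        """255 - g; turns bright-on-dark input into the dark-structure convention."""
        return GrayscaleImage(255 - self.values)


@dataclass(frozen=True)
class BinaryImage:
    """A binary image ``f : P -> {0, 1}`` with 0 = black = structure."""

    values: np.ndarray  # 2-D uint8 in {0, 1}

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.size == 0:
            raise ValueError(f"expected a non-empty 2-D array, got shape {v.shape}")
        if not np.isin(v, (0, 1)).all():
            raise ValueError("binary image values must be 0 (black) or 1 (white)")
        object.__setattr__(self, "values", v.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def black_mask(self) -> np.ndarray:
        """Boolean mask of the black set K(f)."""
        return self.values == 0


def load_grayscale(path: str | Path, *, invert: bool = False) -> GrayscaleImage:
    """Read a raster file (TIFF/PNG/JPEG) as an 8-bit grayscale image.

    RGB(A) input is converted with BT.601 luma weights and rounded; integer
    images deeper than 8 bits are rescaled linearly by their type maximum.
    Multi-page TIFFs contribute their first page.
    """
    path = Path(path)
    try:
        arr = np.asarray(iio.imread(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio wraps many backend errors
        raise OSError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 4:  # multi-page with channels
        arr = arr[0]
    if arr.ndim == 3:
        if arr.shape[-1] in (3, 4):  # RGB(A)
            arr = np.tensordot(arr[..., :3].astype(float), _LUMA, axes=([-1], [0]))
            if arr.max() > 255:  # 16-bit RGB
                arr = arr * (255.0 / np.iinfo(np.uint16).max)
            arr = np.rint(arr)
        else:  # multi-page grayscale stack
            arr = arr[0]
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    if arr.dtype != np.uint8 and not np.issubdtype(arr.dtype, np.floating):
        info = np.iinfo(arr.dtype)
        if info.max > 255:
            arr = np.rint(arr.astype(float) * (255.0 / info.max))
    arr = np.clip(np.rint(np.asarray(arr, dtype=float)), 0, 255).astype(np.uint8)
    img = GrayscaleImage(arr)
    return img.inverted() if invert else img


def threshold(g: GrayscaleImage, t: int) -> BinaryImage:
    """Global thresholding: pixel black (0) iff ``g(x, y) <= t``.

    The resulting black sets are nested in ``t``: K(g_0) ⊆ ... ⊆ K(g_255).
    """
    if not 0 <= int(t) <= 255:
        raise ValueError(f"threshold must be in [0, 255], got {t}")
    return BinaryImage(np.where(g.values <= int(t), 0, 1).astype(np.uint8))


def black_set(f: BinaryImage) -> set[tuple[int, int]]:
    """K(f): the set of (row, col) coordinates of black pixels."""
    rows, cols = np.nonzero(f.black_mask)
    return set(zip(rows.tolist(), cols.tolist()))
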