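"""The threshold x opening bifiltration and its axis-aligned paths.

For a grayscale image g, define X_(t,i) = K(O_{S_i}(g_t)): threshold at t,
open the white set with the (i+1)x(i+1) square, keep the black set.  Black
sets are nested in both parameters,

    X_(t1,i1) ⊆ X_(t2,i2)   whenever t1 <= t2 and i1 <= i2,

so each row (fixed i, t = 0..255) and each column (fixed t, i = 0..max_i)
is a one-parameter filtration.  :class:`Bifiltration` evaluates members
lazily with memoization — a dense 256 x (max_i+1) stack is never built —
and exposes each path as an integer :class:`FiltrationFunction` ready for
:func:`mitotopo.persistence.cubical_diagrams`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphology import INF_LEVEL, StructuringElement, opening, opening_level_map
from .raster import BinaryImage, GrayscaleImage, threshold

__all__ = ["FiltrationFunction", "Bifiltration", "INF_LEVEL"]


@dataclass(frozen=True)
class FiltrationFunction:
    """Per-pixel entry level of a one-parameter filtration of black sets.

    ``levels[p]`` is the smallest parameter value at which pixel p is black;
    :data:`INF_LEVEL` marks pixels that never enter by ``max_level``.  The
    sublevel set at s is exactly the s-th black set of the path.
    """

    levels: np.ndarray  # 2-D int64
    max_level: int

    def __post_init__(self) -> None:
        lv = np.asarray(self.levels, dtype=np.int64)
        finite = lv[lv != INF_LEVEL]
        if finite.size and (finite.min() < 0 or finite.max() > self.max_level):
            raise ValueError("finite levels must lie in [0, max_level]")
        object.__setattr__(self, "levels", lv)

    def sublevel(self, s: int) -> BinaryImage:
        """Binary image whose black set is the filtration member at s."""
        mask = (self.levels <= s) & (self.levels != INF_LEVEL)
        return BinaryImage(np.where(mask, 0, 1).astype(np.uint8))


class Bifiltration:
    """Lazy view of {X_(t,i)} for one grayscale image.

    Parameters
    ----------
    image : GrayscaleImage
        The input, dark-structure convention (invert fluorescence first).
    max_i : int
        Largest structuring-element index of the opening axis (default 20,
        i.e. elements up to 21 x 21).
    """

    def __init__(self, image: GrayscaleImage, max_i: int = 20) -> None:
        if max_i < 0:
            raise ValueError("max_i must be >= 0")
        self.image = image
        self.max_i = int(max_i)
        self._members: dict[tuple[int, int], BinaryImage] = {}
        self._horizontal: dict[int, FiltrationFunction] = {}
        self._vertical: dict[int, FiltrationFunction] = {}

    def _check(self, t: int, i: int) -> tuple[int, int]:
        t, i = int(t), int(i)
        if not 0 <= t <= 255:
            raise ValueError(f"threshold index t={t} out of [0, 255]")
        if not 0 <= i <= self.max_i:
            raise ValueError(f"opening index i={i} out of [0, {self.max_i}]")
        return t, i

    def member(self, t: int, i: int) -> BinaryImage:
        """X_(t,i) = K(O_{S_i}(g_t)) as a binary image."""
        t, i = self._check(t, i)
        key = (t, i)
        if key not in self._members:
            f_t = threshold(self.image, t)
            self._members[key] = f_t if i == 0 else opening(f_t, StructuringElement(i))
        return self._members[key]

    def horizontal_map(self, i: int) -> FiltrationFunction:
        """Row i as a filtration function: level(p) = min{t : p in X_(t,i)}.

        For i = 0 this is the raw sublevel filtration (levels equal the
        intensities).  Only thresholds at intensities actually present in
        the image are evaluated: the opening is constant in between.
        """
        _, i = self._check(0, i)
        if i in self._horizontal:
            return self._horizontal[i]
        g = self.image.values
        if i == 0:
            levels = g.astype(np.int64)
        else:
            levels = np.full(g.shape, INF_LEVEL, dtype=np.int64)
            remaining = np.ones(g.shape, dtype=bool)
            for t in np.unique(g):
                newly = self.member(int(t), i).black_mask & remaining
                levels[newly] = int(t)
                remaining &= ~newly
                if not remaining.any():
                    break
        fm = FiltrationFunction(levels, 255)
        self._horizontal[i] = fm
        return fm

    def vertical_map(self, t: int) -> FiltrationFunction:
        """Column t as a filtration function: the opening level map of g_t."""
        t, _ = self._check(t, 0)
        if t not in self._vertical:
            levels = opening_level_map(threshold(self.image, t), self.max_i)
            self._vertical[t] = FiltrationFunction(levels, self.max_i)
        return self._vertical[t]
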