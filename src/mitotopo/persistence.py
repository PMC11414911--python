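"""Cubical persistent homology of 2-D integer filtrations (dims 0 and 1).

Black pixels are closed unit squares in the plane (the T-construction), so
black regions are 8-connected and the enclosed white complement is
4-connected.  :func:`betti_numbers` counts both directly by connected
component labeling; it is deliberately independent of the persistence
engine and serves as its correctness oracle through the identity

    #{(b, d) in pairs_k : b <= t < d}  =  beta_k(sublevel image at t)

for every level t and k in {0, 1}.

Dimension 0 is computed by union-find over pixels in increasing level order
with the elder rule (the older component survives a merge).  Dimension 1
uses planar duality: enclosed white regions of the sublevel filtration are
exactly the components of the complement in the *superlevel* direction, so
running union-find on the white set in decreasing level order — with a
virtual node for the unbounded outside — yields each hole's birth (the
level sealing it off from the outside) and death (the level at which its
last white pixel turns black).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .morphology import INF_LEVEL
from .raster import BinaryImage

__all__ = [
    "BettiPair",
    "PersistencePair",
    "PersistenceDiagram",
    "betti_numbers",
    "cubical_diagrams",
    "betti_curve",
    "write_diagrams_csv",
    "write_perseus",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class BettiPair:
    beta0: int
    beta1: int


@dataclass(frozen=True)
class PersistencePair:
    """A birth-death interval; ``death == math.inf`` marks an essential class."""

    birth: int
    death: int | float

    @property
    def essential(self) -> bool:
        return math.isinf(self.death)

    @property
    def lifespan(self) -> float:
        return self.death - self.birth


@dataclass(frozen=True)
class PersistenceDiagram:
    """Multiset of birth-death pairs in a fixed homology dimension."""

    dimension: int
    pairs: tuple[PersistencePair, ...]
    max_level: int

    def __len__(self) -> int:
        return len(self.pairs)

    def finite(self) -> tuple[PersistencePair, ...]:
        return tuple(p for p in self.pairs if not p.essential)


def betti_numbers(f: BinaryImage) -> BettiPair:
    """(beta0, beta1) of the black set of ``f`` by component labeling.

    beta0 = number of 8-connected black components; beta1 = number of
    4-connected white components that do not touch the image border.
    """
    black = f.black_mask
    _, beta0 = ndimage.label(black, structure=_EIGHT)
    white_labels, n_white = ndimage.label(~black)  # 4-connectivity
    if n_white == 0:
        return BettiPair(int(beta0), 0)
    border = np.zeros_like(white_labels, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    touching = np.unique(white_labels[border & (white_labels > 0)])
    return BettiPair(int(beta0), int(n_white - len(touching)))


# ---------------------------------------------------------------------------
# union-find kernels (numba-compiled when available)
# ---------------------------------------------------------------------------


def _maybe_njit(func):
    try:
        from numba import njit
    except ImportError:  # pragma: no cover - numba is a declared dependency
        return func
    return njit(cache=True)(func)


@_maybe_njit
def _pairs_dim0(order, levels, h, w, inf_level):  # pragma: no cover - jitted
    n = h * w
    parent = np.full(n, -1, dtype=np.int64)
    birth = np.zeros(n, dtype=np.int64)
    births_out = np.empty(n, dtype=np.int64)
    deaths_out = np.empty(n, dtype=np.int64)
    m = 0
    for oi in range(order.shape[0]):
        p = order[oi]
        lvl = levels[p]
        if lvl == inf_level:
            break  # sorted ascending: the rest never enter the complex
        parent[p] = p
        birth[p] = lvl
        r0 = p // w
        c0 = p % w
        for dr in range(-1, 2):
            for dc in range(-1, 2):
                if dr == 0 and dc == 0:
                    continue
                r = r0 + dr
                c = c0 + dc
                if r < 0 or r >= h or c < 0 or c >= w:
                    continue
                q = r * w + c
                if parent[q] == -1:
                    continue
                ra = p
                while parent[ra] != ra:
                    parent[ra] = parent[parent[ra]]
                    ra = parent[ra]
                rb = q
                while parent[rb] != rb:
                    parent[rb] = parent[parent[rb]]
                    rb = parent[rb]
                if ra == rb:
                    continue
                # elder rule: the component with the smaller birth survives
                if birth[ra] <= birth[rb]:
                    elder, young = ra, rb
                else:
                    elder, young = rb, ra
                if birth[young] < lvl:
                    births_out[m] = birth[young]
                    deaths_out[m] = lvl
                    m += 1
                parent[young] = elder
    # essential classes: one per surviving root
    e = 0
    ess = np.empty(n, dtype=np.int64)
    for p in range(n):
        if parent[p] == p:
            ess[e] = birth[p]
            e += 1
    return births_out[:m], deaths_out[:m], ess[:e]


@_maybe_njit
def _pairs_dim1(order, levels, h, w, inf_level):  # pragma: no cover - jitted
    n = h * w
    parent = np.full(n + 1, -1, dtype=np.int64)
    birth = np.zeros(n + 1, dtype=np.int64)
    border = n  # virtual node for the unbounded outside, white forever
    parent[border] = border
    birth[border] = inf_level
    births_out = np.empty(n, dtype=np.int64)
    deaths_out = np.empty(n, dtype=np.int64)
    m = 0
    for oi in range(order.shape[0] - 1, -1, -1):  # decreasing level
        p = order[oi]
        lvl = levels[p]
        parent[p] = p
        birth[p] = lvl
        r0 = p // w
        c0 = p % w
        for k in range(5):
            if k == 0:
                if r0 == 0 or r0 == h - 1 or c0 == 0 or c0 == w - 1:
                    q = border
                else:
                    continue
            else:
                if k == 1:
                    r, c = r0 - 1, c0
                elif k == 2:
                    r, c = r0 + 1, c0
                elif k == 3:
                    r, c = r0, c0 - 1
                else:
                    r, c = r0, c0 + 1
                if r < 0 or r >= h or c < 0 or c >= w:
                    continue
                q = r * w + c
                if parent[q] == -1:
                    continue
            ra = p
            while parent[ra] != ra:
                parent[ra] = parent[parent[ra]]
                ra = parent[ra]
            rb = q
            while parent[rb] != rb:
                parent[rb] = parent[parent[rb]]
                rb = parent[rb]
            if ra == rb:
                continue
            # superlevel elder rule: the larger birth (older) survives
            if birth[ra] >= birth[rb]:
                elder, young = ra, rb
            else:
                elder, young = rb, ra
            if birth[young] > lvl:
                # hole enclosed at lvl, last white pixel blackens at birth[young]
                births_out[m] = lvl
                deaths_out[m] = birth[young]
                m += 1
            parent[young] = elder
    return births_out[:m], deaths_out[:m]


def cubical_diagrams(fm) -> tuple[PersistenceDiagram, PersistenceDiagram]:
    """Persistence diagrams (dim 0, dim 1) of an integer filtration function.

    ``fm`` is any object with ``levels`` (2-D int array, :data:`INF_LEVEL`
    marking pixels outside the filtration) and ``max_level`` attributes —
    see :class:`mitotopo.filtration.FiltrationFunction`.  Pixels enter the
    complex at their level; classes alive at ``max_level`` are essential.
    """
    levels = np.asarray(fm.levels, dtype=np.int64)
    max_level = int(fm.max_level)
    h, w = levels.shape
    flat = levels.ravel()
    order = np.argsort(flat, kind="stable").astype(np.int64)

    b0, d0, ess0 = _pairs_dim0(order, flat, h, w, INF_LEVEL)
    pairs0 = [PersistencePair(int(b), int(d)) for b, d in zip(b0, d0)]
    pairs0 += [PersistencePair(int(b), math.inf) for b in ess0]
    pairs0.sort(key=lambda p: (p.birth, p.death))

    b1, d1 = _pairs_dim1(order, flat, h, w, INF_LEVEL)
    pairs1 = [
        PersistencePair(int(b), math.inf if d == INF_LEVEL else int(d))
        for b, d in zip(b1, d1)
    ]
    pairs1.sort(key=lambda p: (p.birth, p.death))

    return (
        PersistenceDiagram(0, tuple(pairs0), max_level),
        PersistenceDiagram(1, tuple(pairs1), max_level),
    )


def betti_curve(pd: PersistenceDiagram, t: int) -> int:
    """Number of classes alive at level ``t``: #{(b, d) : b <= t < d}."""
    return sum(1 for p in pd.pairs if p.birth <= t < p.death)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def write_diagrams_csv(path: str | Path, diagrams: Iterable[PersistenceDiagram],
                       header_comment: str | None = None) -> None:
    """Write diagrams as CSV with columns dim,birth,death ('inf' if essential)."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("dim,birth,death\n")
        for pd in diagrams:
            for p in pd.pairs:
                death = "inf" if p.essential else str(int(p.death))
                fh.write(f"{pd.dimension},{p.birth},{death}\n")


def write_perseus(path: str | Path, pd: PersistenceDiagram) -> None:
    """Perseus-style output: one 'birth death' line per pair, -1 for infinity."""
    with open(path, "w") as fh:
        for p in pd.pairs:
            death = -1 if p.essential else int(p.death)
            fh.write(f"{p.birth} {death}\n")
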