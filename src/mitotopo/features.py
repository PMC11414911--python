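"""The three bifiltration features: normalized Betti curve, size
distribution, and connectivity index.

All three read the bifiltration X_(t,i) of one grayscale image along a
single row or column:

* ``rho_i(t)`` — beta_1 of X_(t,i) divided by the total number of points
  (finite and essential) of the row's dimension-1 persistence diagram;
  values in [0, 1], identically 0 when the diagram is empty.  Scale- and
  size-independent by construction.
* ``phi(D_t)`` — a 20-bin histogram of the death indices D_t = {d : (0, d)}
  of column t's dimension-1 diagram, normalized to sum to 1.  A hole of the
  thresholded image that dies at opening index d is (d+1) x (d+1)-sized, so
  the histogram is a granulometric size distribution of holes.
* ``C_t`` — the fraction of total finite dimension-1 lifespan in column t
  carried by holes born strictly after opening index 0, i.e. holes created
  by the opening sealing narrow gaps.  Near 1: connected, loop-rich
  morphology; near 0: fragmented.  Essential pairs (holes outliving S_max)
  are excluded throughout.

Empty-diagram conventions: rho is the zero curve; phi and C_t carry a
missing marker (NaN) rather than a manufactured value.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .filtration import Bifiltration
from .persistence import betti_curve, cubical_diagrams

__all__ = [
    "FeatureCurve",
    "DeathMultiset",
    "normalized_betti_curve",
    "death_multiset",
    "size_distribution",
    "connectivity_index",
    "connectivity_curve",
    "features_frame",
]


@dataclass(frozen=True)
class FeatureCurve:
    """A real-valued curve over an integer domain; NaN marks missing values."""

    feature_name: str
    path_index: int
    domain: tuple[int, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.domain) != len(self.values):
            raise ValueError("domain and values must have equal length")
        if any(b <= a for a, b in zip(self.domain, self.domain[1:])):
            raise ValueError("domain must be strictly increasing")

    def value_at(self, x: int) -> float:
        return self.values[self.domain.index(x)]


@dataclass(frozen=True)
class DeathMultiset:
    """D_t: finite deaths of dimension-1 pairs born at opening index 0."""

    column_t: int
    deaths: tuple[int, ...]

    def counts(self) -> Counter:
        return Counter(self.deaths)


def normalized_betti_curve(bif: Bifiltration, i: int) -> FeatureCurve:
    """rho_i(t) = beta_1(X_(t,i)) / #P1 over t = 0..255 for row i."""
    fm = bif.horizontal_map(i)
    _, d1 = cubical_diagrams(fm)
    n = len(d1)
    domain = tuple(range(256))
    if n == 0:
        values = (0.0,) * 256
    else:
        values = tuple(betti_curve(d1, t) / n for t in domain)
    return FeatureCurve("normalized_betti", i, domain, values)


def death_multiset(bif: Bifiltration, t: int) -> DeathMultiset:
    """D_t for column t: deaths d of pairs (0, d), finite deaths only."""
    _, d1 = cubical_diagrams(bif.vertical_map(t))
    deaths = tuple(
        sorted(int(p.death) for p in d1.pairs if p.birth == 0 and not p.essential)
    )
    return DeathMultiset(t, deaths)


def size_distribution(bif: Bifiltration, t: int) -> FeatureCurve:
    """phi(D_t): histogram of D_t over bins 1..max_i, normalized to sum 1.

    Bin d holds the fraction of holes of X_(t,0) removed by S_d, i.e. holes
    of size (d+1) x (d+1) or smaller but larger than S_(d-1).  All bins are
    NaN (missing) when D_t is empty.
    """
    dm = death_multiset(bif, t)
    domain = tuple(range(1, bif.max_i + 1))
    if not dm.deaths:
        values = (math.nan,) * len(domain)
    else:
        counts = dm.counts()
        total = len(dm.deaths)
        values = tuple(counts.get(d, 0) / total for d in domain)
    return FeatureCurve("size_distribution", t, domain, values)


def connectivity_index(bif: Bifiltration, t: int) -> float:
    """C_t: share of finite dim-1 lifespan in column t born after index 0.

    C_t = sum_{(b,d), b>0} (d - b) / sum_{(b,d)} (d - b) over the finite
    pairs of the column diagram; NaN when there are no finite pairs.
    """
    _, d1 = cubical_diagrams(bif.vertical_map(t))
    finite = d1.finite()
    denom = sum(p.lifespan for p in finite)
    if denom == 0:
        return math.nan
    num = sum(p.lifespan for p in finite if p.birth > 0)
    return num / denom


def connectivity_curve(bif: Bifiltration, t_range: Sequence[int]) -> FeatureCurve:
    """C_t evaluated over a range of columns, as one curve."""
    domain = tuple(int(t) for t in t_range)
    values = tuple(connectivity_index(bif, t) for t in domain)
    return FeatureCurve("connectivity_index", -1, domain, values)


def features_frame(curves: Sequence[FeatureCurve], image_id: str) -> pd.DataFrame:
    """Long-format table (image_id, feature, path_index, domain_index, value)."""
    rows = [
        (image_id, c.feature_name, c.path_index, x, v)
        for c in curves
        for x, v in zip(c.domain, c.values)
    ]
    return pd.DataFrame(
        rows, columns=["image_id", "feature", "path_index", "domain_index", "value"]
    )


def curves_to_json(curves: Sequence[FeatureCurve], path: str | Path) -> None:
    payload = [
        {
            "feature": c.feature_name,
            "path_index": c.path_index,
            "domain": list(c.domain),
            "values": [None if math.isnan(v) else v for v in c.values],
        }
        for c in curves
    ]
    Path(path).write_text(json.dumps(payload, indent=1))
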