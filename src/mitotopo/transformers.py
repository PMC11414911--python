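"""Scikit-learn-compatible batch feature extraction.

:class:`MFPHFeatureExtractor` maps a sequence of grayscale images to a
fixed-length vector of bifiltration feature summaries per image, so the
topological features compose directly with sklearn pipelines, classifiers
and model selection.  The transformer is stateless: ``fit`` only validates
parameters.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .features import connectivity_index, normalized_betti_curve, size_distribution
from .filtration import Bifiltration
from .raster import GrayscaleImage
from .stats import curve_summary

__all__ = ["MFPHFeatureExtractor"]


class MFPHFeatureExtractor(BaseEstimator, TransformerMixin):
    """Summarized threshold x opening persistence features per image.

    For each image the transformer emits, in order: the mean normalized
    Betti curve over ``summary_range`` for every row in ``rows``; the mean
    size-distribution bin value over ``size_bin_range`` at column
    ``size_column``; and the mean connectivity index over
    ``summary_range``.  Undefined summaries (empty diagrams) are NaN.

    Parameters
    ----------
    rows : sequence of int
        Opening indices i of the normalized Betti curves (default 0, 3, 5).
    size_column : int
        Threshold t of the size distribution (default 128).
    summary_range : (int, int)
        Inclusive threshold band for curve means (default (100, 150)).
    size_bin_range : (int, int)
        Inclusive size-bin band for the histogram mean (default (5, 15)).
    max_opening : int
        Largest structuring-element index of the opening axis.
    invert : bool
        Apply 255 - g first (bright-on-dark fluorescence input).
    """

    def __init__(
        self,
        rows: Sequence[int] = (0, 3, 5),
        size_column: int = 128,
        summary_range: tuple[int, int] = (100, 150),
        size_bin_range: tuple[int, int] = (5, 15),
        max_opening: int = 20,
        invert: bool = False,
    ) -> None:
        self.rows = rows
        self.size_column = size_column
        self.summary_range = summary_range
        self.size_bin_range = size_bin_range
        self.max_opening = max_opening
        self.invert = invert

    def fit(self, X, y=None):
        if any(not 0 <= i <= self.max_opening for i in self.rows):
            raise ValueError("rows must lie within [0, max_opening]")
        if not 0 <= self.size_column <= 255:
            raise ValueError("size_column must lie in [0, 255]")
        self.n_features_in_ = 1
        self.feature_names_out_ = np.asarray(self.get_feature_names_out())
        return self

    def get_feature_names_out(self, input_features=None):
        a, b = self.summary_range
        names = [f"rho_row{i}_mean_{a}_{b}" for i in self.rows]
        sa, sb = self.size_bin_range
        names.append(f"phi_col{self.size_column}_meanbin_{sa}_{sb}")
        names.append(f"connectivity_mean_{a}_{b}")
        return np.asarray(names, dtype=object)

    def _as_image(self, x) -> GrayscaleImage:
        img = x if isinstance(x, GrayscaleImage) else GrayscaleImage(np.asarray(x))
        return img.inverted() if self.invert else img

    def transform(self, X) -> np.ndarray:
        a, b = self.summary_range
        sa, sb = self.size_bin_range
        out = []
        for x in X:
            bif = Bifiltration(self._as_image(x), max_i=self.max_opening)
            row = [curve_summary(normalized_betti_curve(bif, i), a, b)
                   for i in self.rows]
            phi = size_distribution(bif, self.size_column)
            try:
                row.append(curve_summary(phi, sa, sb))
            except ValueError:
                row.append(math.nan)
            c_vals = [connectivity_index(bif, t) for t in range(a, b + 1)]
            defined = [v for v in c_vals if not math.isnan(v)]
            row.append(float(np.mean(defined)) if defined else math.nan)
            out.append(row)
        return np.asarray(out, dtype=float)
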