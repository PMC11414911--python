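import math

import numpy as np
import pytest

from mitotopo import (
    Bifiltration,
    GrayscaleImage,
    connectivity_curve,
    connectivity_index,
    death_multiset,
    normalized_betti_curve,
    size_distribution,
)
from mitotopo.features import features_frame


def _bif(values, max_i=20) -> Bifiltration:
    return Bifiltration(GrayscaleImage(np.asarray(values, dtype=np.uint8)), max_i=max_i)


@pytest.fixture()
def two_hole_field() -> Bifiltration:
    """Black field (intensity 0) with a 1x1 and a 3x3 white (255) hole."""
    v = np.zeros((11, 15), dtype=np.uint8)
    v[2, 2] = 255
    v[4:7, 8:11] = 255
    return _bif(v)


class TestNormalizedBettiCurve:
    def test_worked_example_row0_is_indicator_of_3_to_9(self, worked_bif):
        curve = normalized_betti_curve(worked_bif, 0)
        for t, v in zip(curve.domain, curve.values):
            assert v == (1.0 if 3 <= t <= 9 else 0.0)

    def test_image_without_holes_gives_zero_curve(self):
        curve = normalized_betti_curve(_bif(np.full((6, 6), 30)), 0)
        assert set(curve.values) == {0.0}

    def test_values_within_unit_interval(self, rng):
        g = GrayscaleImage(rng.integers(0, 256, (20, 20)).astype(np.uint8))
        for i in (0, 2):
            curve = normalized_betti_curve(Bifiltration(g, max_i=5), i)
            assert all(0.0 <= v <= 1.0 for v in curve.values)


class TestDeathMultiset:
    def test_worked_example_column3_has_one_size1_hole(self, worked_bif):
        assert death_multiset(worked_bif, 3).deaths == (1,)

    def test_all_black_column_is_empty(self, worked_bif):
        assert death_multiset(worked_bif, 255).deaths == ()

    def test_holes_report_their_sizes(self, two_hole_field):
        assert death_multiset(two_hole_field, 128).deaths == (1, 3)


class TestSizeDistribution:
    def test_worked_example_concentrates_on_bin_one(self, worked_bif):
        phi = size_distribution(worked_bif, 3)
        assert phi.value_at(1) == 1.0
        assert sum(v for v in phi.values if not math.isnan(v)) == pytest.approx(1.0)

    def test_direct_normalization_of_two_sizes(self, two_hole_field):
        phi = size_distribution(two_hole_field, 128)
        assert phi.value_at(1) == 0.5 and phi.value_at(3) == 0.5
        assert sum(phi.values) == pytest.approx(1.0)

    def test_empty_multiset_marks_all_bins_missing(self, worked_bif):
        phi = size_distribution(worked_bif, 255)
        assert all(math.isnan(v) for v in phi.values)

    def test_has_one_bin_per_opening_index(self, worked_bif):
        assert size_distribution(worked_bif, 3).domain == tuple(range(1, 21))


class TestConnectivityIndex:
    def test_worked_example_column3_is_zero(self, worked_bif):
        # the only pair is (0, 1), which belongs to D_3: numerator empty
        assert connectivity_index(worked_bif, 3) == 0.0

    def test_column_without_pairs_is_missing(self, worked_bif):
        assert math.isnan(connectivity_index(worked_bif, 255))

    def test_c_shape_sealed_by_opening_scores_one(self):
        # black "C" whose 1-pixel mouth is sealed by S_1: the only hole is
        # born at opening index 1, so all lifespan mass is opening-born
        v = np.full((9, 9), 255, dtype=np.uint8)
        v[2:7, 2:7] = 0  # 5x5 black block
        v[3:6, 3:6] = 255  # 3x3 white pocket
        v[4, 6] = 255  # 1-px mouth through the right wall
        bif = _bif(v)
        assert connectivity_index(bif, 128) == 1.0

    def test_within_unit_interval_when_defined(self, rng):
        g = GrayscaleImage(rng.integers(0, 256, (24, 24)).astype(np.uint8))
        bif = Bifiltration(g, max_i=10)
        for t in (80, 128, 180):
            c = connectivity_index(bif, t)
            assert math.isnan(c) or 0.0 <= c <= 1.0


class TestInvarianceAndExport:
    def test_features_invariant_under_translation_and_rotation(self):
        v = np.zeros((10, 12), dtype=np.uint8)
        v[2, 2] = 255
        v[4:7, 6:9] = 255
        shifted = np.pad(v, ((3, 1), (2, 4)), constant_values=0)
        rotated = np.rot90(v).copy()
        ref = _bif(v)
        for other in (_bif(shifted), _bif(rotated)):
            assert (death_multiset(ref, 128).deaths
                    == death_multiset(other, 128).deaths)
            assert (size_distribution(ref, 128).values
                    == size_distribution(other, 128).values)
            c_ref, c_other = connectivity_index(ref, 128), connectivity_index(other, 128)
            assert c_ref == c_other
            r_ref = normalized_betti_curve(ref, 1)
            r_other = normalized_betti_curve(other, 1)
            assert r_ref.values == r_other.values

    def test_long_format_frame(self, worked_bif):
        frame = features_frame([size_distribution(worked_bif, 3)], "demo")
        assert list(frame.columns) == [
            "image_id", "feature", "path_index", "domain_index", "value"
        ]
        assert len(frame) == 20
        assert frame["value"].iloc[0] == 1.0

    def test_connectivity_curve_collects_columns(self, worked_bif):
        curve = connectivity_curve(worked_bif, range(3, 6))
        assert curve.domain == (3, 4, 5)
        assert curve.values[0] == 0.0
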