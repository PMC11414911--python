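import math

import numpy as np
import pytest

from mitotopo import (
    Bifiltration,
    BinaryImage,
    FiltrationFunction,
    GrayscaleImage,
    INF_LEVEL,
    betti_curve,
    betti_numbers,
    cubical_diagrams,
    threshold,
)
from mitotopo.persistence import write_diagrams_csv, write_perseus


def _pairs(pd):
    return sorted((p.birth, p.death) for p in pd.pairs)


class TestBettiNumbers:
    def test_worked_example_ring_has_one_component_one_hole(self, worked_example):
        b = betti_numbers(threshold(worked_example, 3))
        assert (b.beta0, b.beta1) == (1, 1)

    def test_all_black_and_all_white(self):
        assert betti_numbers(BinaryImage(np.zeros((4, 4), np.uint8))).beta0 == 1
        assert betti_numbers(BinaryImage(np.zeros((4, 4), np.uint8))).beta1 == 0
        w = betti_numbers(BinaryImage(np.ones((4, 4), np.uint8)))
        assert (w.beta0, w.beta1) == (0, 0)

    def test_diagonal_contact_connects_black(self):
        # closed unit squares share a corner vertex -> one component
        v = np.ones((2, 2), np.uint8)
        v[0, 0] = v[1, 1] = 0
        b = betti_numbers(BinaryImage(v))
        assert (b.beta0, b.beta1) == (1, 0)

    def test_border_touching_white_is_not_a_hole(self):
        v = np.zeros((3, 3), np.uint8)
        v[0, 1] = v[1, 1] = 1  # white channel open to the border
        assert betti_numbers(BinaryImage(v)).beta1 == 0


class TestCubicalDiagrams:
    def test_worked_example_reproduces_printed_diagrams(self, worked_bif):
        d0, d1 = cubical_diagrams(worked_bif.horizontal_map(0))
        assert _pairs(d0) == [(1, math.inf), (2, 3)]
        assert _pairs(d1) == [(3, 10)]

    def test_constant_image_has_one_essential_component(self):
        fm = FiltrationFunction(np.full((3, 3), 7, dtype=np.int64), 255)
        d0, d1 = cubical_diagrams(fm)
        assert _pairs(d0) == [(7, math.inf)]
        assert len(d1) == 0

    def test_two_separate_blobs_are_both_essential(self):
        lv = np.full((3, 5), INF_LEVEL, dtype=np.int64)
        lv[1, 0], lv[1, 4] = 1, 2
        d0, d1 = cubical_diagrams(FiltrationFunction(lv, 255))
        assert _pairs(d0) == [(1, math.inf), (2, math.inf)]
        assert len(d1) == 0

    def test_all_infinite_input_yields_empty_diagrams(self):
        fm = FiltrationFunction(np.full((4, 4), INF_LEVEL, dtype=np.int64), 10)
        d0, d1 = cubical_diagrams(fm)
        assert len(d0) == 0 and len(d1) == 0

    @pytest.mark.parametrize("size", [8, 12])
    def test_diagrams_count_betti_numbers_at_every_level(self, rng, size):
        """The primary correctness oracle: levelwise pair counts = Betti numbers."""
        for _ in range(30):
            lv = rng.integers(0, 11, (size, size)).astype(np.int64)
            if rng.random() < 0.3:
                lv[rng.random((size, size)) < 0.15] = INF_LEVEL
            d0, d1 = cubical_diagrams(FiltrationFunction(lv, 10))
            for t in range(11):
                sub = BinaryImage(
                    np.where((lv <= t) & (lv != INF_LEVEL), 0, 1).astype(np.uint8)
                )
                b = betti_numbers(sub)
                assert betti_curve(d0, t) == b.beta0
                assert betti_curve(d1, t) == b.beta1

    def test_one_essential_dim0_pair_per_final_component(self, rng):
        lv = rng.integers(0, 6, (10, 10)).astype(np.int64)
        d0, _ = cubical_diagrams(FiltrationFunction(lv, 5))
        ess = [p for p in d0.pairs if p.essential]
        final = betti_numbers(BinaryImage(np.zeros((10, 10), np.uint8)))
        assert len(ess) == final.beta0 == 1

    def test_invariant_under_translation_and_rotation(self, rng):
        lv = rng.integers(0, 8, (7, 9)).astype(np.int64)
        d0, d1 = cubical_diagrams(FiltrationFunction(lv, 7))
        padded = np.pad(lv, 3, constant_values=INF_LEVEL)
        p0, p1 = cubical_diagrams(FiltrationFunction(padded, 7))
        assert _pairs(p0) == _pairs(d0) and _pairs(p1) == _pairs(d1)
        r0, r1 = cubical_diagrams(FiltrationFunction(np.rot90(lv).copy(), 7))
        assert _pairs(r0) == _pairs(d0) and _pairs(r1) == _pairs(d1)

    def test_adding_a_constant_shifts_births_and_deaths(self, rng):
        lv = rng.integers(0, 8, (8, 8)).astype(np.int64)
        d0, d1 = cubical_diagrams(FiltrationFunction(lv, 7))
        s0, s1 = cubical_diagrams(FiltrationFunction(lv + 5, 12))
        for a, b in ((d0, s0), (d1, s1)):
            assert _pairs(b) == [(x + 5, y + 5) for x, y in _pairs(a)]


class TestBettiCurve:
    def test_counts_pairs_alive_at_t(self, worked_bif):
        d0, d1 = cubical_diagrams(worked_bif.horizontal_map(0))
        assert betti_curve(d1, 5) == 1
        assert betti_curve(d0, 2) == 2
        assert betti_curve(d1, 2) == 0  # below the minimum birth


class TestSerialization:
    def test_csv_and_perseus_outputs(self, tmp_path, worked_bif):
        d0, d1 = cubical_diagrams(worked_bif.horizontal_map(0))
        csv = tmp_path / "d.csv"
        write_diagrams_csv(csv, (d0, d1), header_comment="demo")
        text = csv.read_text()
        assert "dim,birth,death" in text
        assert "0,1,inf" in text and "0,2,3" in text and "1,3,10" in text
        pers = tmp_path / "d1.txt"
        write_perseus(pers, d0)
        assert pers.read_text().splitlines() == ["1 -1", "2 3"]
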