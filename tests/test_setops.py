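"""Hypergeometric overlap scoring, intersections, Venn regions, harmonization."""

import math
from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from overlapkit import (
    GeneList,
    InputError,
    OverlapResult,
    harmonize_symbols,
    hypergeometric_overlap_p,
    intersect,
    venn_regions,
)


def exact_upper_tail(n_universe: int, size_x: int, size_y: int, k: int) -> Fraction:
    """Closed-form rational upper tail, independent of the implementation."""
    num = sum(
        math.comb(size_x, i) * math.comb(n_universe - size_x, size_y - i)
        for i in range(k, min(size_x, size_y) + 1)
    )
    return Fraction(num, math.comb(n_universe, size_y))


class TestHypergeometricOverlapP:
    def test_zero_overlap_is_one(self):
        assert hypergeometric_overlap_p(100, 10, 10, 0) == 1.0

    def test_forced_full_overlap(self):
        # only one 4-subset of a 10-universe achieves full overlap with X
        p = hypergeometric_overlap_p(10, 4, 4, 4)
        assert p == pytest.approx(1 / 210, rel=1e-12)

    def test_derived_enumeration_case(self):
        # frozen before the build by enumerating all C(20,5)=15504 subsets:
        # 2036 of them share >=3 members with a fixed 6-set
        p = hypergeometric_overlap_p(20, 6, 5, 3)
        assert p == pytest.approx(2036 / 15504, rel=1e-12)

    def test_matches_subset_enumeration_small(self):
        # literal enumeration of every |Y|-subset at N=12
        n, sx, sy = 12, 5, 4
        x = set(range(sx))
        for k in range(0, min(sx, sy) + 1):
            hits = sum(
                1 for y in combinations(range(n), sy) if len(x.intersection(y)) >= k
            )
            expected = hits / math.comb(n, sy)
            assert hypergeometric_overlap_p(n, sx, sy, k) == pytest.approx(
                expected, rel=1e-12
            )

    def test_matches_rational_oracle_sample(self):
        for n, sx, sy, k in [(25, 12, 10, 6), (18, 9, 9, 9), (22, 4, 20, 3)]:
            assert hypergeometric_overlap_p(n, sx, sy, k) == pytest.approx(
                float(exact_upper_tail(n, sx, sy, k)), rel=1e-12
            )

    def test_genome_scale_no_overflow(self):
        p = hypergeometric_overlap_p(20000, 6777, 2400, 1100)
        assert 0.0 < p <= 1.0 and np.isfinite(p)

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_symmetry_in_list_sizes(self, data):
        n = data.draw(st.integers(2, 60))
        sx = data.draw(st.integers(0, n))
        sy = data.draw(st.integers(0, n))
        lo = max(0, sx + sy - n)
        k = data.draw(st.integers(lo, min(sx, sy)))
        assert hypergeometric_overlap_p(n, sx, sy, k) == pytest.approx(
            hypergeometric_overlap_p(n, sy, sx, k), rel=1e-9
        )

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_monotone_nonincreasing_in_overlap(self, data):
        n = data.draw(st.integers(2, 60))
        sx = data.draw(st.integers(1, n))
        sy = data.draw(st.integers(1, n))
        lo = max(0, sx + sy - n)
        ps = [
            hypergeometric_overlap_p(n, sx, sy, k) for k in range(lo, min(sx, sy) + 1)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))

    def test_null_calibration_super_uniform(self, rng):
        # random Y at N=1000: P(p <= alpha) <= alpha (+3 binomial SDs)
        n, sx, sy, reps = 1000, 120, 80, 400
        x = set(range(sx))
        ps = []
        for _ in range(reps):
            y = rng.choice(n, size=sy, replace=False)
            k = len(x.intersection(y))
            ps.append(hypergeometric_overlap_p(n, sx, sy, k))
        ps = np.asarray(ps)
        for alpha in (0.05, 0.1, 0.25):
            frac = float(np.mean(ps <= alpha))
            assert frac <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / reps)

    @pytest.mark.parametrize(
        "args",
        [(10, 11, 5, 3), (10, 5, 11, 3), (10, 5, 5, 6), (10, 8, 8, 2), (0, 0, 0, 0)],
    )
    def test_impossible_configurations_rejected(self, args):
        with pytest.raises(InputError):
            hypergeometric_overlap_p(*args)


class TestIntersect:
    def test_identical_lists_minimal_p(self, toy_universe):
        x = GeneList("x", ["U00", "U01", "U02"])
        res = intersect(x, x, toy_universe)
        assert res.overlap_size == 3
        assert res.p_value == pytest.approx(
            hypergeometric_overlap_p(10, 3, 3, 3), rel=1e-12
        )

    def test_disjoint_lists_covering_universe(self, toy_universe):
        x = GeneList("x", [f"U{i:02d}" for i in range(5)])
        y = GeneList("y", [f"U{i:02d}" for i in range(5, 10)])
        res = intersect(x, y, toy_universe)
        assert res.overlap_size == 0
        assert res.p_value == 1.0

    def test_members_outside_universe_dropped(self, toy_universe):
        x = GeneList("x", ["U00", "U01", "NOT_THERE"])
        y = GeneList("y", ["U01", "ALSO_MISSING"])
        res = intersect(x, y, toy_universe)
        assert (res.size_x, res.size_y) == (2, 1)
        assert (res.dropped_x, res.dropped_y) == (1, 1)
        assert res.overlap_genes == ("U01",)

    def test_case_folding_makes_cross_species_symbols_match(self):
        uni = GeneList("u", ["COL1A1", "GFAP", "ACTB"])
        res = intersect(GeneList("x", ["Col1a1", "Gfap"]), GeneList("y", ["COL1A1"]), uni)
        assert res.overlap_genes == ("COL1A1",)

    def test_empty_universe_rejected(self):
        with pytest.raises(InputError):
            intersect(GeneList("x", ["A"]), GeneList("y", ["A"]), GeneList("u", []))

    def test_invariants_hold(self, toy_universe, rng):
        for _ in range(20):
            xs = rng.choice(10, size=rng.integers(0, 10), replace=False)
            ys = rng.choice(10, size=rng.integers(0, 10), replace=False)
            res = intersect(
                GeneList("x", [f"U{i:02d}" for i in xs]),
                GeneList("y", [f"U{i:02d}" for i in ys]),
                toy_universe,
            )
            assert res.overlap_size <= min(res.size_x, res.size_y)
            assert res.overlap_size >= max(0, res.size_x + res.size_y - res.universe_size)
            assert 0 < res.p_value <= 1


class TestVennRegions:
    def test_identical_lists(self, toy_universe):
        x = GeneList("x", ["U00", "U01"])
        s = venn_regions([x, GeneList("y", ["U00", "U01"])], toy_universe)
        assert s.region_counts[(1, 1)] == 2
        assert s.region_counts[(1, 0)] == 0
        assert s.region_counts[(0, 1)] == 0

    def test_disjoint_lists(self, toy_universe):
        s = venn_regions(
            [GeneList("x", ["U00", "U01"]), GeneList("y", ["U02"])], toy_universe
        )
        assert s.region_counts == {(1, 0): 2, (0, 1): 1, (1, 1): 0}

    def test_three_lists_hand_enumerated(self, toy_universe):
        # U00..U09; a={0,1,2,3}, b={2,3,4,5}, c={3,5,6}
        a = GeneList("a", ["U00", "U01", "U02", "U03"])
        b = GeneList("b", ["U02", "U03", "U04", "U05"])
        c = GeneList("c", ["U03", "U05", "U06"])
        s = venn_regions([a, b, c], toy_universe)
        expected = {
            (1, 0, 0): 2,  # U00 U01
            (1, 1, 0): 1,  # U02
            (1, 1, 1): 1,  # U03
            (0, 1, 0): 1,  # U04
            (0, 1, 1): 1,  # U05
            (0, 0, 1): 1,  # U06
            (1, 0, 1): 0,
        }
        assert dict(s.region_counts) == expected
        assert s.union_size() == 7

    def test_region_counts_sum_to_union(self, toy_universe, rng):
        lists = [
            GeneList(
                f"l{j}",
                [f"U{i:02d}" for i in rng.choice(10, size=rng.integers(1, 9), replace=False)],
            )
            for j in range(3)
        ]
        s = venn_regions(lists, toy_universe)
        union = set().union(*(gl.as_set() for gl in lists))
        assert s.union_size() == len(union)

    def test_more_than_three_lists_unsupported(self, toy_universe):
        lists = [GeneList(f"l{j}", ["U00"]) for j in range(4)]
        with pytest.raises(InputError):
            venn_regions(lists, toy_universe)


class TestHarmonizeSymbols:
    def test_case_fold_dedup(self):
        out, dropped = harmonize_symbols(GeneList("l", ["Col1a1", "COL1A1"]))
        assert out.genes == ["COL1A1"]
        assert dropped == 0

    def test_map_translation(self):
        out, dropped = harmonize_symbols(GeneList("l", ["Gfap"]), {"Gfap": "GFAP"})
        assert out.genes == ["GFAP"]
        assert dropped == 0

    def test_unmapped_member_dropped_and_counted(self):
        out, dropped = harmonize_symbols(
            GeneList("l", ["Gfap", "Novel1"]), {"Gfap": "GFAP"}
        )
        assert out.genes == ["GFAP"]
        assert dropped == 1

    @given(st.lists(st.text(alphabet="abcXYZ123", min_size=1, max_size=6), max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_idempotent(self, genes):
        once, _ = harmonize_symbols(GeneList("l", genes))
        twice, dropped = harmonize_symbols(once)
        assert twice.genes == once.genes
        assert dropped == 0

    def test_malformed_map_row_named(self, tmp_path):
        from overlapkit.setops import read_ortholog_map

        bad = tmp_path / "map.tsv"
        bad.write_text("Gfap\tGFAP\nbroken_row_without_tab\n")
        with pytest.raises(InputError, match="line 2"):
            read_ortholog_map(bad)
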