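"""Hypergeometric tail, BH adjustment and the enrichment front end."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirhost.enrichment import (
    bh_adjust,
    enrich,
    hypergeom_upper_tail,
    target_set_enrichment,
)
from mirhost.model import GeneSet, GeneSetCollection


def enumeration_tail(k, K, n, N):
    """Exhaustive oracle: fraction of n-subsets of N with >= k marked."""
    marked = set(range(K))
    total = hits = 0
    for subset in itertools.combinations(range(N), n):
        total += 1
        hits += len(marked.intersection(subset)) >= k
    return hits / total if total else 1.0


class TestHypergeomTail:
    def test_k_zero_covers_whole_support(self):
        assert hypergeom_upper_tail(0, 5, 3, 10) == 1.0

    def test_two_of_two_in_ten(self):
        # C(2,2)*C(8,0)/C(10,2) = 1/45
        assert hypergeom_upper_tail(2, 2, 2, 10) == pytest.approx(1 / 45)

    @pytest.mark.parametrize("N", [5, 8])
    def test_matches_enumeration_small(self, N):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
                        enumeration_tail(k, K, n, N), abs=1e-12
                    )

    def test_monotone_nonincreasing_in_k(self):
        vals = [hypergeom_upper_tail(k, 20, 30, 100) for k in range(21)]
        assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_bound_violations_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(3, 2, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(0, 11, 5, 10)


class TestBhAdjust:
    def test_single_p_is_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_executed_step_up(self):
        # q_(i) = min_{j>=i} m*p_(j)/j: all collapse to 0.04 here
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones_stay_one(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_range_monotonicity_and_step_up_definition(self, pvals):
        q = bh_adjust(pvals)
        assert np.all((q >= 0) & (q <= 1))
        # monotone in the sorted-p order
        order = np.argsort(pvals)
        assert np.all(np.diff(q[order]) >= -1e-12)
        # matches the step-up recursion q_(i) = min_{j>=i} m*p_(j)/j, capped at 1
        m = len(pvals)
        ps = np.sort(pvals)
        expected_sorted = np.minimum.accumulate(
            (m * ps / np.arange(1, m + 1))[::-1]
        )[::-1].clip(max=1.0)
        assert q[order] == pytest.approx(expected_sorted)


def toy_collection():
    return GeneSetCollection({
        "HIT": GeneSet("HIT", "planted", frozenset({"A", "B", "C", "D"})),
        "MISS": GeneSet("MISS", "disjoint", frozenset({"X", "Y", "Z"})),
        "TINY": GeneSet("TINY", "below min size", frozenset({"Q"})),
    })


class TestEnrich:
    UNIVERSE = [c for c in "ABCDXYZQRSTUVW"]

    def test_full_membership_query_ranks_term_first(self):
        res = enrich({"A", "B", "C", "D"}, toy_collection(), self.UNIVERSE)
        assert res[0].term_id == "HIT"
        assert res[0].k == 4
        assert res[0].pvalue < res[-1].pvalue or len(res) == 1

    def test_disjoint_query_all_p_one(self):
        res = enrich({"R", "S", "T"}, toy_collection(), self.UNIVERSE)
        assert all(r.k == 0 and r.pvalue == 1.0 for r in res)

    def test_min_term_size_filters(self):
        res = enrich({"A"}, toy_collection(), self.UNIVERSE)
        assert "TINY" not in {r.term_id for r in res}

    def test_tail_matches_brute_sum_on_planted_overlap(self):
        # universe 1000, term of 40 containing 20 of a 71-gene query
        universe = [f"g{i}" for i in range(1000)]
        term = frozenset(universe[:40])
        query = set(universe[20:40]) | {f"g{900 + i}" for i in range(51)}
        col = GeneSetCollection({"T": GeneSet("T", "", term)})
        (res,) = enrich(query, col, universe)
        brute = sum(
            math.comb(40, j) * math.comb(960, 71 - j) / math.comb(1000, 71)
            for j in range(20, 41)
        )
        assert res.pvalue == pytest.approx(brute, rel=1e-9)
        assert res.fold_enrichment == pytest.approx((20 / 71) / (40 / 1000))

    def test_result_order_invariant_to_input_order(self):
        res1 = enrich(["A", "B", "C", "D"], toy_collection(), self.UNIVERSE)
        res2 = enrich(["D", "C", "B", "A"], toy_collection(), list(reversed(self.UNIVERSE)))
        assert res1 == res2

    def test_empty_universe_rejected_and_empty_query_warns(self):
        with pytest.raises(ValueError):
            enrich({"A"}, toy_collection(), [])
        assert enrich(set(), toy_collection(), self.UNIVERSE) == []


class TestTargetMode:
    def test_union_deduplicates_and_reports_unmapped(self):
        tmap = {"m1": {"A", "B"}, "m2": {"B", "C"}}
        res, unmapped = target_set_enrichment(
            ["m1", "m2", "m3"], tmap, toy_collection(), TestEnrich.UNIVERSE
        )
        assert unmapped == ["m3"]
        assert res[0].mode == "target"
        assert res[0].n == 3  # A, B, C after union

    def test_empty_map_empty_results(self):
        res, unmapped = target_set_enrichment(
            ["m1"], {}, toy_collection(), TestEnrich.UNIVERSE
        )
        assert res == []
        assert unmapped == ["m1"]


class TestNullCalibrationSmoke:
    def test_random_query_rejection_rate_close_to_nominal(self):
        """Small version of the calibration study (the full one is in the
        acceptance suite): with near-continuous overlap distributions the
        p < 0.05 rate over random queries is close to 0.05."""
        rng = np.random.default_rng(5)
        N, K, n = 4000, 400, 400
        hits = total = 0
        universe = np.arange(N)
        for _ in range(100):
            q = rng.choice(universe, size=n, replace=False)
            for t in range(5):
                term = set(range(t * 400, (t + 1) * 400))
                k = len(term.intersection(q.tolist()))
                hits += hypergeom_upper_tail(k, K, n, N) < 0.05
                total += 1
        assert 0.02 <= hits / total <= 0.09
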