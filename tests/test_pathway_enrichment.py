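"""Hypergeometric tail, BH adjustment, enrichment and shared-pathway summary.

The tail probability is checked against an exact rational-arithmetic
enumeration (Fraction + binomial coefficients) and scipy's survival
function; BH against statsmodels. Both oracles are independent of the
log-space implementation under test.
"""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mirderep.io_formats import Pathway, PathwayCollection
from mirderep.pathway_enrichment import (
    EnrichmentResult,
    bh_adjust,
    enrich,
    hypergeom_upper_tail,
    shared_pathways,
    significant_pathways,
    top_pathways,
)


def exact_upper_tail(k: int, K: int, n: int, N: int) -> Fraction:
    """Rational-arithmetic enumeration of P(X >= k)."""
    return sum(
        Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
        for i in range(k, min(K, n) + 1)
    ) if k <= min(K, n) else Fraction(0)


class TestHypergeomUpperTail:
    @pytest.mark.parametrize(
        "k, K, n, N, expected",
        [
            (0, 4, 3, 10, 1.0),
            (2, 4, 3, 10, 40 / 120),       # enumeration: (C(4,2)C(6,1)+C(4,3))/C(10,3)
            (3, 5, 5, 20, 1126 / 15504),   # tail terms i=3,4,5
        ],
    )
    def test_frozen_examples(self, k, K, n, N, expected):
        assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize(
        "k, K, n, N",
        [(-1, 4, 3, 10), (4, 3, 10, 10), (2, 11, 3, 10), (2, 4, 11, 10)],
    )
    def test_out_of_range_raises(self, k, K, n, N):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(k, K, n, N)

    def test_matches_rational_enumeration_on_a_grid(self):
        for N in (1, 5, 12):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        got = hypergeom_upper_tail(k, K, n, N)
                        want = float(exact_upper_tail(k, K, n, N))
                        assert got == pytest.approx(want, rel=1e-12), (k, K, n, N)

    def test_matches_scipy_at_large_parameters(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            N = int(rng.integers(50, 3000))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            want = stats.hypergeom.sf(k - 1, N, K, n)
            assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(want, rel=1e-9)

    @given(st.integers(1, 20), st.data())
    @settings(derandomize=True, max_examples=100)
    def test_non_increasing_in_k_and_one_at_zero(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        tails = [hypergeom_upper_tail(k, K, n, N) for k in range(min(K, n) + 1)]
        assert tails[0] == 1.0
        assert all(a >= b for a, b in zip(tails, tails[1:]))


class TestBHAdjust:
    def test_single_value_is_identity(self):
        assert bh_adjust([0.05]) == [0.05]

    def test_hand_computed_step_up(self):
        # p*m/rank = 0.02, 0.018, 0.0667, 0.5; then right-to-left cumulative min
        assert bh_adjust([0.005, 0.009, 0.05, 0.5]) == pytest.approx(
            [0.018, 0.018, 0.2 / 3, 0.5]
        )

    def test_permutation_equivariance(self):
        p = [0.005, 0.009, 0.05, 0.5]
        q = bh_adjust(p)
        perm = [2, 0, 3, 1]
        assert bh_adjust([p[i] for i in perm]) == pytest.approx([q[i] for i in perm])

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])

    def test_output_dominates_input_and_sorted_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        q = np.array(bh_adjust(p))
        assert np.all(q >= p) and np.all(q <= 1)
        assert np.all(np.diff(np.array(q)[np.argsort(p)]) >= -1e-15)

    def test_agrees_with_statsmodels_reference(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            m = int(rng.integers(1, 100))
            p = rng.uniform(size=m)
            want = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), want, rtol=1e-12, atol=0)


def _collection(**pathways):
    return PathwayCollection(
        pathways={
            pid: Pathway(id=pid, name=pid.lower(), members=frozenset(members))
            for pid, members in pathways.items()
        }
    )


class TestEnrich:
    def test_degenerate_saturation_gives_p_one(self):
        genes = {"A", "B", "C"}
        (r,) = enrich(genes, _collection(P1=genes), genes)
        assert (r.k, r.K, r.n, r.N) == (3, 3, 3, 3) and r.p == 1.0

    def test_counts_and_p_after_universe_intersection(self):
        universe = {f"G{i}" for i in range(10)}
        (r,) = enrich({"G0", "G1", "G2"}, _collection(P1={"G0", "G1", "G5", "G6"}), universe)
        assert (r.k, r.K, r.n, r.N) == (2, 4, 3, 10)
        assert r.p == pytest.approx(1 / 3, rel=1e-12)
        assert r.overlap == ("G0", "G1")

    def test_pathway_outside_universe_absent(self):
        universe = {"G0", "G1"}
        results = enrich({"G0"}, _collection(P1={"G0"}, P2={"X1", "X2"}), universe)
        assert [r.pathway_id for r in results] == ["P1"]

    def test_query_genes_outside_universe_dropped(self):
        universe = {"G0", "G1", "G2", "G3"}
        (r,) = enrich({"G0", "ZZZ"}, _collection(P1={"G0", "G1"}), universe)
        assert r.n == 1 and r.k == 1

    def test_empty_universe_raises_and_empty_query_warns(self, caplog):
        with pytest.raises(ValueError):
            enrich({"G0"}, _collection(P1={"G0"}), set())
        with caplog.at_level("WARNING"):
            assert enrich({"ZZZ"}, _collection(P1={"G0"}), {"G0", "G1"}) == []

    def test_bh_family_is_all_tested_pathways(self):
        universe = {f"G{i}" for i in range(20)}
        results = enrich(
            {"G0", "G1", "G2"},
            _collection(P1={"G0", "G1"}, P2={"G5", "G6"}, P3={"G0", "G7"}),
            universe,
        )
        qs = bh_adjust([r.p for r in results])
        assert [r.q for r in results] == pytest.approx([max(q, r.p) for q, r in zip(qs, results)])


class TestTopAndShared:
    def _results(self, n):
        out = []
        for i in range(n):
            p = (i + 1) / (n + 1)
            out.append(
                EnrichmentResult(
                    query_id="m", pathway_id=f"P{i:02d}", pathway_name="x",
                    k=1, K=2, n=3, N=10, p=p, q=min(1.0, p * 2), overlap=("G",),
                )
            )
        return out

    def test_top_n_order_and_short_input(self):
        res = self._results(12)
        top = top_pathways(res, 10)
        assert len(top) == 10 and [r.pathway_id for r in top] == sorted(
            r.pathway_id for r in res
        )[:10]
        assert top_pathways(self._results(3), 10) == self._results(3)

    def test_ties_broken_by_pathway_id(self):
        a = EnrichmentResult("m", "PB", "x", 1, 2, 3, 10, 0.1, 0.2, ("G",))
        b = EnrichmentResult("m", "PA", "x", 1, 2, 3, 10, 0.1, 0.2, ("G",))
        assert [r.pathway_id for r in top_pathways([a, b], 2)] == ["PA", "PB"]

    def test_shared_threshold_boundary(self):
        per_query = {
            "m1": {"P1", "P2"}, "m2": {"P1"}, "m3": {"P1"}, "m4": {"P2"}, "m5": set(),
        }
        records = shared_pathways(per_query, min_queries=3)
        assert [(r.pathway_id, r.count) for r in records] == [("P1", 3)]
        assert {r.pathway_id for r in shared_pathways(per_query, min_queries=2)} == {"P1", "P2"}
        with pytest.raises(ValueError):
            shared_pathways(per_query, min_queries=1)

    def test_significant_pathways_uses_q(self):
        res = [
            EnrichmentResult("m", "PA", "x", 1, 2, 3, 10, 0.001, 0.01, ("G",)),
            EnrichmentResult("m", "PB", "x", 1, 2, 3, 10, 0.04, 0.08, ("G",)),
        ]
        assert significant_pathways(res, alpha=0.05) == {"PA"}
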