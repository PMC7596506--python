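"""Unit and property tests for the ratio-variance screening core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refscreen import (
    ExpressionMatrix,
    delta_factor_matrix,
    find_reference_genes,
    relative_factor_matrix,
    screen_pair,
    stability_scores,
)

from conftest import oracle_pair_scores

positive_vectors = st.lists(
    st.floats(min_value=1e-3, max_value=1e6, allow_nan=False),
    min_size=2, max_size=12,
)


class TestRelativeFactorMatrix:
    @pytest.mark.parametrize(
        "sample, expected",
        [
            ([1, 1, 1], np.ones((3, 3))),
            ([2, 4], [[1.0, 0.5], [2.0, 1.0]]),
        ],
    )
    def test_known_ratio_matrices(self, sample, expected):
        f = relative_factor_matrix(sample)
        np.testing.assert_allclose(f.entries, expected)

    @settings(max_examples=50, deadline=None)
    @given(positive_vectors)
    def test_reciprocal_symmetry_and_unit_diagonal(self, sample):
        m = relative_factor_matrix(sample).entries
        np.testing.assert_allclose(np.diag(m), 1.0)
        np.testing.assert_allclose(m * m.T, 1.0, rtol=1e-9)
        assert (m > 0).all()

    def test_nonpositive_entry_rejected_with_gene_index(self):
        with pytest.raises(ValueError, match="index 2"):
            relative_factor_matrix([1.0, 2.0, 0.0, 4.0])


class TestDeltaFactorMatrix:
    def test_identical_samples_give_zero(self):
        f = relative_factor_matrix([3, 1, 4])
        np.testing.assert_array_equal(
            delta_factor_matrix(f, f).entries, np.zeros((3, 3))
        )

    def test_proportional_samples_give_zero(self):
        # ratios within a sample cancel any global scale factor
        f1 = relative_factor_matrix([2, 4])
        f2 = relative_factor_matrix([1, 2])
        np.testing.assert_allclose(
            delta_factor_matrix(f1, f2).entries, 0.0, atol=1e-12
        )

    def test_two_gene_swap(self):
        f1 = relative_factor_matrix([1, 2])
        f2 = relative_factor_matrix([2, 1])
        np.testing.assert_allclose(
            delta_factor_matrix(f1, f2).entries, [[0.0, -1.5], [1.5, 0.0]]
        )

    def test_mismatched_gene_ids_rejected(self):
        f1 = relative_factor_matrix([1, 2], ["a", "b"])
        f2 = relative_factor_matrix([1, 2], ["a", "c"])
        with pytest.raises(ValueError, match="different gene sets"):
            delta_factor_matrix(f1, f2)


class TestStabilityScores:
    def test_zero_delta_gives_zero_scores(self):
        f = relative_factor_matrix([5, 6, 7])
        s = stability_scores(delta_factor_matrix(f, f))
        np.testing.assert_array_equal(s.scores, 0.0)

    def test_three_gene_closed_form(self):
        # population variances of the normalizer columns for samples
        # [1,2,3] vs [2,3,4], computed by the two-loop reference
        f1 = relative_factor_matrix([1, 2, 3])
        f2 = relative_factor_matrix([2, 3, 4])
        s = stability_scores(delta_factor_matrix(f1, f2))
        expected = oracle_pair_scores([1, 2, 3], [2, 3, 4])
        np.testing.assert_allclose(expected, [1 / 6, 1 / 54, 1 / 216])
        np.testing.assert_allclose(s.scores, expected, rtol=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(positive_vectors, st.integers(0, 2**31 - 1))
    def test_nonnegative_and_matches_oracle(self, a, seed):
        b = np.random.default_rng(seed).uniform(0.1, 100, len(a))
        f1 = relative_factor_matrix(a)
        f2 = relative_factor_matrix(b)
        s = stability_scores(delta_factor_matrix(f1, f2))
        assert (s.scores >= 0).all()
        np.testing.assert_allclose(
            s.scores, oracle_pair_scores(list(a), list(b)), rtol=1e-9
        )


class TestScreenPair:
    def test_returns_exactly_k(self, planted):
        expr, _ = planted
        ranking = screen_pair(expr, "S1", "S2", k=20)
        assert len(ranking) == 20
        scores = [s for _, s in ranking.entries]
        assert scores == sorted(scores)

    def test_proportional_samples_tie_break_lexicographic(
        self, proportional_matrix
    ):
        ranking = screen_pair(proportional_matrix, "S1", "S3", k=5)
        assert [s for _, s in ranking.entries] == [0.0] * 5
        assert ranking.genes == sorted(proportional_matrix.gene_ids)[:5]

    def test_single_block_matches_two_loop_oracle(self):
        rng = np.random.default_rng(7)
        n = 120
        values = rng.uniform(1, 1000, (n, 2))
        expr = ExpressionMatrix(
            [f"g{i:03d}" for i in range(n)], ["A", "B"], values
        )
        ranking = screen_pair(expr, "A", "B", k=n, block_size=n)
        expected = oracle_pair_scores(values[:, 0], values[:, 1])
        got = dict(ranking.entries)
        for i, gid in enumerate(expr.gene_ids):
            assert got[gid] == pytest.approx(expected[i], rel=1e-9)

    def test_blockwise_scores_use_within_block_normalizers(self):
        rng = np.random.default_rng(11)
        n, bs = 250, 100
        values = rng.uniform(1, 500, (n, 2))
        expr = ExpressionMatrix(
            [f"g{i:03d}" for i in range(n)], ["A", "B"], values
        )
        ranking = screen_pair(expr, "A", "B", k=n, block_size=bs)
        got = dict(ranking.entries)
        for start in range(0, n, bs):
            stop = min(start + bs, n)
            block = oracle_pair_scores(
                values[start:stop, 0], values[start:stop, 1]
            )
            for i, score in enumerate(block, start=start):
                assert got[expr.gene_ids[i]] == pytest.approx(score, rel=1e-9)

    def test_scale_invariance_of_ranking(self, planted):
        expr, _ = planted
        reference = screen_pair(expr, "S1", "S2").entries
        for c in (0.1, 10.0):
            scaled = expr.copy()
            scaled.values[:, 0] *= c
            result = screen_pair(scaled, "S1", "S2").entries
            assert [g for g, _ in result] == [g for g, _ in reference]
            np.testing.assert_allclose(
                [s for _, s in result], [s for _, s in reference], rtol=1e-9
            )

    def test_nonpositive_genes_dropped_before_scoring(self):
        values = np.array([[1.0, 2.0], [0.0, 3.0], [2.0, 4.0], [5.0, -1.0]])
        expr = ExpressionMatrix(["a", "b", "c", "d"], ["A", "B"], values)
        ranking = screen_pair(expr, "A", "B", k=10)
        assert set(ranking.genes) == {"a", "c"}

    def test_pseudocount_repairs_nonpositive_genes(self):
        values = np.array([[1.0, 2.0], [0.0, 3.0], [2.0, 4.0]])
        expr = ExpressionMatrix(["a", "b", "c"], ["A", "B"], values)
        ranking = screen_pair(expr, "A", "B", k=10, pseudocount=1.0)
        assert set(ranking.genes) == {"a", "b", "c"}

    def test_unknown_sample_rejected(self, small_matrix):
        with pytest.raises(KeyError, match="nope"):
            screen_pair(small_matrix, "A", "nope")


class TestFindReferenceGenes:
    def test_depth_two_equals_screen_pair(self, planted):
        expr, _ = planted
        direct = screen_pair(expr, "S1", "S2")
        viadepth = find_reference_genes(expr, depth=2)
        assert viadepth.entries == direct.entries
        assert viadepth.score_kind == "sigma2"

    def test_proportional_depth_three_matches_depth_two_genes(
        self, proportional_matrix
    ):
        d2 = find_reference_genes(proportional_matrix, 2, k=10)
        d3 = find_reference_genes(proportional_matrix, 3, k=10)
        assert set(d3.genes) == set(d2.genes)
        assert d3.score_kind == "rank_sum"

    def test_intersection_shrinks_with_depth(self, planted):
        expr, _ = planted
        results = {d: set(find_reference_genes(expr, d).genes) for d in (2, 3, 4)}
        assert results[4] <= results[3] <= results[2]

    def test_rank_sum_ordering_is_ascending(self, planted):
        expr, _ = planted
        d3 = find_reference_genes(expr, 3)
        sums = [s for _, s in d3.entries]
        assert sums == sorted(sums)
        assert len(d3.pairs) == 3

    @pytest.mark.parametrize("depth", [0, 1, 5])
    def test_depth_bounds_enforced(self, depth, proportional_matrix):
        with pytest.raises(ValueError, match="fewer than 2 or more than"):
            find_reference_genes(proportional_matrix, depth)

    def test_explicit_sample_subset(self, planted):
        expr, _ = planted
        sub = find_reference_genes(expr, 2, samples=["S3", "S4"])
        assert sub.pairs == [("S3", "S4")]
        assert sub.entries == screen_pair(expr, "S3", "S4").entries
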