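"""Scoring pipeline: hand-worked examples, a straight-line brute-force
oracle, and the algebraic invariants (beta monotonicity, bounds, Pearson
scale invariance, overlap column masking)."""

import math

import numpy as np
import pytest

from _oracles import brute_force_score, brute_pearson, random_instance
from ppienrich.io import EdgeList, EmbeddingTable, GeneSet, GeneSetCollection, QueryList
from ppienrich.scoring import (
    ScoringConfig,
    SetEncoding,
    apply_filter,
    apply_overlap_mask,
    correlation_matrix,
    count_correlation_entries,
    count_interactions,
    decompose,
    enrich,
    pearson,
    score_pair,
    weighted_score,
)

BETAS = [1, 2, 5, 10, 40, 100]


def pipeline_score(q_ids, q, p_ids, p, beta, threshold=0.9):
    bd = score_pair(
        SetEncoding(tuple(q_ids), q),
        SetEncoding(tuple(p_ids), p),
        ScoringConfig(beta=beta, corr_threshold=threshold),
    )
    return bd


class TestPearson:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3], [1, 1, 2], math.sqrt(3) / 2),  # 0.8660 by direct evaluation
            ([1, 2, 3], [5, 5, 5], 0.0),  # zero-variance convention
        ],
    )
    def test_known_values(self, u, v, expected):
        assert pearson(np.array(u, float), np.array(v, float)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_length_mismatch_and_short_vectors(self):
        with pytest.raises(ValueError):
            pearson(np.ones(3), np.ones(4))
        with pytest.raises(ValueError, match=">= 3"):
            pearson(np.ones(2), np.ones(2))


class TestCorrelationMatrix:
    def test_self_correlation_diagonal(self, rng):
        enc = SetEncoding(("A", "B"), rng.standard_normal((2, 6)))
        C = correlation_matrix(enc, enc)
        np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-12)

    def test_matches_brute_force_loop(self, rng):
        q = SetEncoding(("A", "B", "C"), rng.standard_normal((3, 8)))
        p = SetEncoding(("D", "E", "F", "G"), rng.standard_normal((4, 8)))
        C = correlation_matrix(q, p)
        for k in range(3):
            for l in range(4):
                assert C[k, l] == pytest.approx(
                    brute_pearson(list(q.matrix[k]), list(p.matrix[l])), abs=1e-12
                )

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="dimension"):
            correlation_matrix(
                SetEncoding(("A",), rng.standard_normal((1, 5))),
                SetEncoding(("B",), rng.standard_normal((1, 6))),
            )


class TestFilterAndMask:
    def test_strict_threshold(self):
        np.testing.assert_array_equal(apply_filter(np.array([[0.95, 0.5]])), [[0.95, 0.0]])
        np.testing.assert_array_equal(apply_filter(np.array([[0.9]]), 0.9), [[0.0]])
        assert not apply_filter(-np.ones((2, 2))).any()

    def test_overlap_mask_worked_example(self):
        filtered = np.array([[0.97, 0.95], [0.93, 0.92]])
        masked, pairs = apply_overlap_mask(filtered, ["A", "X"], ["A", "Y"])
        np.testing.assert_array_equal(masked, [[1.0, 0.95], [0.0, 0.92]])
        assert pairs == ((0, 0),)

    def test_no_shared_identifiers_is_identity(self, rng):
        filtered = rng.random((3, 3))
        masked, pairs = apply_overlap_mask(filtered, ["A", "B", "C"], ["D", "E", "F"])
        np.testing.assert_array_equal(masked, filtered)
        assert pairs == ()

    def test_identical_sets_identity_pattern(self):
        filtered = np.full((2, 2), 0.95)
        masked, pairs = apply_overlap_mask(filtered, ["A", "B"], ["A", "B"])
        np.testing.assert_array_equal(masked, np.eye(2))
        assert set(pairs) == {(0, 0), (1, 1)}

    def test_every_overlap_column_has_exactly_one_nonzero(self, rng):
        for _ in range(20):
            q_ids, q, p_ids, p = random_instance(rng)
            raw = correlation_matrix(SetEncoding(tuple(q_ids), q), SetEncoding(tuple(p_ids), p))
            masked, pairs = apply_overlap_mask(apply_filter(raw), q_ids, p_ids)
            for _, l in pairs:
                assert np.count_nonzero(masked[:, l]) == 1


class TestDecompose:
    def test_worked_example_and_reconstruction(self):
        masked = np.array([[1.0, 0.95], [0.0, 0.92]])
        C_ov, C_int = decompose(masked, [(0, 0)])
        np.testing.assert_array_equal(C_ov, [[1, 0], [0, 0]])
        np.testing.assert_array_equal(C_int, [[0, 0.95], [0, 0.92]])
        np.testing.assert_array_equal(C_ov + C_int, masked)

    def test_degenerate_cases(self):
        z = np.zeros((2, 2))
        C_ov, C_int = decompose(z, [])
        assert not C_ov.any() and not C_int.any()
        eye = np.eye(2)
        C_ov, C_int = decompose(eye, [(0, 0), (1, 1)])
        assert not C_int.any()


class TestWeightedScore:
    def test_hand_arithmetic(self):
        C_ov = np.array([[1.0, 0.0], [0.0, 0.0]])
        C_int = np.array([[0.0, 0.95], [0.0, 0.92]])
        maxC, score = weighted_score(C_ov, C_int, beta=10)
        np.testing.assert_array_equal(maxC, [10.0, 0.92])
        assert score == pytest.approx(5.46)
        maxC, score = weighted_score(C_ov, C_int, beta=1)
        np.testing.assert_array_equal(maxC, [1.0, 0.92])
        assert score == pytest.approx(0.96)

    def test_empty_and_zero(self):
        assert weighted_score(np.zeros((3, 2)), np.zeros((3, 2)), 10)[1] == 0.0
        assert weighted_score(np.zeros((0, 0)), np.zeros((0, 0)), 10)[1] == 0.0


class TestCountInteractions:
    def test_enumeration(self):
        edges = EdgeList([("A", "B", 1), ("A", "C", 1), ("B", "C", 1)])
        assert count_interactions(["A", "B"], ["B", "C"], edges) == 3
        assert count_interactions(["A"], ["B"], EdgeList([("A", "B", 1)])) == 1
        assert count_interactions(["A"], ["B"], EdgeList([("C", "D", 1)])) == 0

    def test_correlation_entry_counter(self, rng):
        q_ids, q, p_ids, p = random_instance(rng)
        bd = pipeline_score(q_ids, q, p_ids, p, beta=1)
        assert count_correlation_entries(bd) == np.count_nonzero(bd.C_interaction)


class TestPipelineProperties:
    def test_oracle_equivalence_100_random_instances(self, rng):
        """Full pipeline equals a nested-loop reimplementation to 1e-12."""
        for i in range(100):
            q_ids, q, p_ids, p = random_instance(rng)
            beta = BETAS[i % len(BETAS)]
            expected = brute_force_score(q_ids, [list(r) for r in q], p_ids,
                                         [list(r) for r in p], beta, 0.9)
            bd = pipeline_score(q_ids, q, p_ids, p, beta)
            assert bd.score == pytest.approx(expected, abs=1e-12)

    def test_beta_monotonicity(self, rng):
        for _ in range(20):
            q_ids, q, p_ids, p = random_instance(rng)
            scores = [pipeline_score(q_ids, q, p_ids, p, b).score for b in BETAS]
            assert all(s2 >= s1 - 1e-12 for s1, s2 in zip(scores, scores[1:]))

    def test_bounds(self, rng):
        for _ in range(20):
            q_ids, q, p_ids, p = random_instance(rng)
            for beta in (1, 10, 100):
                bd = pipeline_score(q_ids, q, p_ids, p, beta)
                assert 0 <= bd.score <= beta
                if not bd.overlap_pairs:
                    assert bd.score <= 1.0

    def test_overlap_dominance_limit(self, rng):
        """For large beta the score approaches
        beta * (#overlap rows)/N + (sum of non-overlap row maxima)/N."""
        for _ in range(10):
            q_ids, q, p_ids, p = random_instance(rng)
            bd = pipeline_score(q_ids, q, p_ids, p, beta=1e6)
            overlap_rows = {k for k, _ in bd.overlap_pairs}
            n = len(q_ids)
            residual = sum(
                bd.C_interaction[k].max() if bd.C_interaction.shape[1] else 0.0
                for k in range(n)
                if k not in overlap_rows
            )
            closed_form = 1e6 * len(overlap_rows) / n + residual / n
            assert bd.score == pytest.approx(closed_form, rel=1e-12)

    def test_scale_and_offset_invariance(self, rng):
        q_ids, q, p_ids, p = random_instance(rng)
        base = pipeline_score(q_ids, q, p_ids, p, beta=10).score
        shifted = pipeline_score(q_ids, 3.7 * q + 11.0, p_ids, 3.7 * p + 11.0, beta=10).score
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_reconstruction_invariant(self, rng):
        q_ids, q, p_ids, p = random_instance(rng)
        bd = pipeline_score(q_ids, q, p_ids, p, beta=10)
        np.testing.assert_allclose(bd.C_overlap + bd.C_interaction, bd.C, atol=1e-15)
        assert set(np.unique(bd.C_overlap)) <= {0.0, 1.0}


class TestEnrich:
    @staticmethod
    def world(rng, d=16):
        ids = [f"G{i}" for i in range(12)]
        table = EmbeddingTable(ids, rng.standard_normal((12, d)))
        query = QueryList(tuple(ids[:4]))
        return ids, table, query

    def test_self_pathway_scores_one_at_beta_1(self, rng):
        ids, table, query = self.world(rng)
        coll = GeneSetCollection("c", (GeneSet("SELF", "", query.identifiers),))
        res = enrich(query, coll, table, ScoringConfig(beta=1.0))
        assert res[0].score == 1.0
        assert res[0].overlap == 4
        assert res[0].coverage == 1.0

    def test_unrelated_pathway_scores_zero(self, rng):
        ids, table, query = self.world(rng)
        coll = GeneSetCollection("c", (GeneSet("FAR", "", tuple(ids[4:8])),))
        res = enrich(query, coll, table, ScoringConfig(beta=1.0))
        # independent gaussian embeddings at d=16 essentially never pass 0.9
        assert res[0].score == 0.0

    def test_planted_block_ranks_first(self, planted_table, mixed_world):
        coll, query = mixed_world
        res = enrich(query, coll, planted_table, ScoringConfig(beta=1.0))
        best = max(res, key=lambda r: r.score)
        assert best.pathway_id.startswith("OVERLAP_FREE_LINKED")

    def test_pathway_without_embeddings_is_skipped(self, rng):
        ids, table, query = self.world(rng)
        coll = GeneSetCollection(
            "c", (GeneSet("GHOST", "", ("NOPE1", "NOPE2")), GeneSet("SELF", "", query.identifiers))
        )
        res = enrich(query, coll, table, ScoringConfig(beta=1.0))
        assert res[0].skipped and res[0].score == 0.0
        assert not res[1].skipped

    def test_unencodable_query_is_error(self, rng):
        ids, table, _ = self.world(rng)
        coll = GeneSetCollection("c", (GeneSet("P", "", (ids[0],)),))
        with pytest.raises(ValueError, match="query"):
            enrich(QueryList(("MISSING",)), coll, table)

    def test_missing_as_zero_divides_by_full_query(self, rng):
        ids, table, _ = self.world(rng)
        query = QueryList((ids[0], ids[1], "MISSING"))
        coll = GeneSetCollection("c", (GeneSet("P", "", (ids[0], ids[1])),))
        drop = enrich(query, coll, table, ScoringConfig(beta=1.0))[0].score
        keep = enrich(query, coll, table, ScoringConfig(beta=1.0, missing_as_zero=True))[0].score
        assert drop == pytest.approx(1.0)
        assert keep == pytest.approx(2.0 / 3.0)
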