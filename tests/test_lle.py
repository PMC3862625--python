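"""Neighbor graphs, reconstruction weights, patch/alignment matrices, LLE."""

import numpy as np
import pytest

from mvlle.lle import (
    alignment_matrix,
    build_neighbor_graph,
    geodesic_distances,
    lle_embed,
    patch_matrix,
    reconstruction_weights,
)


class TestNeighborGraph:
    def test_line_points_nearest_two(self):
        x = np.array([[0.0], [1.0], [2.0], [10.0]])
        g = build_neighbor_graph(x, K=2)
        assert set(g.indices[0]) == {1, 2}

    def test_l1_and_l2_orderings_differ(self):
        # nearest to the origin is (2,2) under L2 (2.83 < 3) but (3,0)
        # under L1 (3 < 4)
        x = np.array([[0.0, 0.0], [3.0, 0.0], [2.0, 2.0]])
        assert build_neighbor_graph(x, 1, "l2").indices[0][0] == 2
        assert build_neighbor_graph(x, 1, "l1").indices[0][0] == 1

    def test_geodesic_matches_floyd_warshall(self, rng):
        x = rng.standard_normal((12, 3))
        got = geodesic_distances(x, base_k=3)
        # independent Floyd-Warshall on the same symmetrized K-NN graph
        d = np.linalg.norm(x[:, None] - x[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        adj = np.full((12, 12), np.inf)
        for i in range(12):
            for j in np.argsort(d[i], kind="stable")[:3]:
                adj[i, j] = adj[j, i] = d[i, j]
        np.fill_diagonal(adj, 0.0)
        for k in range(12):
            adj = np.minimum(adj, adj[:, k : k + 1] + adj[k : k + 1, :])
        assert np.isfinite(adj).all(), "fixture graph must be connected"
        assert np.allclose(got, adj)

    def test_geodesic_follows_arc_length_on_a_horseshoe(self):
        """On a nearly-closed circular arc the endpoints are close in chord
        but far in arc length, so geodesic and L2 neighborhoods differ."""
        t = np.linspace(0, 1.9 * np.pi, 60)
        x = np.column_stack([np.cos(t), np.sin(t)])
        l2 = build_neighbor_graph(x, 5, "l2")
        geo = build_neighbor_graph(x, 5, "geodesic", geodesic_base_k=3)
        assert 59 in l2.indices[0]  # other arm is the chordal neighbor
        assert 59 not in geo.indices[0]
        assert set(geo.indices[0]) == {1, 2, 3, 4, 5}

    def test_disconnected_geodesic_names_component_count(self):
        x = np.array([[0.0], [0.1], [0.2], [100.0], [100.1], [100.2]])
        with pytest.raises(ValueError, match="2 components"):
            geodesic_distances(x, base_k=1)

    def test_no_self_neighbors_and_k_bound(self, rng):
        x = rng.standard_normal((20, 2))
        g = build_neighbor_graph(x, 6)
        assert not (g.indices == np.arange(20)[:, None]).any()
        with pytest.raises(ValueError):
            build_neighbor_graph(x, 20)


class TestReconstructionWeights:
    def test_midpoint_of_symmetric_neighbors(self):
        c = reconstruction_weights(np.array([0.0]), np.array([[-1.0], [1.0]]), reg=1e-10)
        assert np.allclose(c, [0.5, 0.5])

    def test_interior_point_recovers_barycentric_coordinates(self):
        tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        x = np.array([0.25, 0.35])
        c = reconstruction_weights(x, tri, reg=0.0)
        # independent barycentric solve
        A = np.vstack([tri.T, np.ones(3)])
        bary = np.linalg.solve(A, np.append(x, 1.0))
        assert np.allclose(c, bary)
        assert np.allclose(c @ tri, x)

    def test_singular_gram_succeeds_with_regularization(self, rng):
        # K=5 neighbors in 2-D: Gram rank <= 2, solvable only via the
        # regularized diagonal
        x = rng.standard_normal(2)
        nbrs = rng.standard_normal((5, 2))
        c = reconstruction_weights(x, nbrs, reg=1e-3)
        assert c.sum() == pytest.approx(1.0)

    def test_translation_invariance(self, rng):
        x = rng.standard_normal(4)
        nbrs = rng.standard_normal((6, 4))
        shift = rng.standard_normal(4)
        c1 = reconstruction_weights(x, nbrs)
        c2 = reconstruction_weights(x + shift, nbrs + shift)
        assert np.allclose(c1, c2)


class TestPatchMatrix:
    def test_k1_block_form(self):
        assert np.array_equal(patch_matrix([1.0]), [[1, -1], [-1, 1]])

    def test_trace_form_equals_reconstruction_error(self, rng):
        for _ in range(5):
            c = rng.standard_normal(4)
            c /= c.sum()
            Yi = rng.standard_normal((3, 5))  # d x (K+1) patch coordinates
            li = patch_matrix(c)
            err = np.linalg.norm(Yi[:, 0] - Yi[:, 1:] @ c) ** 2
            assert np.trace(Yi @ li @ Yi.T) == pytest.approx(err)

    def test_rows_sum_to_zero(self, rng):
        c = rng.standard_normal(6)
        c /= c.sum()
        assert np.allclose(patch_matrix(c).sum(axis=1), 0.0, atol=1e-12)


class TestAlignmentMatrix:
    def test_three_collinear_points_hand_assembly(self):
        x = np.array([[0.0], [1.0], [2.0]])
        L = alignment_matrix(x, K=2, reg=1e-9).toarray()
        # manual scatter of the three 3x3 patch contributions
        g = build_neighbor_graph(x, 2)
        expected = np.zeros((3, 3))
        for i in range(3):
            c = reconstruction_weights(x[i], x[g.indices[i]], reg=1e-9)
            li = patch_matrix(c)
            pos = np.concatenate([[i], g.indices[i]])
            expected[np.ix_(pos, pos)] += li
        assert np.allclose(L, expected)

    def test_equals_i_minus_w_quadratic_form(self, rng):
        """Independent assembly: L == (I-W)^T (I-W) to machine precision."""
        x = rng.standard_normal((30, 4))
        K = 6
        L = alignment_matrix(x, K).toarray()
        g = build_neighbor_graph(x, K)
        W = np.zeros((30, 30))
        for i in range(30):
            W[i, g.indices[i]] = reconstruction_weights(x[i], x[g.indices[i]])
        ref = (np.eye(30) - W).T @ (np.eye(30) - W)
        assert np.abs(L - ref).max() < 1e-12

    def test_annihilates_ones_and_is_psd(self, rng):
        x = rng.standard_normal((25, 3))
        L = alignment_matrix(x, 5)
        assert np.abs(L @ np.ones(25)).max() < 1e-10
        assert np.linalg.eigvalsh(L.toarray()).min() > -1e-10
        assert L.nnz <= 25 * 36


class TestLleEmbed:
    def test_affine_subspace_data_has_near_zero_objective(self, rng):
        z = rng.standard_normal((50, 2))
        x = z @ rng.standard_normal((2, 8))
        L = alignment_matrix(x, 8, reg=1e-3)
        Y = lle_embed(x, 2, 8, reg=1e-3)
        assert np.sum(Y * (L @ Y)) < 1e-4

    def test_columns_are_orthonormal(self, rng):
        x = rng.standard_normal((40, 6))
        Y = lle_embed(x, 3, 8)
        assert np.allclose(Y.T @ Y, np.eye(3), atol=1e-10)

    def test_beats_random_orthonormal_frames(self, rng):
        x = rng.standard_normal((20, 4))
        L = alignment_matrix(x, 5)
        Y = lle_embed(x, 2, 5)
        ours = np.sum(Y * (L @ Y))
        for _ in range(1000):
            q, _ = np.linalg.qr(rng.standard_normal((20, 2)))
            assert ours <= np.sum(q * (L @ q)) + 1e-12
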