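import numpy as np
import pytest

from mogcan.affinity_graph import (SingularDegreeError, affinity_kernel,
                                   build_affinity, degree_and_laplacian,
                                   dynamic_threshold_select,
                                   pairwise_squared_distance, scaling_factor,
                                   sparsify, sparsify_graph)
from oracles import (affinity_loops, min_p_full_rank_loops,
                     scaling_factor_loops, squared_distance_loops)


class TestPairwiseSquaredDistance:
    def test_identical_points_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0]])
        rho = pairwise_squared_distance(X)
        assert rho[0, 1] == 0.0

    def test_three_four_five(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert pairwise_squared_distance(X)[0, 1] == pytest.approx(25.0)

    def test_matches_brute_force(self, rng):
        X = rng.normal(size=(5, 3))
        np.testing.assert_allclose(pairwise_squared_distance(X),
                                   squared_distance_loops(X), atol=1e-10)

    def test_symmetric_zero_diagonal(self, rng):
        rho = pairwise_squared_distance(rng.normal(size=(7, 4)))
        np.testing.assert_allclose(rho, rho.T)
        np.testing.assert_allclose(np.diag(rho), 0.0, atol=1e-12)

    def test_missing_values_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="missing"):
            pairwise_squared_distance(X)


class TestScalingFactor:
    def test_constant_distances(self):
        n, c = 5, 3.7
        rho = np.full((n, n), c)
        np.fill_diagonal(rho, 0.0)
        nu = scaling_factor(rho, k_neighbors=n - 1)
        off = ~np.eye(n, dtype=bool)
        np.testing.assert_allclose(nu[off], c)

    def test_four_point_toy_matches_hand(self, rng):
        X = rng.normal(size=(4, 2))
        rho = pairwise_squared_distance(X)
        np.testing.assert_allclose(scaling_factor(rho, 2),
                                   scaling_factor_loops(rho, 2), atol=1e-12)

    def test_k_max_equals_full_mean(self, rng):
        rho = pairwise_squared_distance(rng.normal(size=(6, 3)))
        n = 6
        nu = scaling_factor(rho, n - 1)
        # closed form: mean over all other samples
        full_mean = rho.sum(axis=1) / (n - 1)
        expected = (full_mean[:, None] + full_mean[None, :] + rho) / 3.0
        np.testing.assert_allclose(nu, expected, atol=1e-12)

    def test_clamps_large_k_with_warning(self, rng):
        rho = pairwise_squared_distance(rng.normal(size=(4, 2)))
        with pytest.warns(UserWarning, match="clamping"):
            nu = scaling_factor(rho, 10)
        np.testing.assert_allclose(nu, scaling_factor(rho, 3))

    def test_symmetric(self, rng):
        rho = pairwise_squared_distance(rng.normal(size=(8, 3)))
        nu = scaling_factor(rho, 3)
        np.testing.assert_allclose(nu, nu.T)


class TestAffinityKernel:
    def test_zero_distance_gives_one(self):
        rho = np.zeros((2, 2))
        nu = np.ones((2, 2))
        A = affinity_kernel(rho, nu, mu=0.5)
        assert A[0, 1] == pytest.approx(1.0)

    def test_unit_exponent(self):
        mu = 0.5
        nu = np.full((2, 2), 2.0)
        rho = np.full((2, 2), mu * 2.0)  # rho = mu * nu -> exp(-1)
        np.fill_diagonal(rho, 0.0)
        A = affinity_kernel(rho, nu, mu)
        assert A[0, 1] == pytest.approx(np.exp(-1))

    def test_toy_matrix_matches_scalar_oracle(self, toy):
        X = toy[0][0].values
        graph = build_affinity(X, k_neighbors=2, mu=0.5)
        np.testing.assert_allclose(graph.A, affinity_loops(X, 2, 0.5),
                                   atol=1e-12)

    def test_bounds_and_diagonal(self, rng):
        X = rng.normal(size=(12, 5))
        A = build_affinity(X, k_neighbors=4).A
        assert (A >= 0).all() and (A <= 1).all()
        np.testing.assert_allclose(np.diag(A), 1.0)
        np.testing.assert_allclose(A, A.T)

    def test_duplicate_samples_kernel_one(self):
        X = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0]])
        A = build_affinity(X, k_neighbors=1).A
        assert A[0, 1] == pytest.approx(1.0)

    def test_invalid_mu(self):
        with pytest.raises(ValueError, match="mu"):
            affinity_kernel(np.zeros((2, 2)), np.ones((2, 2)), mu=0.0)

    def test_snf_original_convention_runs(self, rng):
        X = rng.normal(size=(10, 4))
        g = build_affinity(X, 3, kernel_distance_convention="snf_original")
        assert (g.A >= 0).all() and (g.A <= 1).all()
        # conventions genuinely differ
        g2 = build_affinity(X, 3, kernel_distance_convention="paper_literal")
        assert not np.allclose(g.A, g2.A)


class TestSparsify:
    def test_keep_everything(self, random_affinity):
        A_sparse, eps, count = sparsify(random_affinity, 1.0)
        np.testing.assert_array_equal(A_sparse, random_affinity)
        assert count == random_affinity.size

    def test_top_three_by_hand(self):
        A = np.array([[0.9, 0.1, 0.2],
                      [0.4, 0.8, 0.3],
                      [0.5, 0.6, 0.7]])
        # top 3 of 9 distinct entries: 0.9, 0.8, 0.7 (the diagonal)
        A_sparse, eps, count = sparsify(A, 3 / 9)
        assert eps == pytest.approx(0.7)
        assert count == 3
        np.testing.assert_array_equal(A_sparse, np.diag([0.9, 0.8, 0.7]))

    def test_values_preserved_not_binarized(self, random_affinity):
        A_sparse, _, _ = sparsify(random_affinity, 0.2)
        nz = A_sparse != 0
        np.testing.assert_array_equal(A_sparse[nz], random_affinity[nz])

    def test_ties_at_threshold_all_kept(self):
        A = np.full((4, 4), 0.5)
        A[0, 1] = A[1, 0] = 0.9
        A_sparse, eps, count = sparsify(A, 3 / 16)
        # 3rd largest value is 0.5 -> every tied 0.5 entry retained
        assert eps == pytest.approx(0.5)
        assert count == 16

    def test_symmetrization_keeps_either_copy(self):
        A = np.array([[0.0, 0.9], [0.1, 0.0]])
        A_sparse, _, _ = sparsify(A, 1 / 4)
        # only (0,1)=0.9 makes the cut, but its mirror is kept too
        assert A_sparse[0, 1] == 0.9
        assert A_sparse[1, 0] == 0.1

    def test_invalid_fraction(self, random_affinity):
        with pytest.raises(ValueError):
            sparsify(random_affinity, 0.0)
        with pytest.raises(ValueError):
            sparsify(random_affinity, -0.1)

    def test_retained_count_monotone_in_p(self, rng):
        A = rng.random((15, 15))
        counts = [np.count_nonzero(sparsify(A, p)[0])
                  for p in np.linspace(0.05, 1.0, 12)]
        assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestDegreeAndLaplacian:
    def test_identity(self):
        D, L = degree_and_laplacian(np.eye(4))
        np.testing.assert_array_equal(D, np.eye(4))
        np.testing.assert_array_equal(L, np.eye(4))

    def test_zero_row_raises(self):
        A = np.eye(3)
        A[1, 1] = 0.0
        with pytest.raises(SingularDegreeError, match=r"\[1\]"):
            degree_and_laplacian(A)

    def test_rows_sum_to_one(self, rng):
        A = rng.random((5, 5)) + 0.01
        _, L = degree_and_laplacian(A)
        np.testing.assert_allclose(L.sum(axis=1), 1.0, atol=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            degree_and_laplacian(np.array([[1.0, -0.1], [0.0, 1.0]]))


def _pair_matrix(n, pair_values, background_scale=1e-4, seed=0):
    """Distinct-entry matrix whose largest values sit on disjoint pairs."""
    rng = np.random.default_rng(seed)
    A = rng.random((n, n)) * background_scale
    for rank, (i, j) in enumerate(pair_values):
        A[i, j] = 1.0 - rank * 0.01
    return A


class TestDynamicThresholdSelect:
    def test_first_candidate_succeeds(self, rng):
        X = rng.normal(size=(120, 10))
        A = build_affinity(X, 10).A
        # unit diagonal always ranks at the top, so p0 is full rank
        p_star, A_sparse, L = dynamic_threshold_select(A, 0.01, 0.005)
        assert p_star == 0.01
        np.testing.assert_allclose(L.sum(axis=1), 1.0, atol=1e-12)

    def test_constructed_20_node_case(self):
        # Top 10 entries are 10 disjoint pairs covering all 20 nodes; the
        # pair containing node 19 is the weakest of them. Grid points
        # 0.01/0.015/0.02 retain 4/6/8 entries and leave node 19 (among
        # others) isolated; 0.025 retains all 10 pairs.
        pairs = [(2 * k, 2 * k + 1) for k in range(10)]
        A = _pair_matrix(20, pairs)
        p_star, A_sparse, _ = dynamic_threshold_select(A, 0.01, 0.005)
        assert p_star == pytest.approx(0.025)
        for p_bad in (0.01, 0.015, 0.02):
            bad, _, _ = sparsify(A, p_bad)
            assert np.count_nonzero(bad[19]) == 0

    def test_p0_fails_0015_succeeds(self):
        # 34 nodes: 17 disjoint pairs need floor(p*34^2) >= 17 entries,
        # i.e. p = 0.015; p0 = 0.01 keeps only 11 of them.
        pairs = [(2 * k, 2 * k + 1) for k in range(17)]
        A = _pair_matrix(34, pairs)
        p_star, _, _ = dynamic_threshold_select(A, 0.01, 0.005)
        assert p_star == pytest.approx(0.015)

    def test_minimality_vs_exhaustive_scan(self, rng):
        for trial in range(20):
            n = int(rng.integers(4, 9))
            A = rng.random((n, n)) * 0.9
            p_star, A_sparse, _ = dynamic_threshold_select(A, 0.01, 0.005)
            expected = min_p_full_rank_loops(A, 0.01, 0.005)
            assert p_star == pytest.approx(expected)

    def test_predecessor_grid_point_fails(self):
        pairs = [(2 * k, 2 * k + 1) for k in range(10)]
        A = _pair_matrix(20, pairs)
        p_star, _, _ = dynamic_threshold_select(A, 0.01, 0.005)
        prev, _, _ = sparsify(A, p_star - 0.005)
        assert (np.count_nonzero(prev, axis=1) == 0).any()

    def test_full_rank_monotone_in_p(self, rng):
        A = rng.random((12, 12))
        p_star, _, _ = dynamic_threshold_select(A, 0.01, 0.005)
        for p in np.arange(p_star, 1.0, 0.1):
            A_sparse, _, _ = sparsify(A, min(p, 1.0))
            assert (np.count_nonzero(A_sparse, axis=1) > 0).all()

    def test_never_singular_at_selected_p(self, rng):
        for _ in range(10):
            A = rng.random((10, 10))
            p_star, A_sparse, _ = dynamic_threshold_select(A, 0.01, 0.005)
            degree_and_laplacian(A_sparse)  # must not raise

    def test_all_zero_row_errors(self):
        A = np.ones((3, 3))
        A[2, :] = 0.0
        A[:, 2] = 0.0
        with pytest.raises(SingularDegreeError, match="1.0"):
            dynamic_threshold_select(A)

    def test_invalid_grid(self, random_affinity):
        with pytest.raises(ValueError):
            dynamic_threshold_select(random_affinity, p0=0.0)
        with pytest.raises(ValueError):
            dynamic_threshold_select(random_affinity, step=0.0)


def test_sparsify_graph_fills_fields(rng):
    X = rng.normal(size=(50, 6))
    graph = build_affinity(X, 5)
    graph = sparsify_graph(graph)
    assert graph.retained_fraction is not None
    assert graph.A_sparse is not None
    np.testing.assert_allclose(graph.L.sum(axis=1), 1.0, atol=1e-12)
    edges = graph.edge_list()
    for i, j, w in edges:
        assert i < j
        assert w == graph.A_sparse[i, j]
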