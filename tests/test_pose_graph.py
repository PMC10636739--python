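"""Graph construction, cost, Jacobians, L-M optimisation, fusion modes."""

import numpy as np
import pytest

from endomosaic.geometry import AffineTransform, affine_exp, edge_error
from endomosaic.pose_graph import (
    PoseGraph,
    average_fusion,
    build_graph,
    chain_single_source,
    numerical_jacobian,
    optimize,
    total_cost,
)
from endomosaic.uncertainty import (
    Diagnostics,
    RegistrationEstimate,
    information_from_inliers,
)

T = AffineTransform.translation(4.0, 0.0)


def est(i, j, transform, info, source="flow", loop=False):
    if np.isscalar(info):
        info = info * np.eye(6)
    return RegistrationEstimate(
        i, j, source, transform, info,
        Diagnostics(n_inliers=50, n_correspondences=60, converged=True),
        is_loop=loop,
    )


def consistent_chain(n=5, n_sources=1, info=100.0):
    return [
        est(i, i + 1, T, info, source=s)
        for i in range(n - 1)
        for s in ("flow", "feature", "direct")[:n_sources]
    ]


class TestBuildGraph:
    def test_chained_initialisation(self):
        g = build_graph(consistent_chain(3), 3)
        assert np.array_equal(g.vertices[0].matrix, np.eye(3))
        assert g.vertices[1].almost_equal(T, tol=1e-12)
        assert g.vertices[2].almost_equal(T @ T, tol=1e-12)

    def test_all_failed_pair_gets_identity_bridge(self, caplog):
        edges = consistent_chain(3)
        dead = est(1, 2, T, 0.0)  # zero information = failed
        with caplog.at_level("WARNING"):
            g = build_graph([edges[0], dead], 3)
        assert "identity bridge" in caplog.text
        assert g.vertices[2].almost_equal(g.vertices[1], tol=1e-12)
        bridges = [e for e in g.edges if e.frame_i == 1 and e.info.any()]
        assert len(bridges) == 1
        assert np.allclose(np.diag(bridges[0].info), 1e-6)

    def test_edge_count_two_sources(self):
        n = 6
        edges = consistent_chain(n, n_sources=2)
        loop = est(0, 5, T, 50.0, loop=True)
        g = build_graph(edges + [loop], n)
        assert len([e for e in g.edges if not e.is_loop]) == 2 * (n - 1)
        assert len([e for e in g.edges if e.is_loop]) == 1

    def test_rejects_bad_frame_index(self):
        with pytest.raises(ValueError):
            build_graph([est(0, 7, T, 1.0)], 3)


class TestTotalCost:
    def test_consistent_chain_costs_zero(self):
        g = build_graph(consistent_chain(5), 5)
        assert total_cost(g) < 1e-16

    def test_hand_computed_single_edge(self):
        # e = (0,0,0,0,-1,0) against Omega with translation weight 1
        g = PoseGraph(
            [AffineTransform.identity(), AffineTransform.identity()],
            [est(0, 1, AffineTransform.translation(1.0, 0.0), information_from_inliers(1))],
        )
        assert total_cost(g) == pytest.approx(1.0, abs=1e-10)

    def test_cost_is_linear_in_information(self):
        edges = consistent_chain(4)
        g = build_graph(edges, 4)
        g.vertices[2] = g.vertices[2] @ AffineTransform.translation(0.5, -0.2)
        base = total_cost(g)
        doubled = [est(e.frame_i, e.frame_j, e.transform, 2 * e.info) for e in g.edges]
        assert total_cost(PoseGraph(g.vertices, doubled)) == pytest.approx(2 * base, rel=1e-12)

    def test_zero_information_edges_change_nothing(self):
        edges = consistent_chain(4)
        g = build_graph(edges, 4)
        g.vertices[1] = g.vertices[1] @ AffineTransform.translation(0.3, 0.1)
        with_dead = PoseGraph(
            g.vertices, g.edges + [est(0, 2, AffineTransform.translation(9, 9), 0.0)]
        )
        assert total_cost(with_dead) == pytest.approx(total_cost(g), abs=1e-12)


def dense_fd_jacobian(e, graph, step, which):
    """Independent forward/backward finite-difference oracle."""
    x_i, x_j = graph.vertices[e.frame_i], graph.vertices[e.frame_j]
    J = np.zeros((6, 6))
    for k in range(6):
        d = np.zeros(6)
        d[k] = step
        if which == "i":
            hi = edge_error(x_i @ affine_exp(d), x_j, e.transform)
            lo = edge_error(x_i @ affine_exp(-d), x_j, e.transform)
        else:
            hi = edge_error(x_i, x_j @ affine_exp(d), e.transform)
            lo = edge_error(x_i, x_j @ affine_exp(-d), e.transform)
        J[:, k] = (hi - lo) / (2 * step)
    return J


class TestNumericalJacobian:
    def test_identity_configuration_signs(self):
        g = PoseGraph(
            [AffineTransform.identity(), AffineTransform.identity()],
            [est(0, 1, AffineTransform.identity(), 1.0)],
        )
        J_i, J_j = numerical_jacobian(g.edges[0], g, step=1e-6)
        assert np.max(np.abs(J_j - np.eye(6))) < 1e-6
        assert np.max(np.abs(J_i + np.eye(6))) < 1e-6

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(5)
        vertices = [affine_exp(rng.normal(0, 0.2, 6)) for _ in range(3)]
        e = est(0, 2, vertices[0].inverse() @ vertices[2] @ affine_exp(rng.normal(0, 0.01, 6)), 1.0)
        g = PoseGraph(vertices, [e])
        J_i, J_j = numerical_jacobian(e, g, step=1e-6)
        assert np.max(np.abs(J_i - dense_fd_jacobian(e, g, 2e-6, "i"))) < 1e-6
        assert np.max(np.abs(J_j - dense_fd_jacobian(e, g, 2e-6, "j"))) < 1e-6

    def test_central_difference_step_stability(self):
        # halving the step changes entries only at second order
        g = PoseGraph(
            [affine_exp(np.full(6, 0.1)), affine_exp(np.full(6, -0.1))],
            [est(0, 1, AffineTransform.translation(1, 1), 1.0)],
        )
        J1, _ = numerical_jacobian(g.edges[0], g, step=1e-4)
        J2, _ = numerical_jacobian(g.edges[0], g, step=5e-5)
        assert np.max(np.abs(J1 - J2)) < 1e-7


class TestOptimize:
    def test_consistent_chain_already_optimal(self):
        g = build_graph(consistent_chain(5), 5)
        expect = [v.matrix.copy() for v in g.vertices]
        g2, state = optimize(g)
        assert state.converged
        assert state.cost < 1e-16
        for got, want in zip(g2.vertices, expect):
            assert np.max(np.abs(got.matrix - want)) < 1e-8

    def test_two_edge_information_weighted_mean(self):
        # two translation measurements (2,0) and (4,0) with weights 3:1
        # fuse to (2.5, 0) (commuting pure translations: exact closed form)
        w2 = 10.0
        edges = [
            est(0, 1, AffineTransform.translation(2.0, 0.0), 3 * w2),
            est(0, 1, AffineTransform.translation(4.0, 0.0), w2),
        ]
        g = build_graph(edges, 2)
        g2, state = optimize(g)
        assert state.converged
        assert np.allclose(g2.vertices[1].translation_vector, [2.5, 0.0], atol=1e-3)

    def test_anchor_is_gauge_fixed(self):
        edges = consistent_chain(4)
        edges[1] = est(1, 2, AffineTransform.translation(4.5, 0.3), 100.0)
        g = build_graph(edges, 4)
        g2, _ = optimize(g)
        assert np.array_equal(g2.vertices[0].matrix, np.eye(3))

    def test_corrupted_low_weight_edge_barely_moves_solution(self):
        # consistent high-information chain plus one grossly wrong
        # low-information edge: corruption is suppressed by ~w_lo/w_hi.
        # Both edges carry the method's 100:1 linear-to-translation
        # information structure, which also pins the linear blocks.
        n = 5
        edges = consistent_chain(n, info=information_from_inliers(100))
        corrupt = est(
            0, 2, AffineTransform.translation(58.0, 30.0),
            1e-4 * information_from_inliers(100),
        )
        truth = [np.linalg.matrix_power(T.matrix, k) for k in range(n)]
        g = build_graph(edges + [corrupt], n)
        g2, _ = optimize(g)
        size = 100.0
        corners = np.array([[0, 0], [size, 0], [0, size], [size, size]])
        worst = max(
            np.abs(AffineTransform(t).apply(corners) - v.apply(corners)).max()
            for t, v in zip(truth, g2.vertices)
        )
        assert worst < 0.01 * 50  # < 1% of the corruption magnitude

    def test_accepted_iterations_monotone(self):
        rng = np.random.default_rng(1)
        edges = []
        for i in range(9):
            noisy = T.matrix.copy()
            noisy[:2, 2] += rng.normal(0, 0.5, 2)
            edges.append(est(i, i + 1, AffineTransform(noisy), 100.0))
            edges.append(est(i, i + 1, T, 50.0, source="feature"))
        g = build_graph(edges, 10)
        _, state = optimize(g)
        assert all(b <= a for a, b in zip(state.cost_history, state.cost_history[1:]))

    def test_zero_information_edges_do_not_shift_optimum(self):
        rng = np.random.default_rng(2)
        edges = []
        for i in range(4):
            noisy = T.matrix.copy()
            noisy[:2, 2] += rng.normal(0, 0.3, 2)
            edges.append(est(i, i + 1, AffineTransform(noisy), 100.0))
        dead = est(0, 3, AffineTransform.translation(50, 50), 0.0)
        g_a, _ = optimize(build_graph(edges, 5))
        g_b, _ = optimize(build_graph(edges + [dead], 5))
        for a, b in zip(g_a.vertices, g_b.vertices):
            assert np.max(np.abs(a.matrix - b.matrix)) < 1e-12


class TestAverageFusion:
    def test_identical_sources_reproduce_the_transform(self):
        edges = consistent_chain(3, n_sources=3)
        states = average_fusion(edges, 3)
        assert states[1].almost_equal(T, tol=1e-12)
        assert states[2].almost_equal(T @ T, tol=1e-10)

    def test_mean_of_commuting_translations(self):
        edges = [
            est(0, 1, AffineTransform.translation(2.0, 0.0)  , 1.0, source="flow"),
            est(0, 1, AffineTransform.translation(4.0, 0.0), 1.0, source="direct"),
        ]
        states = average_fusion(edges, 2)
        assert np.allclose(states[1].translation_vector, [3.0, 0.0], atol=1e-12)

    def test_corrupted_source_pulls_one_third(self):
        edges = [
            est(0, 1, AffineTransform.translation(3.0, 0.0), 1.0, source="flow"),
            est(0, 1, AffineTransform.translation(3.0, 0.0), 1.0, source="feature"),
            est(0, 1, AffineTransform.translation(9.0, 0.0), 1.0, source="direct"),
        ]
        states = average_fusion(edges, 2)
        assert np.allclose(states[1].translation_vector, [5.0, 0.0], atol=1e-12)

    def test_all_failed_pair_gives_identity(self):
        edges = [est(0, 1, T, 0.0)]
        states = average_fusion(edges, 2)
        assert states[1].is_identity(tol=1e-15)


class TestChainSingleSource:
    def test_uses_only_named_source(self):
        edges = [
            est(0, 1, AffineTransform.translation(2, 0), 10.0, source="flow"),
            est(0, 1, AffineTransform.translation(9, 9), 10.0, source="direct"),
        ]
        states = chain_single_source(edges, 2, "flow")
        assert np.allclose(states[1].translation_vector, [2, 0])

    def test_failed_pair_contributes_identity(self):
        edges = [est(0, 1, T, 0.0, source="flow"), est(1, 2, T, 10.0, source="flow")]
        states = chain_single_source(edges, 3, "flow")
        assert states[1].is_identity(tol=1e-15)
        assert states[2].almost_equal(T, tol=1e-12)
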