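"""Uncertainty-weighted fusion of registrations as affine pose-graph
optimisation.

Vertices are per-frame absolute affine states (frame k -> anchor-frame
coordinates, anchor = first frame, held at identity).  Edges are the
pairwise registration estimates from all enabled sources — up to three
parallel edges per consecutive pair, plus loop-closure edges — each
weighted by its 6x6 information matrix.  The graph cost

    f = sum_edges  e(x_i, x_j, z_ij)^T  Omega_ij  e(x_i, x_j, z_ij)

with e the Lie-algebra edge residual is minimised by Levenberg-Marquardt
with numerically differentiated Jacobians, updating vertices by right
multiplication ``x <- x exp(xi^)``.

``average_fusion`` provides the naive baseline (per-pair arithmetic mean
of the sources' Lie-algebra vectors) used only for comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import GraphConfig
from .geometry import (
    AffineTransform,
    LogDomainError,
    affine_exp,
    affine_log,
    edge_error,
)
from .uncertainty import RegistrationEstimate

__all__ = [
    "PoseGraph",
    "OptimizerState",
    "build_graph",
    "total_cost",
    "numerical_jacobian",
    "optimize",
    "average_fusion",
    "chain_single_source",
]

logger = logging.getLogger(__name__)

_BASIS = np.eye(6)


@dataclass
class PoseGraph:
    vertices: list                    # per-frame AffineTransform states
    edges: list                       # RegistrationEstimate constraints
    anchor: int = 0


@dataclass
class OptimizerState:
    lam: float
    iteration: int
    cost: float
    converged: bool
    cost_history: list = field(default_factory=list)


def _best_consecutive(estimates, n_frames):
    """Per consecutive pair, the non-failed estimate with largest info trace."""
    best = [None] * (n_frames - 1)
    for est in estimates:
        if est.is_loop or est.frame_j != est.frame_i + 1:
            continue
        if est.failed:
            continue
        i = est.frame_i
        if best[i] is None or np.trace(est.info) > np.trace(best[i].info):
            best[i] = est
    return best


def build_graph(estimates: list, n_frames: int) -> PoseGraph:
    """Assemble the multi-edge graph and chain initial vertex states.

    Initialisation chains, per consecutive pair, the non-failed estimate
    with the largest information trace.  A pair where every source
    failed would disconnect the graph under the zero-information rule,
    so an identity bridge edge with tiny information is inserted (and a
    warning logged) to keep the system solvable without meaningfully
    biasing the connected parts.
    """
    if n_frames < 2:
        raise ValueError("a pose graph needs at least 2 frames")
    for est in estimates:
        if not (0 <= est.frame_i < n_frames and 0 <= est.frame_j < n_frames):
            raise ValueError(
                f"edge ({est.frame_i}, {est.frame_j}) outside 0..{n_frames - 1}"
            )
    edges = [est for est in estimates if not est.failed]
    best = _best_consecutive(estimates, n_frames)
    states = [AffineTransform.identity()]
    for i in range(n_frames - 1):
        if best[i] is None:
            logger.warning(
                "all sources failed for pair (%d, %d); inserting identity bridge",
                i,
                i + 1,
            )
            bridge = RegistrationEstimate(
                frame_i=i,
                frame_j=i + 1,
                source="direct",
                transform=AffineTransform.identity(),
                info=GraphConfig.bridge_information * np.eye(6),
            )
            edges.append(bridge)
            rel = AffineTransform.identity()
        else:
            rel = best[i].transform
        states.append(states[-1] @ rel)
    return PoseGraph(vertices=states, edges=edges)


def total_cost(graph: PoseGraph) -> float:
    """Quadratic graph cost; zero-information edges contribute zero."""
    cost = 0.0
    for est in graph.edges:
        if not est.info.any():
            continue
        e = edge_error(
            graph.vertices[est.frame_i],
            graph.vertices[est.frame_j],
            est.transform,
            context=f"edge ({est.frame_i}, {est.frame_j}) source {est.source}",
        )
        cost += float(e @ est.info @ e)
    return cost


def numerical_jacobian(
    est: RegistrationEstimate, graph: PoseGraph, step: float = 1e-6
) -> tuple:
    """Central-difference Jacobians of the edge residual.

    Returns ``(de/dxi_i, de/dxi_j)`` under right perturbation
    ``x <- x exp(step * basis_k)`` of each endpoint.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    x_i = graph.vertices[est.frame_i]
    x_j = graph.vertices[est.frame_j]
    J_i = np.zeros((6, 6))
    J_j = np.zeros((6, 6))
    for k in range(6):
        d = step * _BASIS[k]
        plus = edge_error(x_i @ affine_exp(d), x_j, est.transform)
        minus = edge_error(x_i @ affine_exp(-d), x_j, est.transform)
        J_i[:, k] = (plus - minus) / (2 * step)
        plus = edge_error(x_i, x_j @ affine_exp(d), est.transform)
        minus = edge_error(x_i, x_j @ affine_exp(-d), est.transform)
        J_j[:, k] = (plus - minus) / (2 * step)
    return J_i, J_j


def optimize(
    graph: PoseGraph,
    lambda0: float = 1e-4,
    tol: float = 1e-9,
    max_iters: int = 100,
    jacobian_step: float = 1e-6,
    cfg: GraphConfig | None = None,
) -> tuple:
    """Levenberg-Marquardt on the Lie algebra; anchor held at identity.

    Each iteration assembles the gradient ``b = sum J^T Omega e`` and
    Gauss-Newton Hessian ``K = sum J^T Omega J`` over active edges,
    solves the damped system ``(K + lambda I) xi = -b`` with the anchor
    block removed, and right-updates every free vertex.  Steps are
    accepted only when the cost decreases, so accepted iterations are
    monotone non-increasing.
    """
    if cfg is not None:
        lambda0, tol = cfg.lambda0, cfg.tol
        max_iters, jacobian_step = cfg.max_iters, cfg.jacobian_step
    active = [e for e in graph.edges if e.info.any()]
    if not active:
        raise ValueError("pose graph has no edge with non-zero information")
    n = len(graph.vertices)
    free = [v for v in range(n) if v != graph.anchor]
    col = {v: 6 * i for i, v in enumerate(free)}
    nu = 6 * len(free)

    vertices = list(graph.vertices)
    work = PoseGraph(vertices, active, graph.anchor)
    lam = lambda0
    cost = total_cost(work)
    history = [cost]
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        K = np.zeros((nu, nu))
        b = np.zeros(nu)
        for est in active:
            e = edge_error(
                vertices[est.frame_i], vertices[est.frame_j], est.transform
            )
            J_i, J_j = numerical_jacobian(est, work, jacobian_step)
            blocks = []
            if est.frame_i != graph.anchor:
                blocks.append((col[est.frame_i], J_i))
            if est.frame_j != graph.anchor:
                blocks.append((col[est.frame_j], J_j))
            for ca, Ja in blocks:
                b[ca : ca + 6] += Ja.T @ est.info @ e
                for cb, Jb in blocks:
                    K[ca : ca + 6, cb : cb + 6] += Ja.T @ est.info @ Jb
        accepted = False
        for _try in range(10):
            try:
                xi = np.linalg.solve(K + lam * np.eye(nu), -b)
            except np.linalg.LinAlgError:
                lam *= 10
                continue
            trial = list(vertices)
            for v in free:
                trial[v] = vertices[v] @ affine_exp(xi[col[v] : col[v] + 6])
            try:
                trial_cost = total_cost(PoseGraph(trial, active, graph.anchor))
            except LogDomainError:
                lam *= 10  # step left the log's domain: shrink and retry
                continue
            # gain ratio: actual vs model-predicted cost reduction.  A
            # step far outside the linearisation regime (rho small) is
            # rejected even if the cost dipped, otherwise a gross
            # outlier edge can drag the solve into a distorted basin.
            predicted = float(xi @ K @ xi + 2 * lam * xi @ xi)
            rho = (cost - trial_cost) / predicted if predicted > 0 else -1.0
            if trial_cost <= cost and rho >= 0.25:
                accepted = True
                break
            lam *= 10
        if not accepted:
            converged = True  # no descent direction left at any damping
            break
        vertices[:] = trial
        lam = max(lam / 10, 1e-15)
        rel_drop = (cost - trial_cost) / cost if cost > 0 else 0.0
        cost = trial_cost
        history.append(cost)
        if cost <= 1e-16 or rel_drop < tol:
            converged = True
            break
    state = OptimizerState(
        lam=lam, iteration=it, cost=cost, converged=converged, cost_history=history
    )
    return PoseGraph(vertices, graph.edges, graph.anchor), state


def average_fusion(estimates: list, n_frames: int) -> list:
    """Naive baseline: per-pair mean of the sources' Lie-algebra vectors.

    The mean of the non-failed consecutive estimates' logs is
    exponentiated and chained; an all-failed pair contributes identity.
    Loop edges are ignored (the baseline has no global optimisation).
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    per_pair = [[] for _ in range(n_frames - 1)]
    for est in estimates:
        if est.is_loop or est.frame_j != est.frame_i + 1 or est.failed:
            continue
        per_pair[est.frame_i].append(est.transform)
    states = [AffineTransform.identity()]
    for i in range(n_frames - 1):
        if not per_pair[i]:
            rel = AffineTransform.identity()
        else:
            xi = np.mean([affine_log(T) for T in per_pair[i]], axis=0)
            rel = affine_exp(xi)
        states.append(states[-1] @ rel)
    return states


def chain_single_source(estimates: list, n_frames: int, source: str) -> list:
    """Chained trajectory of one source alone; failed pairs give identity."""
    rels = [AffineTransform.identity()] * (n_frames - 1)
    for est in estimates:
        if est.source != source or est.is_loop or est.frame_j != est.frame_i + 1:
            continue
        if not est.failed:
            rels[est.frame_i] = est.transform
    states = [AffineTransform.identity()]
    for rel in rels:
        states.append(states[-1] @ rel)
    return states
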