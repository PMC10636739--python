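"""Information matrices for registration edges, and the failure rule.

Each pairwise registration carries a 6x6 diagonal information matrix
(inverse covariance) weighting its residual in the pose-graph cost.
For correspondence-based sources (features, flow) confidence grows with
the RANSAC inlier count ``n_inl``; for direct registration it shrinks
with the final photometric residual ``e_res``.  In both cases the
linear-block weight is fixed at 100x the translation weight.

A failed estimate (too few inliers, residual too large, RANSAC output
identity, or non-convergence) gets an all-zero information matrix: its
edge contributes nothing to the graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import UncertaintyConfig
from .geometry import AffineTransform

__all__ = [
    "Diagnostics",
    "RegistrationEstimate",
    "information_from_inliers",
    "information_from_residual",
    "classify_failure",
    "finalize_estimate",
]

logger = logging.getLogger(__name__)

SOURCES = ("feature", "flow", "direct")


@dataclass
class Diagnostics:
    n_inliers: int = 0
    n_correspondences: int = 0
    residual: float = float("nan")
    converged: bool = False


@dataclass
class RegistrationEstimate:
    """One pairwise registration: transform + information + provenance."""

    frame_i: int
    frame_j: int
    source: str                       # "feature" | "flow" | "direct"
    transform: AffineTransform
    info: np.ndarray                  # 6x6 diagonal information matrix
    diagnostics: Diagnostics = field(default_factory=Diagnostics)
    is_loop: bool = False

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        self.info = np.asarray(self.info, dtype=float)
        if self.info.shape != (6, 6):
            raise ValueError("information matrix must be 6x6")

    @property
    def failed(self) -> bool:
        return not self.info.any()


def information_from_inliers(n_inl: int) -> np.ndarray:
    """diag(100 n, 100 n, 100 n, 100 n, n, n); zero matrix for n = 0."""
    if n_inl < 0:
        raise ValueError("inlier count cannot be negative")
    n = float(n_inl)
    return np.diag([100 * n, 100 * n, 100 * n, 100 * n, n, n])


def information_from_residual(e_res: float) -> np.ndarray:
    """diag(100/e, 100/e, 100/e, 100/e, 1/e, 1/e).

    A non-positive residual cannot be inverted into a finite confidence
    (e = 0 would claim infinite certainty), so it is treated as a
    failure: zero matrix plus a logged warning.
    """
    if not np.isfinite(e_res) or e_res <= 0:
        logger.warning(
            "non-positive or non-finite photometric residual %r treated as failure",
            e_res,
        )
        return np.zeros((6, 6))
    return np.diag([100 / e_res] * 4 + [1 / e_res] * 2)


def classify_failure(
    est: RegistrationEstimate,
    min_inliers: int = 10,
    max_residual: float = 0.01,
    identity_tol: float = 1e-9,
) -> bool:
    """True when the estimate should be discarded (zero-information rule).

    Failure conditions: not enough inliers/correspondences, residual too
    large, RANSAC returned an (exact) identity, or the underlying solver
    reported non-convergence.
    """
    d = est.diagnostics
    if not d.converged:
        return True
    if est.source in ("feature", "flow"):
        if d.n_inliers < min_inliers:
            return True
        # an exactly-identity output from consecutive frames signals a
        # stalled estimator; a loop pair may legitimately be identity
        # (a perfect revisit), so the rule applies to odometry edges only
        if not est.is_loop and np.max(
            np.abs(est.transform.matrix - np.eye(3))
        ) < identity_tol:
            return True
        return False
    # direct source
    if not np.isfinite(d.residual) or d.residual > max_residual:
        return True
    return False


def finalize_estimate(
    est: RegistrationEstimate, cfg: UncertaintyConfig | None = None
) -> RegistrationEstimate:
    """Apply the failure rule in place: zero the information on failure."""
    cfg = cfg or UncertaintyConfig()
    if classify_failure(
        est,
        min_inliers=cfg.min_inliers,
        max_residual=cfg.max_residual,
        identity_tol=cfg.identity_tol,
    ):
        est.info = np.zeros((6, 6))
    return est
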