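"""Affine estimation from point correspondences: least squares + RANSAC.

Each correspondence pair contributes two linear constraints on the six
affine parameters; with the projective row of the homography fixed the
system is linear and solved directly.  RANSAC draws 4-point minimal
samples (one more than the affine minimum, so hypotheses are slightly
over-constrained), scores them by reprojection distance against a pixel
threshold ``eps``, and polishes the best consensus set with a full
least-squares refit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correspondence_sources import Correspondences
from .geometry import AffineTransform

__all__ = [
    "RansacResult",
    "fit_affine_lstsq",
    "reprojection_distances",
    "ransac_affine",
]


@dataclass
class RansacResult:
    transform: AffineTransform
    inlier_mask: np.ndarray  # boolean, aligned with the input pairs
    n_inliers: int
    converged: bool

    def __post_init__(self):
        self.inlier_mask = np.asarray(self.inlier_mask, dtype=bool)
        assert self.n_inliers == int(self.inlier_mask.sum())


def _collinear(pts: np.ndarray, tol: float = 1e-6) -> bool:
    """True when all points lie (nearly) on one line: degenerate sample."""
    if len(pts) < 3:
        return True
    p0 = pts[0]
    d = pts[1:] - p0
    # max doubled-triangle area over point pairs
    areas = np.abs(d[:, None, 0] * d[None, :, 1] - d[:, None, 1] * d[None, :, 0])
    return float(areas.max()) < tol


def fit_affine_lstsq(corr: Correspondences) -> AffineTransform | None:
    """Least-squares affine fit minimising ``sum ||dst - T(src)||^2``.

    Returns None (an estimation-failure signal, never an exception) for
    fewer than 3 pairs or collinear source points.
    """
    n = len(corr)
    if n < 3 or _collinear(corr.src_pts):
        return None
    # stacked 2n x 6 design: rows [u', v', 1, 0, 0, 0] -> u and
    # [0, 0, 0, u', v', 1] -> v
    A = np.zeros((2 * n, 6))
    A[0::2, 0] = corr.src_pts[:, 0]
    A[0::2, 1] = corr.src_pts[:, 1]
    A[0::2, 2] = 1.0
    A[1::2, 3] = corr.src_pts[:, 0]
    A[1::2, 4] = corr.src_pts[:, 1]
    A[1::2, 5] = 1.0
    rhs = corr.dst_pts.ravel()
    sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    h11, h12, h13, h21, h22, h23 = sol
    # a frame-to-frame camera map is orientation-preserving; a
    # reflection (det <= 0) can only come from degenerate matches
    if h11 * h22 - h12 * h21 <= 1e-12:
        return None
    try:
        return AffineTransform.from_params(h11, h12, h21, h22, h13, h23)
    except ValueError:  # singular linear block
        return None


def reprojection_distances(T: AffineTransform, corr: Correspondences) -> np.ndarray:
    """Per-pair Euclidean distance ``||dst - T(src)||`` in pixels."""
    if len(corr) == 0:
        return np.empty(0)
    return np.linalg.norm(corr.dst_pts - T.apply(corr.src_pts), axis=1)


def ransac_affine(
    corr: Correspondences,
    eps: float = 2.0,
    max_iters: int = 1000,
    min_inliers: int = 10,
    seed: int = 0,
    sample_size: int = 4,
) -> RansacResult:
    """Robust affine estimation; deterministic given ``seed``.

    Returns ``converged=False`` with an identity transform when there
    are fewer pairs than the minimal sample or the best consensus set is
    smaller than ``min_inliers`` (identity output doubles as the failure
    signal consumed by the uncertainty rules).
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    n = len(corr)
    failure = RansacResult(
        AffineTransform.identity(), np.zeros(n, dtype=bool), 0, False
    )
    if n < sample_size:
        return failure
    rng = np.random.default_rng(seed)
    best_mask = np.zeros(n, dtype=bool)
    best_count = 0
    for _ in range(max_iters):
        idx = rng.choice(n, size=sample_size, replace=False)
        sample = Correspondences(corr.src_pts[idx], corr.dst_pts[idx])
        if _collinear(sample.src_pts):
            continue
        T = fit_affine_lstsq(sample)
        if T is None:
            continue
        mask = reprojection_distances(T, corr) < eps
        count = int(mask.sum())
        if count > best_count:
            best_count, best_mask = count, mask
    if best_count < max(min_inliers, 3):
        return failure
    consensus = Correspondences(corr.src_pts[best_mask], corr.dst_pts[best_mask])
    T = fit_affine_lstsq(consensus)
    if T is None:
        return failure
    # re-score after the polish so mask and transform agree
    mask = reprojection_distances(T, corr) < eps
    count = int(mask.sum())
    if count < min_inliers:
        return failure
    return RansacResult(T, mask, count, True)
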