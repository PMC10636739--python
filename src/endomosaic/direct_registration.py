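"""Direct photometric registration by pyramidal Levenberg-Marquardt.

Estimates the affine transform between two frames by minimising the
mean squared intensity difference between the fixed image and the
warped moving image (intensity-constancy assumption), coarse-to-fine
over a Gaussian pyramid.  The residual it returns is the per-valid-pixel
mean of squared differences, so it is resolution-independent and feeds
directly into the information-matrix rules.

The returned transform maps moving-image (frame j) pixel coordinates
into fixed-image (frame i) coordinates, matching the pose-graph edge
convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.transform import pyramid_gaussian

from .config import DirectConfig
from .correspondence_sources import to_gray
from .geometry import AffineTransform

__all__ = ["DirectRegResult", "photometric_loss", "register_direct"]


@dataclass
class DirectRegResult:
    transform: AffineTransform
    residual: float       # final mean squared intensity difference per valid pixel
    n_valid: int          # overlapping pixel count at full resolution
    converged: bool
    loss_history: list = None  # per pyramid level, the accepted-loss sequence


def _warp_valid(img_j: np.ndarray, M: np.ndarray, shape: tuple):
    """Sample img_j at M-mapped coordinates of a `shape` grid.

    M maps fixed-image pixel coordinates (u, v) into img_j coordinates.
    Returns (warped, valid mask, sample coordinates (n, 2)).
    """
    h, w = shape
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    pts = np.column_stack([uu.ravel(), vv.ravel()])
    mapped = pts @ M[:2, :2].T + M[:2, 2]
    hj, wj = img_j.shape
    valid = (
        (mapped[:, 0] >= 0)
        & (mapped[:, 0] <= wj - 1)
        & (mapped[:, 1] >= 0)
        & (mapped[:, 1] <= hj - 1)
    )
    warped = map_coordinates(
        img_j, [mapped[:, 1], mapped[:, 0]], order=1, mode="constant", cval=0.0
    )
    return warped.reshape(h, w), valid.reshape(h, w), mapped


def photometric_loss(
    img_i: np.ndarray, img_j: np.ndarray, T: AffineTransform
) -> tuple:
    """Mean squared intensity difference between img_i and warped img_j.

    ``T`` maps img_j coordinates into img_i coordinates; img_j is warped
    into img_i's frame by inverse mapping and pixels sampling outside
    img_j are masked out.  Returns ``(loss, n_valid)``; ``(None, 0)``
    when no pixel overlaps (loss undefined — a failure signal).
    """
    a, b = to_gray(img_i), to_gray(img_j)
    M = np.linalg.inv(T.matrix)  # fixed -> moving coordinates
    warped, valid, _ = _warp_valid(b, M, a.shape)
    n_valid = int(valid.sum())
    if n_valid == 0:
        return None, 0
    diff = (a - warped)[valid]
    return float(np.mean(diff**2)), n_valid


def _level_loss(a, b, M):
    warped, valid, _ = _warp_valid(b, M, a.shape)
    n = int(valid.sum())
    if n == 0:
        return None, None, None
    r = (a - warped)[valid]
    return float(np.mean(r**2)), r, valid


def register_direct(
    img_i: np.ndarray,
    img_j: np.ndarray,
    init: AffineTransform | None = None,
    pyramid_levels: int = 3,
    tol: float = 1e-6,
    max_iters: int = 50,
    min_valid_fraction: float = 0.25,
    params: DirectConfig | None = None,
) -> DirectRegResult:
    """Coarse-to-fine L-M minimisation of the photometric loss.

    The six affine parameters of the *inverse* warp (fixed -> moving)
    are updated additively with Levenberg-Marquardt damping; a step is
    accepted only if it lowers the loss, so the per-level loss sequence
    is monotone non-increasing.  On a textured scene this recovers
    sub-pixel motion; on featureless input the image gradient vanishes
    and the result stays at ``init`` with a flat loss (low-information,
    classified downstream by its diagnostics).
    """
    if params is not None:
        pyramid_levels = params.pyramid_levels
        tol = params.tol
        max_iters = params.max_iters
        min_valid_fraction = params.min_valid_fraction
    a_full, b_full = to_gray(img_i), to_gray(img_j)
    if a_full.shape != b_full.shape:
        raise ValueError("images must have identical shape")
    init = init or AffineTransform.identity()

    max_levels = max(1, min(pyramid_levels, int(np.log2(min(a_full.shape) / 16)) + 1))
    pyr_a = list(pyramid_gaussian(a_full, max_layer=max_levels - 1, downscale=2))
    pyr_b = list(pyramid_gaussian(b_full, max_layer=max_levels - 1, downscale=2))

    M = np.linalg.inv(init.matrix)  # optimise the fixed->moving map
    diverged = False
    loss_history = []
    for level in range(max_levels - 1, -1, -1):
        a, b = pyr_a[level], pyr_b[level]
        s = a_full.shape[0] / a.shape[0]
        S = np.diag([1.0 / s, 1.0 / s, 1.0])
        S_inv = np.diag([s, s, 1.0])
        Ml = S @ M @ S_inv  # same map expressed in level coordinates
        gy, gx = np.gradient(b)
        lam = 1e-3
        loss, _, _ = _level_loss(a, b, Ml)
        if loss is None:
            diverged = True
            break
        level_losses = [loss]
        loss_history.append(level_losses)
        for _ in range(max_iters):
            warped, valid, mapped = _warp_valid(b, Ml, a.shape)
            vmask = valid.ravel()
            if not vmask.any():
                break
            uu, vv = np.meshgrid(
                np.arange(a.shape[1], dtype=float), np.arange(a.shape[0], dtype=float)
            )
            u = uu.ravel()[vmask]
            v = vv.ravel()[vmask]
            mp = mapped[vmask]
            gxw = map_coordinates(gx, [mp[:, 1], mp[:, 0]], order=1)
            gyw = map_coordinates(gy, [mp[:, 1], mp[:, 0]], order=1)
            r = (a.ravel()[vmask] - warped.ravel()[vmask])
            # residual r = a - b(M p); d r / d theta = -grad_b . d(Mp)/d theta
            # theta order: (m11, m12, tx, m21, m22, ty)
            J = -np.column_stack(
                [gxw * u, gxw * v, gxw, gyw * u, gyw * v, gyw]
            )
            JtJ = J.T @ J
            Jtr = J.T @ r
            accepted = False
            for _try in range(8):
                try:
                    delta = np.linalg.solve(JtJ + lam * np.eye(6), -Jtr)
                except np.linalg.LinAlgError:
                    lam *= 10
                    continue
                M_new = Ml.copy()
                M_new[0, 0] += delta[0]
                M_new[0, 1] += delta[1]
                M_new[0, 2] += delta[2]
                M_new[1, 0] += delta[3]
                M_new[1, 1] += delta[4]
                M_new[1, 2] += delta[5]
                new_loss, _, _ = _level_loss(a, b, M_new)
                if new_loss is not None and new_loss <= loss:
                    accepted = True
                    break
                lam *= 10
            if not accepted:
                break  # flat or diverging: keep the best iterate
            lam = max(lam / 10, 1e-12)
            Ml = M_new
            level_losses.append(new_loss)
            if loss > 0 and (loss - new_loss) / loss < tol:
                loss = new_loss
                break
            loss = new_loss
        M = S_inv @ Ml @ S
    try:
        transform = AffineTransform(np.linalg.inv(_fix_last_row(M)))
    except (ValueError, np.linalg.LinAlgError):
        transform = init
        diverged = True
    residual, n_valid = photometric_loss(a_full, b_full, transform)
    if residual is None:
        return DirectRegResult(init, float("inf"), 0, False, loss_history)
    converged = (not diverged) and n_valid >= min_valid_fraction * a_full.size
    return DirectRegResult(transform, residual, n_valid, converged, loss_history)


def _fix_last_row(M: np.ndarray) -> np.ndarray:
    M = M.copy()
    M[2] = (0.0, 0.0, 1.0)
    return M
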