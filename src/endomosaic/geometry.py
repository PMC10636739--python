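"""Affine(2) Lie-group machinery.

A planar affine transform is stored as a 3x3 matrix with fixed last row
``(0, 0, 1)``.  The group acts on homogeneous pixel coordinates
``(u, v, 1)`` where ``u`` is the column and ``v`` the row, 0-based, origin
at the top-left corner — this convention is used everywhere in the
package.

The Lie algebra aff(2) is parameterised by 6-vectors with the coordinate
order ``(B11, B12, B21, B22, t1, t2)``: the first four coordinates span
the linear 2x2 block, the last two the translation.  This ordering
matches the information-matrix convention used by :mod:`.uncertainty`
(first four diagonal entries weight the linear block, last two the
translation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

__all__ = [
    "AffineTransform",
    "affine_exp",
    "affine_log",
    "edge_error",
    "hat",
    "vee",
]

_LAST_ROW = np.array([0.0, 0.0, 1.0])


class LogDomainError(ValueError):
    """The principal matrix logarithm does not exist for this transform."""


@dataclass(frozen=True)
class AffineTransform:
    """A 2-D affine map as a 3x3 homogeneous matrix.

    Invariants: the bottom row is exactly ``(0, 0, 1)`` and the
    upper-left 2x2 block is non-singular.
    """

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"affine matrix must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("affine matrix contains non-finite entries")
        if not np.array_equal(m[2], _LAST_ROW):
            if np.allclose(m[2], _LAST_ROW, atol=1e-12):
                m = m.copy()
                m[2] = _LAST_ROW
            else:
                raise ValueError(f"last row must be (0, 0, 1), got {m[2]}")
        det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
        if abs(det) <= 1e-12:
            raise ValueError("linear block is singular")
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)

    # -- constructors ---------------------------------------------------
    @staticmethod
    def identity() -> "AffineTransform":
        return AffineTransform(np.eye(3))

    @staticmethod
    def from_params(a11, a12, a21, a22, tx, ty) -> "AffineTransform":
        return AffineTransform(
            np.array([[a11, a12, tx], [a21, a22, ty], [0.0, 0.0, 1.0]])
        )

    @staticmethod
    def translation(tx: float, ty: float) -> "AffineTransform":
        return AffineTransform.from_params(1.0, 0.0, 0.0, 1.0, tx, ty)

    # -- group operations -----------------------------------------------
    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Return ``self @ other`` (apply *other* first)."""
        return AffineTransform(self.matrix @ other.matrix)

    def __matmul__(self, other: "AffineTransform") -> "AffineTransform":
        return self.compose(other)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    # -- action on points -----------------------------------------------
    def apply(self, pts: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of (u, v) points."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.matrix[:2, :2].T + self.matrix[:2, 2]

    # -- properties ------------------------------------------------------
    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:2, :2]

    @property
    def translation_vector(self) -> np.ndarray:
        return self.matrix[:2, 2]

    def is_identity(self, tol: float = 1e-9) -> bool:
        return bool(np.max(np.abs(self.matrix - np.eye(3))) < tol)

    def almost_equal(self, other: "AffineTransform", tol: float = 1e-9) -> bool:
        return bool(np.max(np.abs(self.matrix - other.matrix)) < tol)

    def to_list(self) -> list:
        """Row-major 9-element list (JSON serialisation form)."""
        return [float(x) for x in self.matrix.ravel()]

    @staticmethod
    def from_list(values) -> "AffineTransform":
        return AffineTransform(np.asarray(values, dtype=float).reshape(3, 3))


def hat(xi: np.ndarray) -> np.ndarray:
    """Map a 6-vector to its aff(2) matrix ``[[B, t], [0, 0]]``."""
    xi = np.asarray(xi, dtype=float)
    if xi.shape != (6,):
        raise ValueError(f"tangent vector must have shape (6,), got {xi.shape}")
    return np.array(
        [
            [xi[0], xi[1], xi[4]],
            [xi[2], xi[3], xi[5]],
            [0.0, 0.0, 0.0],
        ]
    )


def vee(m: np.ndarray) -> np.ndarray:
    """Inverse of :func:`hat`."""
    return np.array([m[0, 0], m[0, 1], m[1, 0], m[1, 1], m[0, 2], m[1, 2]])


def affine_exp(xi: np.ndarray) -> AffineTransform:
    """Exponential map aff(2) -> Aff(2) via the dense matrix exponential."""
    xi = np.asarray(xi, dtype=float)
    if not np.all(np.isfinite(xi)):
        raise ValueError("tangent vector contains non-finite entries")
    return AffineTransform(expm(hat(xi)))


def _log_linear_2x2(A: np.ndarray, context: str) -> np.ndarray:
    """Principal log of a real 2x2 matrix, closed form.

    Writes ``A = m I + N`` with ``m = tr(A)/2`` and uses the
    Cayley-Hamilton identity ``N^2 = d^2 I`` (``d^2 = m^2 - det A``),
    so any analytic f satisfies ``f(A) = c0 I + c1 N`` with
    ``c0 = (f(l1) + f(l2))/2`` and ``c1 = (f(l1) - f(l2)) / (l1 - l2)``
    for the eigenvalues ``l = m +- d``.  For the log, ``c0`` reduces to
    ``log(det A)/2`` and ``c1`` to ``artanh(d/m)/d``, which is stable as
    the eigenvalues coalesce.
    """
    m = 0.5 * (A[0, 0] + A[1, 1])
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    d = np.sqrt(complex(m * m - det))
    l1, l2 = m + d, m - d
    for lam in (l1, l2):
        if lam.real <= 0 and abs(lam.imag) < 1e-12:
            where = f" ({context})" if context else ""
            raise LogDomainError(
                "principal logarithm undefined: linear block has an eigenvalue "
                f"on the closed negative real axis{where}"
            )
    c0 = 0.5 * np.log(det)  # = (log l1 + log l2)/2, real since det > 0 here
    # m is real (A is real); the artanh form of the divided difference is
    # branch-safe only in the right half-plane (m > 0)
    if m > 0 and abs(d) < 1e-14 * max(1.0, m):
        c1 = 1.0 / m
    elif m > 0 and abs(d) < 0.5 * m:
        c1 = np.arctanh(d / m) / d  # stable as the eigenvalues coalesce
    else:
        c1 = (np.log(l1) - np.log(l2)) / (2 * d)
    N = A - m * np.eye(2)
    B = c0 * np.eye(2) + c1 * N
    if np.iscomplexobj(B):
        if np.max(np.abs(B.imag)) > 1e-9:
            where = f" ({context})" if context else ""
            raise LogDomainError(f"matrix logarithm is not real{where}")
        B = B.real
    return B


def affine_log(T: AffineTransform, context: str = "") -> np.ndarray:
    """Logarithm map Aff(2) -> aff(2) as a 6-vector.

    The linear block is the closed-form principal log of the 2x2 block;
    the translation coordinates solve ``phi1(B) u = t`` where
    ``phi1(B) = (exp(B) - I) B^{-1}`` (limit-continuous at singular B)
    is obtained from a 4x4 block exponential.  Requires the principal
    logarithm to exist: no eigenvalue of the linear block on the closed
    negative real axis.
    """
    B = _log_linear_2x2(T.linear, context)
    # phi1 from exp([[B, I], [0, 0]]) = [[e^B, phi1(B)], [0, I]]
    block = np.zeros((4, 4))
    block[:2, :2] = B
    block[:2, 2:] = np.eye(2)
    V = expm(block)[:2, 2:]
    u = np.linalg.solve(V, T.translation_vector)
    return np.array([B[0, 0], B[0, 1], B[1, 0], B[1, 1], u[0], u[1]])


def edge_error(
    x_i: AffineTransform, x_j: AffineTransform, z_ij: AffineTransform,
    context: str = "",
) -> np.ndarray:
    """Pose-graph edge residual ``log(z_ij^-1 x_i^-1 x_j)`` as a 6-vector.

    ``x_i`` and ``x_j`` are absolute vertex states (frame -> anchor
    coordinates); ``z_ij`` is the measured relative transform mapping
    frame-j coordinates into frame-i coordinates.  Zero iff the edge is
    perfectly consistent, i.e. ``x_j == x_i @ z_ij``.
    """
    m = np.linalg.inv(z_ij.matrix) @ np.linalg.inv(x_i.matrix) @ x_j.matrix
    return affine_log(AffineTransform(m), context=context)
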