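"""Pairwise point correspondences from sparse features or dense flow.

Both sources feed the same downstream RANSAC affine estimator: SIFT
keypoint matching gives sparse pairs, a dense optical-flow field is
subsampled into pairs via the flow-to-correspondence map
``(u, v) = (u', v') + (ox, oy)``.

Coordinates are (u, v) = (column, row), 0-based.  A ``Correspondences``
object pairs ``src_pts`` in image A with ``dst_pts`` in image B, so an
affine fit maps A-coordinates into B-coordinates.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.feature import SIFT, match_descriptors
from skimage.registration import optical_flow_ilk, optical_flow_tvl1

from .config import FeatureConfig, FlowConfig

__all__ = [
    "Correspondences",
    "FlowField",
    "to_gray",
    "detect_keypoints",
    "match_keypoints",
    "detect_and_match_features",
    "compute_dense_flow",
    "flow_to_correspondences",
    "read_flo",
    "write_flo",
]

FLO_MAGIC = 202021.25  # sanity-check sentinel of the .flo raster layout


@dataclass
class Correspondences:
    """Paired pixel coordinates; ``dst ~ T(src)`` for the fitted T."""

    src_pts: np.ndarray  # (n, 2) float (u, v) in the source image
    dst_pts: np.ndarray  # (n, 2) float (u, v) in the target image

    def __post_init__(self):
        self.src_pts = np.asarray(self.src_pts, dtype=float).reshape(-1, 2)
        self.dst_pts = np.asarray(self.dst_pts, dtype=float).reshape(-1, 2)
        if len(self.src_pts) != len(self.dst_pts):
            raise ValueError("src_pts and dst_pts must have equal length")

    def __len__(self) -> int:
        return len(self.src_pts)

    @staticmethod
    def empty() -> "Correspondences":
        return Correspondences(np.empty((0, 2)), np.empty((0, 2)))


@dataclass
class FlowField:
    """Dense per-pixel displacement ``(ox, oy)``, same size as the images."""

    flow: np.ndarray  # (h, w, 2) float, last axis (ox, oy)

    def __post_init__(self):
        self.flow = np.asarray(self.flow, dtype=float)
        if self.flow.ndim != 3 or self.flow.shape[2] != 2:
            raise ValueError("flow must have shape (h, w, 2)")

    @property
    def shape(self) -> tuple:
        return self.flow.shape[:2]


def to_gray(img: np.ndarray) -> np.ndarray:
    """Luminance conversion + [0, 1] scaling, shared by all sources."""
    img = np.asarray(img, dtype=float)
    if img.ndim == 3:
        img = img[..., 0] * 0.2125 + img[..., 1] * 0.7154 + img[..., 2] * 0.0721
    if img.max() > 1.5:  # 8-bit input
        img = img / 255.0
    return img


def detect_keypoints(
    img: np.ndarray, params: FeatureConfig | None = None
) -> tuple:
    """SIFT keypoints (as (u, v)) and descriptors of one image.

    Returns empty arrays on featureless input instead of raising.
    """
    params = params or FeatureConfig()
    det = SIFT(c_dog=params.c_dog, c_edge=params.c_edge)
    try:
        det.detect_and_extract(to_gray(img))
    except RuntimeError:  # skimage raises when no keypoint survives
        return np.empty((0, 2)), np.empty((0, 128))
    # skimage keypoints are (row, col); flip to (u, v)
    return det.keypoints[:, ::-1].astype(float), det.descriptors.astype(float)


def match_keypoints(
    kp_a: np.ndarray,
    desc_a: np.ndarray,
    kp_b: np.ndarray,
    desc_b: np.ndarray,
    params: FeatureConfig | None = None,
) -> Correspondences:
    """Descriptor matching with Lowe ratio test and mutual-nearest filter."""
    params = params or FeatureConfig()
    if len(kp_a) == 0 or len(kp_b) == 0:
        return Correspondences.empty()
    matches = match_descriptors(
        desc_a,
        desc_b,
        cross_check=params.cross_check,
        max_ratio=params.max_ratio,
    )
    if len(matches) == 0:
        return Correspondences.empty()
    return Correspondences(kp_a[matches[:, 0]], kp_b[matches[:, 1]])


def detect_and_match_features(
    img_a: np.ndarray, img_b: np.ndarray, params: FeatureConfig | None = None
) -> Correspondences:
    """SIFT detection + descriptor matching with ratio and mutual tests.

    Returns matched (src in A, dst in B) pairs; empty on featureless
    input — never raises, downstream treats empty as a failure signal.
    """
    a, b = to_gray(img_a), to_gray(img_b)
    if a.shape != b.shape:
        raise ValueError("images must have identical shape")
    kp_a, desc_a = detect_keypoints(a, params)
    kp_b, desc_b = detect_keypoints(b, params)
    return match_keypoints(kp_a, desc_a, kp_b, desc_b, params)


def compute_dense_flow(
    img_a: np.ndarray,
    img_b: np.ndarray,
    params: FlowConfig | None = None,
    pair_key: str | None = None,
) -> FlowField:
    """Dense flow on image A's grid such that ``B(p + o(p)) ~ A(p)``.

    Backends: ``ilk`` (iterative Lucas-Kanade, default), ``tvl1``
    (variational), and ``precomputed`` — an adapter reading a stored
    two-plane ``.flo`` raster named after ``pair_key``, for plugging in
    an external (e.g. learned) flow producer without this package ever
    needing its weights.
    """
    params = params or FlowConfig()
    a, b = to_gray(img_a), to_gray(img_b)
    if a.shape != b.shape:
        raise ValueError("images must have identical shape")
    if params.backend == "ilk":
        v, u = optical_flow_ilk(a, b, radius=params.radius)
    elif params.backend == "tvl1":
        v, u = optical_flow_tvl1(a, b)
    elif params.backend == "precomputed":
        if pair_key is None:
            raise ValueError("precomputed flow backend needs a pair_key")
        path = Path(params.precomputed_dir) / f"{pair_key}.flo"
        field = read_flo(path)
        if field.shape != a.shape:
            raise ValueError(
                f"precomputed flow {path} has shape {field.shape}, images {a.shape}"
            )
        return field
    else:
        raise ValueError(f"unknown flow backend {params.backend!r}")
    return FlowField(np.stack([u, v], axis=-1))


def flow_to_correspondences(
    flow: FlowField, stride: int = 8, border_margin: int = 4
) -> Correspondences:
    """Subsample a flow field into point pairs ``(p, p + o(p))``.

    Grid locations within ``border_margin`` of any edge are excluded
    (flow is unreliable at the border), as are pairs whose destination
    falls outside the image.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    h, w = flow.shape
    us = np.arange(border_margin, w - border_margin, stride)
    vs = np.arange(border_margin, h - border_margin, stride)
    if len(us) == 0 or len(vs) == 0:
        return Correspondences.empty()
    uu, vv = np.meshgrid(us, vs)
    src = np.column_stack([uu.ravel(), vv.ravel()]).astype(float)
    o = flow.flow[src[:, 1].astype(int), src[:, 0].astype(int)]
    dst = src + o
    inside = (
        (dst[:, 0] >= 0) & (dst[:, 0] <= w - 1) & (dst[:, 1] >= 0) & (dst[:, 1] <= h - 1)
    )
    return Correspondences(src[inside], dst[inside])


def read_flo(path: str | Path) -> FlowField:
    """Read a two-plane float32 flow raster (the de-facto .flo layout)."""
    with open(path, "rb") as fh:
        magic = struct.unpack("<f", fh.read(4))[0]
        if abs(magic - FLO_MAGIC) > 1e-3:
            raise ValueError(f"{path}: bad magic {magic}, expected {FLO_MAGIC}")
        w, h = struct.unpack("<ii", fh.read(8))
        data = np.frombuffer(fh.read(w * h * 2 * 4), dtype="<f4")
    return FlowField(data.reshape(h, w, 2).astype(float))


def write_flo(path: str | Path, flow: FlowField) -> None:
    h, w = flow.shape
    with open(path, "wb") as fh:
        fh.write(struct.pack("<f", FLO_MAGIC))
        fh.write(struct.pack("<ii", w, h))
        fh.write(flow.flow.astype("<f4").tobytes())
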