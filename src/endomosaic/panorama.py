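"""Panorama assembly: re-anchoring, canvas sizing, first-write-wins blend.

The optimised vertex states are expressed relative to the first frame;
for display the sequence is re-anchored so the *middle* frame is the
identity (1-based index n/2 for even n, (n+1)/2 for odd), which keeps
the least-distorted frame at the centre of the mosaic.  The canvas is
the bounding box of all warped image corners; images are warped into it
in sequence order by inverse mapping, and each later image writes only
canvas pixels that are still blank ("first write wins") — blankness is
tracked with a boolean mask, never by pixel value, so genuinely black
content is handled correctly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import AffineTransform

__all__ = [
    "Panorama",
    "middle_index",
    "anchor_to_middle",
    "compute_canvas",
    "blend",
]


@dataclass
class Panorama:
    canvas: np.ndarray        # (H, W) or (H, W, C) float raster
    offset: np.ndarray        # 2-vector: canvas coords = anchor coords + offset
    filled_mask: np.ndarray   # (H, W) bool, True where some image wrote


def middle_index(n: int) -> int:
    """0-based middle-frame index: 1-based n/2 (even n) or (n+1)/2 (odd)."""
    if n < 1:
        raise ValueError("need at least one frame")
    return (n // 2) - 1 if n % 2 == 0 else n // 2


def anchor_to_middle(states: list) -> list:
    """Re-express first-frame-relative states relative to the middle frame.

    Returns ``M_k = X_mid^-1 @ X_k``; the middle entry becomes identity.
    """
    if not states:
        raise ValueError("empty state list")
    mid = middle_index(len(states))
    inv_mid = states[mid].inverse()
    return [inv_mid @ x for x in states]


def _corners(width: int, height: int) -> np.ndarray:
    return np.array(
        [
            [0.0, 0.0],
            [width - 1.0, 0.0],
            [0.0, height - 1.0],
            [width - 1.0, height - 1.0],
        ]
    )


def compute_canvas(transforms: list, width: int, height: int) -> tuple:
    """Canvas size and offset covering every warped image corner.

    Maps the four corners of a ``width`` x ``height`` image through each
    transform, takes the bounding box (floor of the minima, ceil of the
    maxima) and returns ``(canvas_w, canvas_h, offset)`` with
    ``offset = -(min corner)`` so all warped pixels land in-bounds.
    """
    if not transforms:
        raise ValueError("need at least one transform")
    pts = np.concatenate([t.apply(_corners(width, height)) for t in transforms])
    lo = np.floor(pts.min(axis=0)).astype(int)
    hi = np.ceil(pts.max(axis=0)).astype(int)
    canvas_w = int(hi[0] - lo[0] + 1)
    canvas_h = int(hi[1] - lo[1] + 1)
    return canvas_w, canvas_h, -lo.astype(float)


def blend(
    images: list, transforms: list, interpolation: str = "bilinear"
) -> Panorama:
    """Warp images into the canvas in order; first write wins per pixel.

    ``transforms`` must already be middle-anchored; each maps its
    image's pixel coordinates into the common (middle-frame) plane.
    Warping is done by inverse mapping with bilinear (default) or
    nearest-neighbour sampling.
    """
    if len(images) != len(transforms):
        raise ValueError("images and transforms must align")
    order = {"bilinear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    h, w = np.asarray(images[0]).shape[:2]
    canvas_w, canvas_h, offset = compute_canvas(transforms, w, h)
    color = np.asarray(images[0]).ndim == 3
    shape = (canvas_h, canvas_w, np.asarray(images[0]).shape[2]) if color else (canvas_h, canvas_w)
    canvas = np.zeros(shape)
    filled = np.zeros((canvas_h, canvas_w), dtype=bool)

    for img, T in zip(images, transforms):
        img = np.asarray(img, dtype=float)
        # restrict work to the warped footprint's bounding box
        pts = T.apply(_corners(w, h)) + offset
        u0 = max(int(np.floor(pts[:, 0].min())), 0)
        v0 = max(int(np.floor(pts[:, 1].min())), 0)
        u1 = min(int(np.ceil(pts[:, 0].max())), canvas_w - 1)
        v1 = min(int(np.ceil(pts[:, 1].max())), canvas_h - 1)
        if u1 < u0 or v1 < v0:
            continue
        uu, vv = np.meshgrid(
            np.arange(u0, u1 + 1, dtype=float), np.arange(v0, v1 + 1, dtype=float)
        )
        inv = T.inverse()
        src = (
            np.column_stack([uu.ravel(), vv.ravel()]) - offset
        ) @ inv.matrix[:2, :2].T + inv.matrix[:2, 2]
        valid = (
            (src[:, 0] >= 0)
            & (src[:, 0] <= w - 1)
            & (src[:, 1] >= 0)
            & (src[:, 1] <= h - 1)
        ).reshape(uu.shape)
        sub_filled = filled[v0 : v1 + 1, u0 : u1 + 1]
        write = valid & ~sub_filled
        if not write.any():
            continue
        coords = [src[:, 1].reshape(uu.shape)[write], src[:, 0].reshape(uu.shape)[write]]
        if color:
            for c in range(img.shape[2]):
                vals = map_coordinates(img[..., c], coords, order=order, mode="nearest")
                canvas[v0 : v1 + 1, u0 : u1 + 1, c][write] = vals
        else:
            vals = map_coordinates(img, coords, order=order, mode="nearest")
            canvas[v0 : v1 + 1, u0 : u1 + 1][write] = vals
        sub_filled |= write
    return Panorama(canvas=canvas, offset=offset, filled_mask=filled)
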