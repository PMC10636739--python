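"""Mosaic-consistency metric: SSIM between overlapping registered frames.

For every frame pair at temporal distance d = 1..d_max, the later frame
is warped into the earlier frame's coordinates via the relative
transform implied by the estimated states, and the structural similarity
index is computed over the valid overlap.  A registration that drifts
mis-aligns the pair and lowers SSIM, so the per-distance averages
quantify mosaic quality without ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion, map_coordinates
from skimage.metrics import structural_similarity

from .correspondence_sources import to_gray
from .geometry import AffineTransform

__all__ = ["SsimReport", "pairwise_ssim", "summarize"]

_WIN = 7  # Gaussian SSIM window size


@dataclass
class SsimReport:
    """Per-temporal-distance SSIM distributions and their means."""

    per_distance: dict = field(default_factory=dict)  # d -> list of SSIM values
    skipped: dict = field(default_factory=dict)       # d -> pairs with no overlap

    def mean(self, d: int | None = None) -> float:
        """Mean SSIM at distance d, or pooled over all distances."""
        values = (
            self.per_distance.get(d, [])
            if d is not None
            else [v for vals in self.per_distance.values() for v in vals]
        )
        return float(np.mean(values)) if values else float("nan")

    @property
    def means(self) -> dict:
        out = {d: self.mean(d) for d in sorted(self.per_distance)}
        out["overall"] = self.mean()
        return out


def _pair_ssim(
    img_i: np.ndarray, img_j: np.ndarray, rel: AffineTransform, min_overlap_frac: float
) -> float | None:
    """SSIM of img_j warped into img_i's frame, over the overlap mask."""
    a, b = to_gray(img_i), to_gray(img_j)
    h, w = a.shape
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    inv = rel.inverse()
    src = np.column_stack([uu.ravel(), vv.ravel()]) @ inv.matrix[:2, :2].T + inv.matrix[:2, 2]
    valid = (
        (src[:, 0] >= 0) & (src[:, 0] <= w - 1) & (src[:, 1] >= 0) & (src[:, 1] <= h - 1)
    ).reshape(h, w)
    if valid.mean() < min_overlap_frac:
        return None
    warped = map_coordinates(b, [src[:, 1], src[:, 0]], order=1, mode="constant").reshape(h, w)
    _, ssim_map = structural_similarity(
        a, warped, gaussian_weights=True, data_range=1.0, full=True
    )
    # exclude windows touching invalid pixels
    core = binary_erosion(valid, np.ones((_WIN, _WIN)))
    if not core.any():
        return None
    return float(ssim_map[core].mean())


def pairwise_ssim(
    frames: list,
    transforms: list,
    d_max: int = 5,
    min_overlap_frac: float = 0.2,
) -> SsimReport:
    """SSIM for all frame pairs (i, i+d), d = 1..d_max.

    ``transforms`` are per-frame absolute states; the relative warp for
    a pair is ``X_i^-1 @ X_j``.  Pairs whose overlap fraction is below
    ``min_overlap_frac`` are recorded as skipped, not scored as zero.
    """
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    if len(frames) != len(transforms):
        raise ValueError("frames and transforms must align")
    report = SsimReport()
    n = len(frames)
    for d in range(1, d_max + 1):
        values, skipped = [], []
        for i in range(n - d):
            rel = transforms[i].inverse() @ transforms[i + d]
            s = _pair_ssim(frames[i], frames[i + d], rel, min_overlap_frac)
            if s is None:
                skipped.append((i, i + d))
            else:
                values.append(s)
        report.per_distance[d] = values
        report.skipped[d] = skipped
    return report


def summarize(reports: dict, d_max: int = 5) -> dict:
    """Mean-SSIM table: method -> {distance means..., "overall": pooled}.

    ``reports`` maps a method name to its SsimReport.  The pooled mean
    concatenates all distances' value lists (so distances with more
    scored pairs weigh more), matching how per-sequence averages are
    usually reported.
    """
    table = {}
    for method, report in reports.items():
        row = {d: report.mean(d) for d in range(1, d_max + 1)}
        row["overall"] = report.mean()
        table[method] = row
    return table
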