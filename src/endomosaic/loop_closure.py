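"""Loop-closure detection: keyframes + bag-of-visual-words retrieval.

Drift accumulated over a long trajectory can be corrected when the
camera revisits a previously seen part of the scene.  Keyframes are
selected by distance/time thresholds on the running chained transform;
their SIFT descriptors are quantised against a k-means vocabulary into
tf-idf-weighted bag-of-words histograms.  A new frame whose histogram
is cosine-similar to a sufficiently old keyframe becomes a loop
candidate, which is then geometrically verified by feature matching +
RANSAC; a verified pair contributes a loop edge to the pose graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .affine_estimation import ransac_affine
from .config import EstimationConfig, FeatureConfig, LoopClosureConfig, UncertaintyConfig
from .correspondence_sources import detect_keypoints, match_keypoints
from .geometry import AffineTransform
from .uncertainty import (
    Diagnostics,
    RegistrationEstimate,
    finalize_estimate,
    information_from_inliers,
)

__all__ = [
    "FrameFeatures",
    "KeyframeStore",
    "extract_features",
    "maybe_add_keyframe",
    "detect_loops",
    "register_loop_pair",
    "find_loop_closures",
]


@dataclass
class FrameFeatures:
    """Keypoints (u, v) and 128-D descriptors of one frame."""

    keypoints: np.ndarray
    descriptors: np.ndarray

    def __len__(self) -> int:
        return len(self.keypoints)


def extract_features(img: np.ndarray, params: FeatureConfig | None = None) -> FrameFeatures:
    kp, desc = detect_keypoints(img, params)
    return FrameFeatures(kp, desc)


def _kmeans_codebook(descriptors: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Plain Lloyd k-means codebook (scipy.cluster backs the iteration)."""
    from scipy.cluster.vq import kmeans2

    k = int(min(k, max(2, len(descriptors) // 4)))
    centers, _ = kmeans2(descriptors, k, minit="++", seed=seed, iter=20)
    # drop empty clusters (kmeans2 can return degenerate centres)
    keep = np.linalg.norm(centers, axis=1) > 0
    return centers[keep] if keep.any() else centers


@dataclass
class KeyframeStore:
    """Keyframe registry with a lazily (re)trained visual vocabulary.

    Frame 0 is always the first keyframe.  The vocabulary is k-means
    over the descriptors of the keyframes accumulated so far and is
    refreshed whenever the keyframe count doubles.
    """

    cfg: LoopClosureConfig = field(default_factory=LoopClosureConfig)
    seed: int = 0
    frames: list = field(default_factory=list)        # keyframe indices
    features: dict = field(default_factory=dict)      # idx -> FrameFeatures
    vocabulary: np.ndarray | None = None
    _bow: dict = field(default_factory=dict)          # idx -> L2-normalised tf-idf
    _trained_at: int = 0

    def __len__(self) -> int:
        return len(self.frames)

    # -- vocabulary -----------------------------------------------------
    def _ensure_vocabulary(self):
        need = self.vocabulary is None or len(self.frames) >= 2 * max(self._trained_at, 1)
        if not need:
            return
        descs = [self.features[i].descriptors for i in self.frames
                 if len(self.features[i]) > 0]
        if not descs:
            return
        stacked = np.concatenate(descs)
        if len(stacked) < 8:
            return
        self.vocabulary = _kmeans_codebook(stacked, self.cfg.vocab_size, self.seed)
        self._trained_at = len(self.frames)
        self._bow.clear()  # histograms are stale under a new codebook

    def _quantize(self, descriptors: np.ndarray) -> np.ndarray | None:
        if self.vocabulary is None or len(descriptors) == 0:
            return None
        d2 = (
            (descriptors**2).sum(1)[:, None]
            - 2 * descriptors @ self.vocabulary.T
            + (self.vocabulary**2).sum(1)[None, :]
        )
        words = np.argmin(d2, axis=1)
        hist = np.bincount(words, minlength=len(self.vocabulary)).astype(float)
        return hist

    def _idf(self) -> np.ndarray:
        counts = np.zeros(len(self.vocabulary))
        n_docs = 0
        for idx in self.frames:
            h = self._histogram(idx)
            if h is None:
                continue
            counts += h > 0
            n_docs += 1
        return np.log((n_docs + 1) / (counts + 1)) + 1.0

    def _histogram(self, idx: int) -> np.ndarray | None:
        if idx not in self._bow:
            h = self._quantize(self.features[idx].descriptors)
            if h is None:
                return None
            self._bow[idx] = h
        return self._bow[idx]

    def bow_vector(self, features: FrameFeatures) -> np.ndarray | None:
        """tf-idf-weighted, L2-normalised word histogram."""
        h = self._quantize(features.descriptors)
        if h is None or h.sum() == 0:
            return None
        v = (h / h.sum()) * self._idf()
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else None


def maybe_add_keyframe(
    store: KeyframeStore,
    frame_idx: int,
    current_state: AffineTransform,
    features: FrameFeatures,
) -> bool:
    """Add the frame as a keyframe per the distance-or-time rule.

    ``current_state`` is the running chained transform of the frame
    relative to the latest keyframe; a frame becomes a keyframe when its
    translation magnitude exceeds the distance threshold OR the frame
    gap exceeds the time threshold.  Frame 0 (an empty store) is always
    added.
    """

    def _add():
        store.frames.append(frame_idx)
        store.features[frame_idx] = features
        store._ensure_vocabulary()
        return True

    if len(store) == 0:
        return _add()
    gap = frame_idx - store.frames[-1]
    dist = float(np.linalg.norm(current_state.translation_vector))
    if dist > store.cfg.dist_thresh or gap > store.cfg.time_thresh:
        return _add()
    return False


def detect_loops(
    store: KeyframeStore,
    frame_idx: int,
    features: FrameFeatures,
    sim_thresh: float | None = None,
    min_gap: int | None = None,
) -> list:
    """Keyframes whose bag-of-words vector is similar to the query frame.

    Returns keyframe indices with cosine similarity >= ``sim_thresh``
    and frame gap >= ``min_gap`` (trivial temporal neighbours excluded).
    """
    sim_thresh = store.cfg.sim_thresh if sim_thresh is None else sim_thresh
    min_gap = store.cfg.min_gap if min_gap is None else min_gap
    store._ensure_vocabulary()
    q = store.bow_vector(features)
    if q is None:
        return []
    hits = []
    for idx in store.frames:
        if frame_idx - idx < min_gap:
            continue
        h = store._histogram(idx)
        if h is None or h.sum() == 0:
            continue
        v = (h / h.sum()) * store._idf()
        norm = np.linalg.norm(v)
        if norm == 0:
            continue
        sim = float(q @ (v / norm))
        if sim >= sim_thresh:
            hits.append((sim, idx))
    return [idx for _, idx in sorted(hits, reverse=True)]


def register_loop_pair(
    img_a: np.ndarray,
    img_b: np.ndarray,
    frame_a: int,
    frame_b: int,
    feature_cfg: FeatureConfig | None = None,
    est_cfg: EstimationConfig | None = None,
    unc_cfg: UncertaintyConfig | None = None,
    seed: int = 0,
    feats_a: FrameFeatures | None = None,
    feats_b: FrameFeatures | None = None,
) -> RegistrationEstimate:
    """Geometric verification of a loop candidate.

    Matches features of the two frames, runs RANSAC, and wraps the
    result as a loop edge ``z`` mapping frame-b coordinates into
    frame-a coordinates, weighted by the inlier count.  Failed
    estimates carry zero information and are dropped by the graph.
    Precomputed ``feats_a`` / ``feats_b`` skip re-detection.
    """
    est_cfg = est_cfg or EstimationConfig()
    if feats_a is None:
        feats_a = extract_features(img_a, feature_cfg)
    if feats_b is None:
        feats_b = extract_features(img_b, feature_cfg)
    # src in b, dst in a, so z maps frame-b coordinates into frame-a
    corr = match_keypoints(
        feats_b.keypoints, feats_b.descriptors,
        feats_a.keypoints, feats_a.descriptors, feature_cfg,
    )
    res = ransac_affine(
        corr,
        eps=est_cfg.eps,
        max_iters=est_cfg.max_iters,
        min_inliers=est_cfg.min_inliers,
        seed=seed,
        sample_size=est_cfg.sample_size,
    )
    est = RegistrationEstimate(
        frame_i=frame_a,
        frame_j=frame_b,
        source="feature",
        transform=res.transform,
        info=information_from_inliers(res.n_inliers if res.converged else 0),
        diagnostics=Diagnostics(
            n_inliers=res.n_inliers,
            n_correspondences=len(corr),
            residual=float("nan"),
            converged=res.converged,
        ),
        is_loop=True,
    )
    return finalize_estimate(est, unc_cfg)


def find_loop_closures(
    frames: list,
    chained_states: list,
    cfg: LoopClosureConfig | None = None,
    feature_cfg: FeatureConfig | None = None,
    est_cfg: EstimationConfig | None = None,
    unc_cfg: UncertaintyConfig | None = None,
    seed: int = 0,
    features: list | None = None,
) -> list:
    """Scan a sequence once and return verified loop-closure edges.

    ``chained_states`` are provisional anchor-relative states (from
    chaining the consecutive estimates) used only for the keyframe
    distance rule.  ``features`` may carry precomputed per-frame
    FrameFeatures.  At most one (best-similarity) verified loop edge is
    kept per query frame.
    """
    cfg = cfg or LoopClosureConfig()
    if cfg.dist_thresh <= 0:
        cfg.dist_thresh = 0.5 * np.asarray(frames[0]).shape[1]
    store = KeyframeStore(cfg=cfg, seed=seed)
    edges = []
    for k, frame in enumerate(frames):
        feats = features[k] if features is not None else extract_features(frame, feature_cfg)
        last_kf = store.frames[-1] if len(store) else 0
        rel = (
            chained_states[last_kf].inverse() @ chained_states[k]
            if len(store)
            else AffineTransform.identity()
        )
        candidates = detect_loops(store, k, feats)
        for idx in candidates:
            est = register_loop_pair(
                frames[idx], frame, idx, k, feature_cfg, est_cfg, unc_cfg,
                seed=seed + k, feats_a=store.features[idx], feats_b=feats,
            )
            if not est.failed:
                edges.append(est)
                break
        maybe_add_keyframe(store, k, rel, feats)
    return edges
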