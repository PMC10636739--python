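"""Ground-truth-known synthetic frame sequences.

Renders video frames from a large textured scene through a known affine
camera trajectory, with optional endoscopy-like corruptions: a drifting
multiplicative illumination gradient (the light source moves with the
camera), saturated specular blobs that travel inconsistently with camera
motion, texture-poor regions, and sensor noise.  Every stage of the
mosaicking pipeline can therefore be tested against exact ground truth
without any external dataset.

Rendering is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, zoom

from .geometry import AffineTransform

__all__ = [
    "SyntheticSequence",
    "generate_scene",
    "featureless_patch_bounds",
    "generate_trajectory",
    "render_sequence",
    "make_sequence",
    "export_sequence",
]

SCENE_KINDS = ("textured", "vessel_like", "featureless_patches")
TRAJECTORY_MODELS = ("pan", "out_and_back", "random_walk")


@dataclass
class SyntheticSequence:
    """Rendered frames plus everything needed to check them."""

    frames: list                      # float images in [0, 1], equal size
    truth: list                       # anchor-relative AffineTransforms, truth[0] = I
    scene: np.ndarray                 # the source texture
    scene_offset: np.ndarray          # anchor-frame origin in scene coordinates (u, v)
    corruption_log: list = field(default_factory=list)  # per-frame effect record


def _value_noise(size: int, rng: np.random.Generator, decay: float = 0.7) -> np.ndarray:
    """Multi-octave value noise, normalised to [0, 1]."""
    img = np.zeros((size, size))
    octave, amp = 4, 1.0
    while octave <= size:
        grid = rng.standard_normal((octave, octave))
        img += amp * zoom(grid, size / octave, order=3)[:size, :size]
        octave *= 2
        amp *= decay
    img -= img.min()
    img /= img.max()
    return img


def featureless_patch_bounds(size: int) -> tuple:
    """(u0, v0, u1, v1) of the designated low-contrast patch."""
    return (int(0.50 * size), int(0.30 * size), int(0.90 * size), int(0.70 * size))


def generate_scene(kind: str, size: int, seed: int) -> np.ndarray:
    """Render a ``size`` x ``size`` scene texture, deterministic per seed.

    ``textured``            multi-octave value noise, keypoint-rich.
    ``vessel_like``         dark curvilinear structures on a smooth
                            background (placenta-like).
    ``featureless_patches`` textured scene with a large low-contrast
                            region (see :func:`featureless_patch_bounds`).
    """
    if kind not in SCENE_KINDS:
        raise ValueError(f"unknown scene kind {kind!r}; valid: {SCENE_KINDS}")
    if size < 64:
        raise ValueError("scene size must be at least 64 px")
    rng = np.random.default_rng(seed)
    if kind == "textured":
        return _value_noise(size, rng)
    if kind == "vessel_like":
        # smooth bright background with dark meandering curves
        bg = 0.65 + 0.25 * _value_noise(size, rng, decay=0.35)
        vessels = np.zeros((size, size))
        n_vessels = max(6, size // 48)
        for _ in range(n_vessels):
            pos = rng.uniform(0, size, 2)
            ang = rng.uniform(0, 2 * np.pi)
            width = rng.uniform(1.0, 2.5)
            for _ in range(size * 2):
                r, c = int(pos[1]), int(pos[0])
                if 0 <= r < size and 0 <= c < size:
                    rr = slice(max(r - int(width), 0), r + int(width) + 1)
                    cc = slice(max(c - int(width), 0), c + int(width) + 1)
                    vessels[rr, cc] = 1.0
                ang += rng.normal(0, 0.15)
                pos += [np.cos(ang), np.sin(ang)]
        vessels = gaussian_filter(vessels, 1.0)
        img = bg * (1.0 - 0.55 * vessels)
        img -= img.min()
        img /= img.max()
        return img
    # featureless_patches: crush (but do not erase) the contrast inside
    # the designated box — low-texture tissue still has faint structure,
    # which yields few, poorly localised keypoints rather than none
    img = _value_noise(size, rng)
    u0, v0, u1, v1 = featureless_patch_bounds(size)
    smooth = gaussian_filter(img, size / 24)
    mask = np.zeros((size, size))
    mask[v0:v1, u0:u1] = 1.0
    # feather the boundary so the patch edge itself is not a feature line
    mask = gaussian_filter(mask, size / 64)
    low_contrast = smooth * 0.85 + img * 0.15
    return img * (1 - mask) + low_contrast * mask


def generate_trajectory(
    n_frames: int, model: str, magnitude, seed: int = 0
) -> list:
    """Ground-truth anchor-relative camera states ``x_0 .. x_{n-1}``.

    ``magnitude`` is the per-step translation: a ``(dx, dy)`` pair for
    ``pan``, a scalar maximum step length for ``out_and_back`` and
    ``random_walk``.  ``x_k`` maps frame-k pixel coordinates into
    anchor-frame (frame-0) coordinates; ``x_0`` is the identity.
    """
    if model not in TRAJECTORY_MODELS:
        raise ValueError(f"unknown trajectory model {model!r}; valid: {TRAJECTORY_MODELS}")
    if n_frames < 2:
        raise ValueError("a trajectory needs at least 2 frames")
    rng = np.random.default_rng(seed)
    if model == "pan":
        dx, dy = magnitude
        return [AffineTransform.translation(dx * k, dy * k) for k in range(n_frames)]
    if model == "out_and_back":
        # smooth sine excursion along +u returning exactly to the start;
        # the peak step length equals `magnitude`
        amp = float(magnitude) * (n_frames - 1) / np.pi
        pos = amp * np.sin(np.pi * np.arange(n_frames) / (n_frames - 1))
        return [AffineTransform.translation(p, 0.0) for p in pos]
    # random_walk: translation-dominant with small rotation and scale drift
    step = float(magnitude)
    states = [AffineTransform.identity()]
    for _ in range(n_frames - 1):
        dx, dy = rng.normal(0, step / np.sqrt(2), 2)
        theta = rng.normal(0, 0.01)
        scale = 1.0 + rng.normal(0, 0.005)
        c, s = np.cos(theta), np.sin(theta)
        rel = AffineTransform.from_params(scale * c, -scale * s, scale * s, scale * c, dx, dy)
        states.append(states[-1] @ rel)
    return states


def _frame_corners(w: int, h: int) -> np.ndarray:
    return np.array([[0.0, 0.0], [w - 1.0, 0.0], [0.0, h - 1.0], [w - 1.0, h - 1.0]])


def render_sequence(
    scene: np.ndarray,
    trajectory: list,
    frame_size: tuple,
    effects: dict | None = None,
    seed: int = 0,
) -> SyntheticSequence:
    """Sample frames from the scene along the trajectory and corrupt them.

    ``effects`` keys (all optional):
      ``illum_gradient_strength``  peak-to-centre multiplicative gradient
                                   amplitude (0 disables),
      ``specular_blobs``           number of saturated moving blobs,
      ``specular_frames``          (start, stop) frame window for the blobs,
      ``noise_sigma``              additive Gaussian noise, intensity units.
    """
    effects = dict(effects or {})
    illum = float(effects.pop("illum_gradient_strength", 0.0))
    n_blobs = int(effects.pop("specular_blobs", 0))
    blob_window = effects.pop("specular_frames", None)
    blob_speed = float(effects.pop("specular_speed", 6.0))
    noise_sigma = float(effects.pop("noise_sigma", 0.0))
    if effects:
        raise ValueError(f"unknown effect keys: {sorted(effects)}")

    w, h = int(frame_size[0]), int(frame_size[1])
    corners = _frame_corners(w, h)
    all_pts = np.concatenate([t.apply(corners) for t in trajectory])
    lo, hi = all_pts.min(axis=0), all_pts.max(axis=0)
    sh, sw = scene.shape
    extent = hi - lo
    if extent[0] > sw - 2 or extent[1] > sh - 2:
        # name the first frame whose footprint leaves the scene when the
        # start of the trajectory is placed at the scene origin
        offending = 0
        for k, t in enumerate(trajectory):
            span = t.apply(corners) - lo
            if span[:, 0].max() > sw - 2 or span[:, 1].max() > sh - 2:
                offending = k
                break
        need = int(np.ceil(max(extent) + 2))
        raise ValueError(
            f"frame {offending} samples outside the {sw}x{sh} scene "
            f"(trajectory extent {extent}); need at least {need}x{need}"
        )
    # integer offset so that an identity trajectory samples exact pixels
    offset = np.floor((np.array([sw, sh]) - 2 - extent) / 2 - lo)

    rng = np.random.default_rng(seed)
    blob_pos = rng.uniform([0, 0], [w, h], size=(n_blobs, 2))
    # blobs travel fast and inconsistently with the camera, so the
    # saturated regions of consecutive frames overlap only partially
    blob_vel = rng.uniform(-blob_speed, blob_speed, size=(n_blobs, 2))
    blob_radius = max(4.0, 0.06 * min(w, h))
    theta0 = rng.uniform(0, 2 * np.pi)

    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    frames, log = [], []
    for k, truth in enumerate(trajectory):
        pts = truth.apply(np.column_stack([uu.ravel(), vv.ravel()])) + offset
        frame = map_coordinates(
            scene, [pts[:, 1], pts[:, 0]], order=1, mode="constant", cval=0.0
        ).reshape(h, w)
        entry = {"frame": k, "effects": []}
        if illum > 0:
            theta = theta0 + 0.05 * k  # gradient direction drifts with the camera
            ramp = (uu / w - 0.5) * np.cos(theta) + (vv / h - 0.5) * np.sin(theta)
            frame = frame * np.clip(1.0 + illum * ramp, 0.0, None)
            entry["effects"].append({"illum_theta": float(theta), "strength": illum})
        blobs_active = n_blobs > 0 and (
            blob_window is None or blob_window[0] <= k < blob_window[1]
        )
        if blobs_active:
            for b in range(n_blobs):
                p = blob_pos[b] + k * blob_vel[b]
                p = np.mod(p, [w, h])  # wrap so blobs stay in view
                d2 = (uu - p[0]) ** 2 + (vv - p[1]) ** 2
                frame[d2 <= blob_radius**2] = 1.0
            entry["effects"].append({"specular_blobs": n_blobs, "radius": blob_radius})
        if noise_sigma > 0:
            frame = frame + rng.normal(0, noise_sigma, frame.shape)
            entry["effects"].append({"noise_sigma": noise_sigma})
        frames.append(np.clip(frame, 0.0, 1.0))
        log.append(entry)
    return SyntheticSequence(
        frames=frames,
        truth=list(trajectory),
        scene=scene,
        scene_offset=offset,
        corruption_log=log,
    )


def make_sequence(
    n_frames: int = 30,
    scene_kind: str = "textured",
    trajectory_model: str = "pan",
    magnitude=(4.0, 0.0),
    frame_size: tuple = (100, 100),
    scene_size: int = 512,
    effects: dict | None = None,
    seed: int = 0,
) -> SyntheticSequence:
    """One-call generator used by tests, the CLI and the benchmark."""
    scene = generate_scene(scene_kind, scene_size, seed)
    traj = generate_trajectory(n_frames, trajectory_model, magnitude, seed=seed + 1)
    return render_sequence(scene, traj, frame_size, effects=effects, seed=seed + 2)


def export_sequence(seq: SyntheticSequence, out_dir: str | Path) -> None:
    """Write frames as PNGs plus a ground-truth JSON next to them."""
    import json

    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, frame in enumerate(seq.frames):
        iio.imwrite(out / f"frame_{k:05d}.png", (frame * 255).round().astype(np.uint8))
    truth = {"transforms": [t.to_list() for t in seq.truth]}
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
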