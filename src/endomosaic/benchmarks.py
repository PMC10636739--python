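"""Reference synthetic studies: the corrupted benchmark and the loop study.

These define the package's standard stress conditions in one place so
tests, the CLI preset and the reproduction script all run the same
experiment:

``corrupted_benchmark``  a 60-frame pan across a scene with a large
    low-contrast region, with a saturated fast-moving specular-blob
    sweep over the textured part and sensor noise — each registration
    source has a phase in which it degrades or fails outright.

``loop_closure_study``   a 50-frame noisy out-and-back pan; compares
    the start-vs-revisit positional error of the optimised trajectory
    with and without detected loop-closure edges.
"""

from __future__ import annotations

import numpy as np

from .config import RunConfig
from .loop_closure import extract_features, find_loop_closures
from .pipeline import estimate_pairs, run_benchmark, states_for_mode
from .synthetic_data import make_sequence

__all__ = [
    "CORRUPTED_EFFECTS",
    "corrupted_sequence",
    "corrupted_benchmark",
    "moderate_pan_recovery",
    "loop_closure_study",
]

# Study conditions for the corrupted benchmark: the blob sweep covers
# frames 12-30 (the textured part of the pan), the low-contrast patch is
# crossed from roughly frame 30 onward, and sensor noise acts throughout.
CORRUPTED_EFFECTS = {
    "specular_blobs": 16,
    "specular_frames": (12, 30),
    "specular_speed": 10.0,
    "noise_sigma": 0.015,
}


def corrupted_sequence(seed: int, n_frames: int = 60):
    return make_sequence(
        n_frames=n_frames,
        scene_kind="featureless_patches",
        trajectory_model="pan",
        magnitude=(4.0, 0.0),
        frame_size=(100, 100),
        scene_size=512,
        effects=CORRUPTED_EFFECTS,
        seed=seed,
    )


def corrupted_benchmark(seed: int, n_frames: int = 60) -> dict:
    """All six fusion modes on one corrupted sequence.

    Returns the ``run_benchmark`` dict plus the sequence under "sequence".
    """
    seq = corrupted_sequence(seed, n_frames)
    cfg = RunConfig(seed=seed)
    bench = run_benchmark(seq.frames, cfg)
    bench["sequence"] = seq
    return bench


def moderate_pan_recovery(seed: int, n_frames: int = 60) -> dict:
    """Fused-pipeline accuracy on a pan with moderate corruptions.

    Moderate = a drifting illumination gradient (0.1) plus mild sensor
    noise (0.01) — corruptions that perturb each pairwise estimate
    without biasing it systematically.  That restriction is what makes a
    tight absolute-trajectory bound meaningful: an open 60-frame chain
    amplifies any systematic per-pair bias ~60x, so saturated-specular
    phases (which do bias pairs; see the corrupted benchmark) are
    deliberately not part of this study.  Returns mean/max corner error
    (px) of the optimised states against ground truth.
    """
    seq = make_sequence(
        n_frames=n_frames,
        scene_kind="textured",
        trajectory_model="pan",
        magnitude=(4.0, 0.0),
        frame_size=(100, 100),
        scene_size=512,
        effects={
            "illum_gradient_strength": 0.1,
            "noise_sigma": 0.01,
        },
        seed=seed,
    )
    from .pipeline import run_mosaic

    cfg = RunConfig(seed=seed)
    res = run_mosaic(seq.frames, cfg)
    corners = np.array([[0.0, 0.0], [99.0, 0.0], [0.0, 99.0], [99.0, 99.0]])
    errs = [
        float(np.linalg.norm(got.apply(corners) - want.apply(corners), axis=1).mean())
        for got, want in zip(res.states, seq.truth)
    ]
    return {
        "mean_corner_error": float(np.mean(errs)),
        "max_corner_error": float(np.max(errs)),
        "result": res,
        "sequence": seq,
    }


def loop_closure_study(seed: int, n_frames: int = 50) -> dict:
    """Start-vs-revisit error with and without loop edges, one seed.

    The camera pans out and returns to its start; the error is the
    translation distance between the final optimised state and the
    ground-truth final state (near the anchor).  Feature estimates are
    used as odometry so that drift accumulates and loop edges have
    something to correct.
    """
    seq = make_sequence(
        n_frames=n_frames,
        trajectory_model="out_and_back",
        magnitude=5.0,
        frame_size=(100, 100),
        scene_size=512,
        effects={"noise_sigma": 0.02},
        seed=seed,
    )
    cfg = RunConfig(seed=seed, sources=["feature"])
    features = [extract_features(f, cfg.feature) for f in seq.frames]
    estimates = estimate_pairs(seq.frames, cfg, ["feature"], features)
    chained, _ = states_for_mode(estimates, n_frames, "single:feature")
    loop_edges = find_loop_closures(
        seq.frames, chained, cfg.loop_closure, cfg.feature,
        cfg.estimation, cfg.uncertainty, seed=seed, features=features,
    )
    without, _ = states_for_mode(estimates, n_frames, "graph", [], cfg)
    with_lc, _ = states_for_mode(estimates, n_frames, "graph", loop_edges, cfg)

    def end_error(states):
        d = states[-1].translation_vector - seq.truth[-1].translation_vector
        return float(np.linalg.norm(d))

    return {
        "n_loop_edges": len(loop_edges),
        "error_without": end_error(without),
        "error_with": end_error(with_lc),
        "improved": end_error(with_lc) < end_error(without),
    }
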