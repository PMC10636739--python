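"""Scene rendering, trajectories, corruption effects, recoverability."""

import numpy as np
import pytest

from endomosaic.correspondence_sources import detect_keypoints
from endomosaic.direct_registration import register_direct
from endomosaic.geometry import AffineTransform
from endomosaic.synthetic_data import (
    SyntheticSequence,
    export_sequence,
    featureless_patch_bounds,
    generate_scene,
    generate_trajectory,
    make_sequence,
    render_sequence,
)
from tests.conftest import corner_error


class TestGenerateScene:
    def test_deterministic_per_seed(self):
        a = generate_scene("textured", 128, seed=4)
        b = generate_scene("textured", 128, seed=4)
        assert np.array_equal(a, b)
        c = generate_scene("textured", 128, seed=5)
        assert not np.array_equal(a, c)

    def test_textured_scene_is_keypoint_rich(self, textured_scene):
        kp, _ = detect_keypoints(textured_scene)
        assert len(kp) >= 100

    def test_featureless_patch_starves_the_detector(self):
        scene = generate_scene("featureless_patches", 512, seed=13)
        kp, _ = detect_keypoints(scene)
        u0, v0, u1, v1 = featureless_patch_bounds(512)
        margin = 20  # stay clear of the feathered boundary
        inside = (
            (kp[:, 0] > u0 + margin)
            & (kp[:, 0] < u1 - margin)
            & (kp[:, 1] > v0 + margin)
            & (kp[:, 1] < v1 - margin)
        ).sum()
        assert inside < 5

    def test_vessel_scene_has_dark_structures(self):
        scene = generate_scene("vessel_like", 256, seed=2)
        assert scene.min() < 0.2 and scene.max() > 0.8

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            generate_scene("checkerboard", 128, seed=0)


class TestGenerateTrajectory:
    def test_pan_is_exact_linear_translation(self):
        traj = generate_trajectory(6, "pan", (5.0, 0.0))
        for k, t in enumerate(traj):
            assert np.allclose(t.translation_vector, [5.0 * k, 0.0], atol=0)
            assert np.array_equal(t.linear, np.eye(2))

    def test_out_and_back_returns_to_start(self):
        traj = generate_trajectory(50, "out_and_back", 5.0, seed=1)
        assert np.linalg.norm(traj[0].translation_vector) == 0.0
        assert np.linalg.norm(traj[-1].translation_vector) < 0.5  # 10% of step
        peak = max(np.linalg.norm(t.translation_vector) for t in traj)
        assert peak > 20  # actually goes somewhere

    def test_random_walk_reproducible(self):
        a = generate_trajectory(10, "random_walk", 3.0, seed=7)
        b = generate_trajectory(10, "random_walk", 3.0, seed=7)
        for x, y in zip(a, b):
            assert np.array_equal(x.matrix, y.matrix)

    def test_needs_two_frames(self):
        with pytest.raises(ValueError):
            generate_trajectory(1, "pan", (1.0, 0.0))


class TestRenderSequence:
    def test_identity_trajectory_no_effects_is_exact_crop(self, small_scene):
        traj = [AffineTransform.identity()] * 3
        seq = render_sequence(small_scene, traj, (64, 64), effects=None, seed=0)
        off = seq.scene_offset.astype(int)
        crop = small_scene[off[1] : off[1] + 64, off[0] : off[0] + 64]
        for frame in seq.frames:
            assert np.array_equal(frame, crop)

    def test_effects_off_direct_registration_recovers_steps(self, pan_sequence):
        seq = pan_sequence
        for i in range(2):
            res = register_direct(seq.frames[i], seq.frames[i + 1])
            z_true = seq.truth[i].inverse() @ seq.truth[i + 1]
            assert corner_error(res.transform, z_true) < 0.2

    def test_specular_blobs_saturate_pixels(self, small_scene):
        traj = [AffineTransform.identity()] * 2
        seq = render_sequence(
            small_scene, traj, (100, 100),
            effects={"specular_blobs": 8}, seed=3,
        )
        for frame in seq.frames:
            assert (frame >= 1.0).mean() >= 0.01

    def test_out_of_scene_trajectory_raises(self, small_scene):
        traj = [AffineTransform.identity(), AffineTransform.translation(5000, 0)]
        with pytest.raises(ValueError, match="scene"):
            render_sequence(small_scene, traj, (64, 64))

    def test_unknown_effect_key_rejected(self, small_scene):
        with pytest.raises(ValueError, match="effect"):
            render_sequence(
                small_scene, [AffineTransform.identity()] * 2, (64, 64),
                effects={"lens_flare": 1},
            )

    def test_rendering_is_pure_function_of_config_and_seed(self, small_scene):
        traj = generate_trajectory(4, "pan", (3.0, 1.0))
        eff = {"illum_gradient_strength": 0.3, "noise_sigma": 0.01}
        a = render_sequence(small_scene, traj, (64, 64), eff, seed=9)
        b = render_sequence(small_scene, traj, (64, 64), eff, seed=9)
        for fa, fb in zip(a.frames, b.frames):
            assert np.array_equal(fa, fb)

    def test_corruption_log_records_effects(self, small_scene):
        seq = render_sequence(
            small_scene, [AffineTransform.identity()] * 3, (64, 64),
            effects={"specular_blobs": 2, "specular_frames": (1, 2)}, seed=0,
        )
        blobbed = [
            any("specular_blobs" in e for e in entry["effects"])
            for entry in seq.corruption_log
        ]
        assert blobbed == [False, True, False]


class TestEndToEndRecoverability:
    def test_fused_pipeline_recovers_moderate_pan(self):
        """Core regression: fused states track truth within 3 px mean
        corner error on a 60-frame pan with moderate corruptions."""
        from endomosaic.benchmarks import moderate_pan_recovery

        r = moderate_pan_recovery(seed=34)
        assert r["mean_corner_error"] < 3.0


class TestExport:
    def test_png_directory_roundtrip(self, tmp_path, pan_sequence):
        from endomosaic.pipeline import load_frames

        export_sequence(pan_sequence, tmp_path)
        frames = load_frames(tmp_path)
        assert len(frames) == len(pan_sequence.frames)
        # 8-bit quantisation only
        assert np.abs(frames[0] - pan_sequence.frames[0]).max() <= 1 / 255 + 1e-9
        assert (tmp_path / "truth.json").exists()
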