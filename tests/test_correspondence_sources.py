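"""Feature matching, dense flow, and the flow-to-correspondence map."""

import numpy as np
import pytest

from endomosaic.config import FlowConfig
from endomosaic.correspondence_sources import (
    Correspondences,
    FlowField,
    compute_dense_flow,
    detect_and_match_features,
    flow_to_correspondences,
    read_flo,
    write_flo,
)
from endomosaic.geometry import AffineTransform


@pytest.fixture(scope="module")
def crops(small_scene):
    """Two 100x100 crops of the same scene, offset by (8, 0) pixels."""
    a = small_scene[60:160, 60:160]
    b = small_scene[60:160, 68:168]
    return a, b


class TestFeatureMatching:
    def test_self_matching_is_near_exact(self, small_scene):
        img = small_scene[40:168, 40:168]
        corr = detect_and_match_features(img, img)
        assert len(corr) >= 10
        d = np.linalg.norm(corr.src_pts - corr.dst_pts, axis=1)
        assert np.all(d < 0.5)

    def test_known_translation_recovered(self, crops):
        a, b = crops
        corr = detect_and_match_features(a, b)
        assert len(corr) >= 10
        med = np.median(corr.dst_pts - corr.src_pts, axis=0)
        # b shows the scene 8 px to the right, so content moves by (-8, 0)
        assert np.allclose(med, [-8.0, 0.0], atol=1.0)

    def test_featureless_images_give_empty_result(self):
        flat = np.full((64, 64), 0.5)
        corr = detect_and_match_features(flat, flat)
        assert len(corr) == 0

    def test_matches_follow_ground_truth_affine(self, small_scene):
        # warp the scene by a known affine; at least 80% of matches must
        # agree with the ground-truth mapping to within 1 px
        from scipy.ndimage import map_coordinates

        T = AffineTransform.from_params(1.01, 0.03, -0.02, 0.99, 5.0, -2.0)
        h = w = 128
        uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
        pts = T.apply(np.column_stack([uu.ravel(), vv.ravel()])) + 60.0
        warped = map_coordinates(
            small_scene, [pts[:, 1], pts[:, 0]], order=1
        ).reshape(h, w)
        base = small_scene[60:188, 60:188]
        corr = detect_and_match_features(warped, base)
        assert len(corr) >= 10
        # warped(p) = scene(T p + 60) = base(T p), so dst ~ T(src)
        err = np.linalg.norm(corr.dst_pts - T.apply(corr.src_pts), axis=1)
        assert (err < 1.0).mean() >= 0.8


class TestDenseFlow:
    def test_zero_motion(self, crops):
        a, _ = crops
        field = compute_dense_flow(a, a)
        mag = np.linalg.norm(field.flow, axis=2)
        assert np.median(mag) < 0.2

    def test_pure_translation(self, small_scene):
        # b(p + (5, -3)) = a(p): sampling b at the flow-displaced point
        # recovers a, per the compute_dense_flow contract
        a = small_scene[60:160, 60:160]
        b = small_scene[63:163, 55:155]
        field = compute_dense_flow(a, b)
        interior = field.flow[20:-20, 20:-20]
        med = np.median(interior.reshape(-1, 2), axis=0)
        assert np.allclose(med, [5.0, -3.0], atol=0.5)

    def test_precomputed_adapter_roundtrip(self, tmp_path, crops):
        a, b = crops
        rng = np.random.default_rng(0)
        field = FlowField(rng.normal(0, 3, (100, 100, 2)).astype(np.float32))
        write_flo(tmp_path / "00001_00000.flo", field)
        cfg = FlowConfig(backend="precomputed", precomputed_dir=str(tmp_path))
        got = compute_dense_flow(a, b, cfg, pair_key="00001_00000")
        assert np.array_equal(
            got.flow.astype(np.float32), field.flow.astype(np.float32)
        )

    def test_unknown_backend_rejected(self, crops):
        a, b = crops
        with pytest.raises(ValueError, match="backend"):
            compute_dense_flow(a, b, FlowConfig(backend="flownet"))


def brute_force_pairs(flow, stride, margin):
    """Enumeration oracle for flow_to_correspondences."""
    h, w = flow.shape[:2]
    out = []
    for v in range(margin, h - margin, stride):
        for u in range(margin, w - margin, stride):
            ox, oy = flow[v, u]
            du, dv = u + ox, v + oy
            if 0 <= du <= w - 1 and 0 <= dv <= h - 1:
                out.append(((u, v), (du, dv)))
    return out


class TestFlowToCorrespondences:
    def test_zero_flow_full_grid(self):
        field = FlowField(np.zeros((4, 4, 2)))
        corr = flow_to_correspondences(field, stride=1, border_margin=0)
        assert len(corr) == 16
        assert np.array_equal(corr.src_pts, corr.dst_pts)

    def test_constant_flow_drops_out_of_bounds(self):
        flow = np.zeros((10, 10, 2))
        flow[..., 0] = 5.0
        corr = flow_to_correspondences(FlowField(flow), stride=1, border_margin=0)
        # sources with u >= 5 map outside the image: 10 rows x 5 valid columns
        assert len(corr) == 50
        assert np.array_equal(corr.dst_pts[:, 0], corr.src_pts[:, 0] + 5)

    def test_stride_two_grid_count(self):
        field = FlowField(np.zeros((10, 10, 2)))
        corr = flow_to_correspondences(field, stride=2, border_margin=0)
        assert len(corr) == 25

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        flow = rng.normal(0, 4, (37, 29, 2))
        for stride, margin in [(1, 0), (3, 2), (8, 4)]:
            corr = flow_to_correspondences(FlowField(flow), stride, margin)
            oracle = brute_force_pairs(flow, stride, margin)
            assert len(corr) == len(oracle)

    def test_stride_larger_than_image_gives_empty(self):
        field = FlowField(np.zeros((8, 8, 2)))
        corr = flow_to_correspondences(field, stride=50, border_margin=4)
        assert len(corr) == 0


class TestFloFormat:
    def test_bad_magic_rejected(self, tmp_path):
        path = tmp_path / "bad.flo"
        path.write_bytes(b"\x00" * 32)
        with pytest.raises(ValueError, match="magic"):
            read_flo(path)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Correspondences(np.zeros((3, 2)), np.zeros((2, 2)))
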