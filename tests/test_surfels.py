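"""Surfel map: fusion, time windowing, splatted prediction, PLY I/O."""

import numpy as np
import pytest

from endofusion.geometry import Intrinsics, RigidTransform
from endofusion.preprocess import Frame, luminance
from endofusion.surfels import SurfelMap

K = Intrinsics(fx=55.0, fy=55.0, cx=31.5, cy=31.5, width=64, height=64)


def gt_frame(seq, i=0, margin=2):
    d = seq.ground_truth.depths[i].copy()
    valid = d > 0
    valid[:margin] = valid[-margin:] = valid[:, :margin] = valid[:, -margin:] = False
    img = seq.images[i]
    return Frame(float(seq.timestamps[i]), img, luminance(img), d, valid)


class TestFusion:
    def test_first_fuse_inserts_one_surfel_per_valid_pixel(self, single_frame_seq):
        m = SurfelMap(single_frame_seq.intrinsics)
        f = gt_frame(single_frame_seq)
        m.fuse_frame(f, RigidTransform.identity())
        # insertion count equals valid pixels with usable normals
        assert 0 < len(m) <= int(f.valid_mask.sum())
        assert len(m) > 0.9 * f.valid_mask.sum()
        assert (m.weights == 1).all()

    def test_refusing_smooth_frame_keeps_count_and_bumps_weights(self):
        # gently curved surface: every pixel re-associates on the second fuse
        H, W = K.height, K.width
        cols = np.tile(np.arange(W, dtype=float), (H, 1))
        rows = np.tile(np.arange(H, dtype=float)[:, None], (1, W))
        depth = 1.0 + 0.02 * np.sin(cols / 20) + 0.02 * np.cos(rows / 20)
        gray = np.full((H, W), 0.5)
        valid = np.ones((H, W), bool)
        valid[:2] = valid[-2:] = valid[:, :2] = valid[:, -2:] = False
        f = Frame(0.0, np.stack([gray] * 3, -1), gray, depth, valid)
        m = SurfelMap(K)
        m.fuse_frame(f, RigidTransform.identity())
        n1 = len(m)
        m.fuse_frame(f, RigidTransform.identity())
        assert len(m) == n1
        # every pixel merged somewhere: total confidence doubles exactly
        assert m.weights.sum() == 2 * n1
        assert (m.weights >= 2).mean() > 0.95

    def test_refusing_cavity_frame_barely_grows(self, single_frame_seq):
        m = SurfelMap(single_frame_seq.intrinsics)
        f = gt_frame(single_frame_seq)
        m.fuse_frame(f, RigidTransform.identity())
        n1 = len(m)
        m.fuse_frame(f, RigidTransform.identity())
        # high-curvature pixels may fail the normal gate and re-insert
        assert len(m) - n1 < 0.02 * n1

    def test_weighted_average_merge_rule(self):
        m = SurfelMap(K)
        m._insert(
            np.array([[0.0, 0.0, 1.0]]), np.array([[0.0, 0.0, -1.0]]),
            np.array([[0.5, 0.5, 0.5]]), np.array([0.01]), 0.0,
        )
        m.weights[0] = 3.0
        p2 = np.array([[0.004, 0.0, 1.0]])
        m._merge(
            np.array([0]), p2, np.array([[0.0, 0.0, -1.0]]),
            np.array([[0.9, 0.1, 0.1]]), np.array([0.02]), 1.0,
        )
        assert np.allclose(m.positions[0], (3 * np.array([0, 0, 1.0]) + p2[0]) / 4)
        assert m.weights[0] == 4.0
        assert m.t_last[0] == 1.0
        assert m.radii[0] == 0.01  # radius never grows on merge


class TestTimeWindow:
    def make_map(self):
        m = SurfelMap(K, delta_t=10.0)
        rng = np.random.default_rng(0)
        for t in (0.0, 5.0, 16.0):
            pts = rng.normal(size=(10, 3)) + [0, 0, 5]
            nrm = np.tile([0.0, 0.0, -1.0], (10, 1))
            m._insert(pts, nrm, np.full((10, 3), 0.5), np.full(10, 0.01), t)
        m.advance_time(16.0)
        return m

    def test_window_rule(self):
        m = self.make_map()
        # t_last = 0 and 5 at now=16 exceed delta_t=10 -> inactive
        assert m.inactive_mask.sum() == 20
        assert m.active_mask.sum() == 10

    def test_partition_is_exhaustive_and_disjoint(self):
        m = self.make_map()
        assert (m.active_mask ^ m.inactive_mask).all()
        assert m.active_mask.sum() + m.inactive_mask.sum() == len(m)

    def test_all_recent_means_no_inactive(self):
        m = SurfelMap(K, delta_t=10.0)
        m._insert(
            np.zeros((5, 3)) + [0, 0, 1], np.tile([0.0, 0, -1], (5, 1)),
            np.full((5, 3), 0.5), np.full(5, 0.01), 3.0,
        )
        m.advance_time(3.0)
        assert not m.inactive_mask.any()

    def test_time_backwards_raises(self):
        m = self.make_map()
        with pytest.raises(ValueError):
            m.advance_time(2.0)


class TestPredictView:
    def test_single_surfel_disc_at_principal_point(self):
        m = SurfelMap(K)
        m._insert(
            np.array([[0.0, 0.0, 1.0]]), np.array([[0.0, 0.0, -1.0]]),
            np.array([[0.2, 0.4, 0.6]]), np.array([0.01]), 0.0,
        )
        m.advance_time(0.0)
        pred = m.predict_view(RigidTransform.identity(), subset="active")
        r, c = int(round(K.cy)), int(round(K.cx))
        assert pred.valid_mask[r, c]
        assert pred.depth[r, c] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(pred.color[r, c], [0.2, 0.4, 0.6])
        # disc is local: far corner not covered
        assert not pred.valid_mask[0, 0]

    def test_depth_buffer_nearer_surfel_wins(self):
        m = SurfelMap(K)
        m._insert(
            np.array([[0.0, 0.0, 2.0], [0.0, 0.0, 1.0]]),
            np.tile([0.0, 0.0, -1.0], (2, 1)),
            np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
            np.array([0.02, 0.01]), 0.0,
        )
        m.advance_time(0.0)
        pred = m.predict_view(RigidTransform.identity(), subset="all")
        r, c = int(round(K.cy)), int(round(K.cx))
        assert pred.depth[r, c] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(pred.color[r, c], [0.0, 1.0, 0.0])
        assert pred.index[r, c] == 1

    def test_depth_buffer_minimality_brute_force(self):
        # every rendered depth is <= the centre depth of any surfel that
        # could splat to that pixel (checked exhaustively on a small map)
        rng = np.random.default_rng(1)
        m = SurfelMap(K)
        pts = np.stack(
            [rng.uniform(-0.3, 0.3, 50), rng.uniform(-0.3, 0.3, 50),
             rng.uniform(0.8, 1.5, 50)], axis=1,
        )
        nrm = np.tile([0.0, 0.0, -1.0], (50, 1))
        m._insert(pts, nrm, np.full((50, 3), 0.5), np.full(50, 0.02), 0.0)
        m.advance_time(0.0)
        pred = m.predict_view(RigidTransform.identity(), subset="all")
        for i in range(50):
            u = K.fx * pts[i, 0] / pts[i, 2] + K.cx
            v = K.fy * pts[i, 1] / pts[i, 2] + K.cy
            r, c = int(round(v)), int(round(u))
            if 0 <= r < K.height and 0 <= c < K.width and pred.valid_mask[r, c]:
                # fronto-parallel normals: plane depth == centre depth
                assert pred.depth[r, c] <= pts[i, 2] + 1e-9

    def test_empty_subset_gives_invalid_prediction(self):
        m = SurfelMap(K)
        pred = m.predict_view(RigidTransform.identity(), subset="inactive")
        assert not pred.valid_mask.any()

    def test_fuse_then_predict_roundtrip(self, single_frame_seq):
        seq = single_frame_seq
        m = SurfelMap(seq.intrinsics)
        f = gt_frame(seq)
        m.fuse_frame(f, RigidTransform.identity())
        pred = m.predict_view(RigidTransform.identity(), subset="active")
        both = pred.valid_mask & f.valid_mask
        gap = np.abs(pred.depth[both] - f.depth[both])
        assert (gap < m.depth_gate).mean() >= 0.95


class TestPlyRoundtrip:
    def test_roundtrip_preserves_fields(self, tmp_path):
        rng = np.random.default_rng(5)
        m = SurfelMap(K, delta_t=7.0)
        n = 1000
        nrm = rng.normal(size=(n, 3))
        nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
        m._insert(
            rng.normal(size=(n, 3)), nrm, rng.uniform(size=(n, 3)),
            rng.uniform(0.001, 0.02, n), 0.0,
        )
        m.t_last = rng.uniform(0, 9, n)
        m.weights = rng.uniform(1, 5, n)
        path = tmp_path / "map.ply"
        m.save_ply(path)
        back = SurfelMap.load_ply(path, K)
        for attr in ("positions", "normals", "colors", "weights", "radii", "t_init", "t_last"):
            assert np.abs(getattr(back, attr) - getattr(m, attr)).max() < 1e-6

    def test_empty_map_valid_ply(self, tmp_path):
        m = SurfelMap(K)
        path = tmp_path / "empty.ply"
        m.save_ply(path)
        assert "element vertex 0" in path.read_text()
        back = SurfelMap.load_ply(path, K)
        assert len(back) == 0
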