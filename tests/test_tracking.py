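"""Joint photometric-geometric pose estimation."""

import numpy as np
import pytest

from endofusion.geometry import Intrinsics, RigidTransform, se3_exp
from endofusion.preprocess import Frame, luminance
from endofusion.surfels import compute_normals
from endofusion.tracking import (
    TrackingConfig,
    TrackingLostError,
    estimate_pose,
    icp_residuals,
    prediction_from_frame,
    rgb_residuals,
)

K64 = Intrinsics(fx=55.0, fy=55.0, cx=31.5, cy=31.5, width=64, height=64)


def plane_frame(z=1.0, K=K64, ramp_slope=0.0):
    """Fronto-parallel plane at depth ``z`` with an optional intensity ramp."""
    H, W = K.height, K.width
    depth = np.full((H, W), float(z))
    cols = np.arange(W, dtype=float)
    gray = np.clip(0.5 + ramp_slope * (cols - W / 2), 0, 1) * np.ones((H, 1))
    rgb = np.stack([gray] * 3, axis=-1)
    valid = np.ones((H, W), bool)
    valid[:2] = valid[-2:] = valid[:, :2] = valid[:, -2:] = False
    return Frame(0.0, rgb, gray, depth, valid)


def frame_to_pred(frame, K=K64):
    return prediction_from_frame(frame, K)


class TestIcpResiduals:
    def test_self_alignment_zero(self, single_frame_seq):
        seq = single_frame_seq
        d = seq.ground_truth.depths[0]
        valid = d > 0
        valid[:2] = valid[-2:] = valid[:, :2] = valid[:, -2:] = False
        f = Frame(0.0, seq.images[0], luminance(seq.images[0]), d, valid)
        pred = prediction_from_frame(f, seq.intrinsics)
        fn = compute_normals(d, seq.intrinsics, valid)
        r, J, n = icp_residuals(
            d, valid, fn, pred.depth, pred.valid_mask, pred.normals,
            RigidTransform.identity(), seq.intrinsics, TrackingConfig(),
        )
        assert len(r) > 0
        assert np.abs(r).max() < 1e-9
        assert len(r) <= int(valid.sum())

    def test_plane_translated_along_normal(self):
        f = plane_frame(z=1.0)
        pred = frame_to_pred(f)
        f2 = plane_frame(z=1.01)  # observed 1 cm farther
        fn = compute_normals(f2.depth, K64, f2.valid_mask)
        cfg = TrackingConfig(depth_gate=0.05)  # gate must not eat the gap
        r, _, _ = icp_residuals(
            f2.depth, f2.valid_mask, fn, pred.depth, pred.valid_mask,
            pred.normals, RigidTransform.identity(), K64, cfg,
        )
        assert len(r) > 1000
        # point-to-plane distance is exactly the depth gap; the camera-facing
        # normal convention (n_z < 0) fixes the sign to +0.01
        assert (np.abs(np.abs(r) - 0.01) < 1e-9).mean() > 0.9
        assert np.allclose(np.sign(r[np.abs(r) > 1e-12]), np.sign(r[0]))

    def test_jacobian_matches_numeric(self, single_frame_seq):
        seq = single_frame_seq
        d = seq.ground_truth.depths[0]
        valid = d > 0
        valid[:3] = valid[-3:] = valid[:, :3] = valid[:, -3:] = False
        f = Frame(0.0, seq.images[0], luminance(seq.images[0]), d, valid)
        pred = prediction_from_frame(f, seq.intrinsics)
        fn = compute_normals(d, seq.intrinsics, valid)
        T0 = se3_exp([0.01, -0.02, 0.015, 0.001, -0.002, 0.0015])
        cfg = TrackingConfig()
        r0, J0, _ = icp_residuals(
            d, valid, fn, pred.depth, pred.valid_mask, pred.normals,
            T0, seq.intrinsics, cfg,
        )
        eps = 1e-7
        for j in range(6):
            e = np.zeros(6)
            e[j] = eps
            rp, _, _ = icp_residuals(
                d, valid, fn, pred.depth, pred.valid_mask, pred.normals,
                se3_exp(e) @ T0, seq.intrinsics, cfg, with_jacobian=False,
            )
            if len(rp) != len(r0):
                continue  # association set changed under perturbation
            num = (rp - r0) / eps
            assert np.abs(num - J0[:, j]).max() < 1e-5


class TestRgbResiduals:
    def test_identical_images_zero(self):
        f = plane_frame(ramp_slope=0.004)
        pred = frame_to_pred(f)
        r, _, _ = rgb_residuals(
            f.gray, f.depth, f.valid_mask, pred.gray, pred.valid_mask,
            RigidTransform.identity(), K64,
        )
        assert len(r) > 0 and np.abs(r).max() < 1e-12

    def test_constant_image_uninformative(self):
        f = plane_frame(ramp_slope=0.0)
        pred = frame_to_pred(f)
        T = se3_exp([0, 0, 0, 0.005, 0.0, 0.0])
        r, _, _ = rgb_residuals(
            f.gray, f.depth, f.valid_mask, pred.gray, pred.valid_mask, T, K64
        )
        assert np.abs(r).max() < 1e-12

    def test_ramp_shift_closed_form(self):
        # 1-pixel shift of a linear ramp: slope s per pixel; a lateral
        # translation of z/fx metres warps by exactly one pixel
        s = 0.004
        f = plane_frame(z=1.0, ramp_slope=s)
        pred = frame_to_pred(f)
        shift_one_px = se3_exp([0, 0, 0, 1.0 / K64.fx, 0.0, 0.0])
        shifted_gray = f.gray + s  # a ramp shifted one pixel gains one slope
        r_comp, _, _ = rgb_residuals(
            shifted_gray, f.depth, f.valid_mask, pred.gray, pred.valid_mask,
            shift_one_px, K64,
        )
        r_id, _, _ = rgb_residuals(
            shifted_gray, f.depth, f.valid_mask, pred.gray, pred.valid_mask,
            RigidTransform.identity(), K64,
        )
        # the compensating warp cancels the shift; identity leaves residual s
        assert np.abs(r_comp).max() < 1e-6
        assert np.abs(r_id - s).max() < 1e-6


class TestEstimatePose:
    def test_self_alignment_identity(self, single_frame_seq):
        seq = single_frame_seq
        d = seq.ground_truth.depths[0]
        valid = d > 0
        valid[:2] = valid[-2:] = valid[:, :2] = valid[:, -2:] = False
        f = Frame(0.0, seq.images[0], luminance(seq.images[0]), d, valid)
        pred = prediction_from_frame(f, seq.intrinsics)
        res = estimate_pose(
            f, pred, RigidTransform.identity(), TrackingConfig(), seq.intrinsics
        )
        assert np.linalg.norm(res.pose_update.t) < 1e-6
        assert res.final_energy < 1e-12
        assert res.converged

    def test_pure_icp_matches_standalone_oracle(self):
        """omega=1 reduces to point-to-plane ICP: on analytically exact
        sphere-interior depth images both the projective-association solver
        and an independent closest-point ICP recover the same transform."""
        from endofusion.geometry import back_project_map

        K = K64

        def radius(d):
            """Bumpy star-shaped cavity: radius as a function of direction.
            The relief removes the tangential-sliding gauge of smooth
            point-to-plane alignment."""
            return 0.05 * (
                1.0
                + 0.06 * np.sin(7.0 * d[..., 0])
                + 0.05 * np.cos(6.0 * d[..., 1])
                + 0.06 * np.sin(8.0 * d[..., 2])
            )

        def cavity_depth(pose):
            """Depth image solved per ray by bisection (machine precision)."""
            H, W = K.height, K.width
            cols = np.tile(np.arange(W, dtype=float), (H, 1))
            rows = np.tile(np.arange(H, dtype=float)[:, None], (1, W))
            d_cam = np.stack(
                [(cols - K.cx) / K.fx, (rows - K.cy) / K.fy, np.ones((H, W))],
                axis=-1,
            )
            d_world = d_cam @ pose.R.T
            o = pose.t

            def f(t):
                p = o + t[..., None] * d_world
                n = np.linalg.norm(p, axis=-1)
                return n - radius(p / n[..., None])

            lo = np.full((H, W), 1e-3)
            hi = np.full((H, W), 0.2)
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                pos = f(mid) > 0
                hi = np.where(pos, mid, hi)
                lo = np.where(pos, lo, mid)
            return 0.5 * (lo + hi)  # z in camera frame (d_cam has unit z)

        xi = np.array([0.004, -0.006, 0.003, 0.0012, -0.0009, 0.0015])
        T_pose = se3_exp(xi)  # frame camera pose; prediction at identity
        d0 = cavity_depth(RigidTransform.identity())
        d1 = cavity_depth(T_pose)
        valid = np.ones_like(d0, bool)
        valid[:2] = valid[-2:] = valid[:, :2] = valid[:, -2:] = False
        gray = np.full_like(d0, 0.5)
        rgb = np.stack([gray] * 3, axis=-1)
        pred = prediction_from_frame(Frame(0.0, rgb, gray, d0, valid), K)
        frame = Frame(0.1, rgb, gray, d1, valid.copy())

        cfg = TrackingConfig(
            icp_weight=1.0,
            pyramid_levels=1,
            iterations_per_level=(40,),
            huber_delta_icp=1.0,  # far above any residual: plain least squares
        )
        res = estimate_pose(frame, pred, RigidTransform.identity(), cfg, K)

        # independent oracle: from-scratch projective-association
        # point-to-plane ICP (own GN loop, no robustifier, no pyramid)
        pred_pts = back_project_map(d0, K)
        pred_nrm = compute_normals(d0, K, valid)
        src_all = back_project_map(d1, K)[valid]
        R_o, t_o = np.eye(3), np.zeros(3)
        for _ in range(60):
            cur = src_all @ R_o.T + t_o
            u = np.round(K.fx * cur[:, 0] / cur[:, 2] + K.cx).astype(int)
            v = np.round(K.fy * cur[:, 1] / cur[:, 2] + K.cy).astype(int)
            inb = (u >= 0) & (u < K.width) & (v >= 0) & (v < K.height)
            inb[inb] &= valid[v[inb], u[inb]]
            n = pred_nrm[v[inb], u[inb]]
            tgt = pred_pts[v[inb], u[inb]]
            e = np.einsum("ij,ij->i", n, tgt - cur[inb])
            A = np.concatenate([np.cross(cur[inb], n), n], axis=1)
            delta, *_ = np.linalg.lstsq(A, e, rcond=None)
            dT = se3_exp(delta)
            R_o = dT.R @ R_o
            t_o = dT.R @ t_o + dT.t
            if np.linalg.norm(delta) < 1e-14:
                break

        assert np.linalg.norm(t_o - T_pose.t) < 2e-5  # oracle sanity
        assert np.linalg.norm(res.pose_update.t - t_o) < 1e-6
        assert np.abs(res.pose_update.R - R_o).max() < 1e-5

    def test_recovers_injected_perturbation(self, single_frame_seq):
        from endofusion.synthetic import (
            SyntheticScene,
            _build_cavity,
            _shade,
            _vertex_normals,
            render_view,
        )

        seq = single_frame_seq
        K = seq.intrinsics
        d = seq.ground_truth.depths[0]
        valid = d > 0
        valid[:2] = valid[-2:] = valid[:, :2] = valid[:, -2:] = False
        f = Frame(0.0, seq.images[0], luminance(seq.images[0]), d, valid)
        pred = prediction_from_frame(f, K)

        sc = SyntheticScene(seed=3, n_frames=1)
        rng = np.random.default_rng(sc.seed)
        dirs, faces, radii, albedo, spec, _ = _build_cavity(sc, rng)
        V = dirs * radii[:, None]
        N = _vertex_normals(V, faces)

        trial_rng = np.random.default_rng(11)
        ok = 0
        n_trials = 10
        for _ in range(n_trials):
            t = trial_rng.normal(size=3)
            t *= trial_rng.uniform(0.002, 0.01) / np.linalg.norm(t)
            w = trial_rng.normal(size=3)
            w *= np.radians(trial_rng.uniform(0.5, 2.0)) / np.linalg.norm(w)
            T_pert = se3_exp(np.concatenate([w, t]))
            dep2, attrs, hit = render_view(
                V, faces, {"normal": N, "albedo": albedo, "spec": spec}, T_pert, K
            )
            rgb2, _ = _shade(dep2, attrs, hit, T_pert, K, sc)
            v2 = dep2 > 0
            v2[:2] = v2[-2:] = v2[:, :2] = v2[:, -2:] = False
            f2 = Frame(0.1, rgb2, luminance(rgb2), dep2, v2)
            res = estimate_pose(
                f2, pred, RigidTransform.identity(), TrackingConfig(), K
            )
            rel = np.linalg.norm(res.pose_update.t - T_pert.t) / np.linalg.norm(
                T_pert.t
            )
            ok += rel < 0.10
        assert ok >= 9

    def test_textureless_plane_flags_low_conditioning(self):
        f = plane_frame(ramp_slope=0.0)
        pred = frame_to_pred(f)
        cfg = TrackingConfig(condition_limit=1e5)
        res = estimate_pose(f, pred, RigidTransform.identity(), cfg, K64)
        # in-plane translation unobservable: must be flagged, not asserted
        assert not res.well_conditioned

    def test_tracking_lost_on_disjoint_depth(self):
        f = plane_frame(z=1.0)
        pred_far = frame_to_pred(plane_frame(z=3.0))
        with pytest.raises(TrackingLostError):
            estimate_pose(
                f, pred_far, RigidTransform.identity(), TrackingConfig(), K64
            )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrackingConfig(icp_weight=1.5)
        with pytest.raises(ValueError):
            TrackingConfig(pyramid_levels=2)  # mismatched iteration list
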