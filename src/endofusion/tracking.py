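"""Joint photometric-geometric frame-to-model pose estimation.

Each incoming frame is registered against a splatted prediction of the
active surfel model by minimising, over a twist ``xi``,

    E_track = omega * E_icp + (1 - omega) * E_rgb

where ``E_icp`` is a point-to-plane ICP energy with projective data
association and ``E_rgb`` a direct photometric energy, both Huber-robust,
solved by coarse-to-fine Gauss-Newton with analytic Jacobians.  Writing the
blend as a convex combination makes the ICP-weight sweep a first-class
experiment; ``omega = 0.87`` is the default operating point and
``w_rgb = (1 - omega) / omega`` recovers the conventional two-term form.

Residuals of both terms are pre-scaled by their median absolute value at
the initial pose so the weight ``omega`` blends two dimensionless,
comparably sized energies (depths in metres and intensities in [0, 1]
otherwise live on unrelated scales).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from endofusion.geometry import Intrinsics, RigidTransform, se3_exp
from endofusion.preprocess import Frame
from endofusion.surfels import ModelPrediction, compute_normals

__all__ = [
    "TrackingConfig",
    "TrackingResult",
    "TrackingLostError",
    "icp_residuals",
    "rgb_residuals",
    "estimate_pose",
    "prediction_from_frame",
]


class TrackingLostError(RuntimeError):
    """Raised when too few valid associations remain to estimate a pose."""


@dataclass
class TrackingConfig:
    """Knobs of the joint alignment.

    icp_weight
        The convex blend ``omega`` in [0, 1]: 1 is pure geometric
        (point-to-plane ICP), 0 pure photometric.
    """

    icp_weight: float = 0.87
    pyramid_levels: int = 3
    iterations_per_level: tuple[int, ...] = (10, 5, 4)  # coarse -> fine
    huber_delta_icp: float = 0.003  # metres
    huber_delta_rgb: float = 0.03  # intensity units
    min_valid_fraction: float = 0.05
    depth_gate: float = 0.01  # metres, association compatibility
    normal_gate_deg: float = 30.0
    update_tol: float = 1e-6
    condition_limit: float = 1e7

    def __post_init__(self) -> None:
        if not (0.0 <= self.icp_weight <= 1.0):
            raise ValueError("icp_weight must be in [0, 1]")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if len(self.iterations_per_level) != self.pyramid_levels:
            raise ValueError("iterations_per_level must list one count per level")


@dataclass
class TrackingResult:
    pose_update: RigidTransform
    final_energy: float
    e_icp: float
    e_rgb: float
    inlier_fraction: float
    converged: bool
    iterations_used: int
    well_conditioned: bool = True


def prediction_from_frame(frame: Frame, K: Intrinsics) -> ModelPrediction:
    """View a preprocessed frame as a model prediction (frame-to-frame mode)."""
    valid = frame.valid_mask & (frame.depth > 0)
    normals = compute_normals(frame.depth, K, valid)
    valid = valid & (np.linalg.norm(normals, axis=-1) > 0.5)
    return ModelPrediction(
        depth=np.where(valid, frame.depth, 0.0),
        color=frame.rgb,
        normals=normals,
        valid_mask=valid,
        index=np.where(valid, 0, -1),
    )


# ---------------------------------------------------------------------------
# pyramids
# ---------------------------------------------------------------------------


def _downsample2(img: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 average over valid pixels; a cell is valid if any source pixel is."""
    H, W = valid.shape
    H2, W2 = H // 2, W // 2
    img = img[: 2 * H2, : 2 * W2]
    valid = valid[: 2 * H2, : 2 * W2]
    shape = (H2, 2, W2, 2) + img.shape[2:]
    blocks = img.reshape(shape)
    vblocks = valid.reshape(H2, 2, W2, 2)
    if img.ndim == 3:
        vb = vblocks[..., None]
    else:
        vb = vblocks
    cnt = vblocks.sum(axis=(1, 3))
    s = np.where(vb, blocks, 0.0).sum(axis=(1, 3))
    out_valid = cnt > 0
    if img.ndim == 3:
        out = s / np.maximum(cnt, 1)[..., None]
    else:
        out = s / np.maximum(cnt, 1)
    return out, out_valid


def _frame_pyramid(frame: Frame, K: Intrinsics, levels: int):
    """Fine-to-coarse list of (gray, depth, valid, normals, K)."""
    pyr = []
    gray, depth = frame.gray, frame.depth
    valid = frame.valid_mask & (depth > 0)
    Kl = K
    for lvl in range(levels):
        normals = compute_normals(depth, Kl, valid)
        v = valid & (np.linalg.norm(normals, axis=-1) > 0.5)
        pyr.append((gray, depth, v, normals, Kl))
        if lvl + 1 < levels:
            gray, _ = _downsample2(gray, valid)
            depth, valid = _downsample2(depth, valid)
            Kl = Kl.scaled(0.5)
    return pyr


def _pred_pyramid(pred: ModelPrediction, K: Intrinsics, levels: int):
    pyr = []
    gray, depth, valid, normals = pred.gray, pred.depth, pred.valid_mask, pred.normals
    Kl = K
    for lvl in range(levels):
        n = normals / np.maximum(np.linalg.norm(normals, axis=-1, keepdims=True), 1e-12)
        pyr.append((gray, depth, valid, n, Kl))
        if lvl + 1 < levels:
            gray, _ = _downsample2(gray, valid)
            normals, _ = _downsample2(normals, valid)
            depth, valid = _downsample2(depth, valid)
            Kl = Kl.scaled(0.5)
    return pyr


def _bilinear(img: np.ndarray, u: np.ndarray, v: np.ndarray):
    """Bilinear sample ``img`` at float pixel coords; also returns a mask of
    samples whose four neighbours are all inside the image."""
    H, W = img.shape[:2]
    ok = (u >= 0) & (u <= W - 1 - 1e-9) & (v >= 0) & (v <= H - 1 - 1e-9)
    uc = np.clip(u, 0, W - 1 - 1e-9)
    vc = np.clip(v, 0, H - 1 - 1e-9)
    x0 = np.floor(uc).astype(int)
    y0 = np.floor(vc).astype(int)
    fx = uc - x0
    fy = vc - y0
    w00 = (1 - fx) * (1 - fy)
    w10 = fx * (1 - fy)
    w01 = (1 - fx) * fy
    w11 = fx * fy
    if img.ndim == 3:
        w00, w10, w01, w11 = (w[..., None] for w in (w00, w10, w01, w11))
    val = (
        w00 * img[y0, x0]
        + w10 * img[y0, x0 + 1]
        + w01 * img[y0 + 1, x0]
        + w11 * img[y0 + 1, x0 + 1]
    )
    return val, ok


# ---------------------------------------------------------------------------
# residuals
# ---------------------------------------------------------------------------


def icp_residuals(
    frame_depth: np.ndarray,
    frame_valid: np.ndarray,
    frame_normals: np.ndarray,
    pred_depth: np.ndarray,
    pred_valid: np.ndarray,
    pred_normals: np.ndarray,
    T: RigidTransform,
    K: Intrinsics,
    cfg: TrackingConfig,
    *,
    with_jacobian: bool = True,
):
    """Point-to-plane residuals under projective data association.

    Each valid frame pixel is back-projected, transformed by the current
    estimate ``T`` into the prediction's camera frame, and associated with
    the prediction pixel it projects to.  The residual is
    ``n_hat . (v_hat - T v)`` with ``v_hat``/``n_hat`` the model point and
    normal; pairs failing the depth-gap or normal-angle gate are dropped.

    Returns ``(r, J, n_candidates)`` (``J`` is None without Jacobians).
    """
    rows, cols = np.nonzero(frame_valid)
    n_cand = len(rows)
    if n_cand == 0:
        return np.zeros(0), (np.zeros((0, 6)) if with_jacobian else None), 0
    z = frame_depth[rows, cols]
    v = np.stack(
        [(cols - K.cx) / K.fx * z, (rows - K.cy) / K.fy * z, z], axis=1
    )
    p = T.apply(v)
    front = p[:, 2] > 1e-6
    p, v = p[front], v[front]
    fr, fc = rows[front], cols[front]
    u_proj = K.fx * p[:, 0] / p[:, 2] + K.cx
    v_proj = K.fy * p[:, 1] / p[:, 2] + K.cy
    ui = np.round(u_proj).astype(int)
    vi = np.round(v_proj).astype(int)
    inb = (ui >= 0) & (ui < K.width) & (vi >= 0) & (vi < K.height)
    p, v, fr, fc, ui, vi = p[inb], v[inb], fr[inb], fc[inb], ui[inb], vi[inb]

    assoc_ok = pred_valid[vi, ui]
    vhat_z = pred_depth[vi, ui]
    nhat = pred_normals[vi, ui]
    fnrm = frame_normals[fr, fc] @ T.R.T  # frame normal in prediction frame
    cos_gate = np.cos(np.radians(cfg.normal_gate_deg))
    gates = (
        assoc_ok
        & (np.abs(vhat_z - p[:, 2]) < cfg.depth_gate)
        & (np.einsum("ij,ij->i", nhat, fnrm) > cos_gate)
    )
    p, nhat, ui, vi = p[gates], nhat[gates], ui[gates], vi[gates]
    vhat = np.stack(
        [
            (ui - K.cx) / K.fx * pred_depth[vi, ui],
            (vi - K.cy) / K.fy * pred_depth[vi, ui],
            pred_depth[vi, ui],
        ],
        axis=1,
    )
    r = np.einsum("ij,ij->i", nhat, vhat - p)
    J = None
    if with_jacobian:
        # d r / d(omega, nu) = [ n^T [p]x , -n^T ] = [ (n x p)^T , -n^T ]
        Jw = np.cross(nhat, p)
        J = np.concatenate([Jw, -nhat], axis=1)
    return r, J, n_cand


def rgb_residuals(
    frame_gray: np.ndarray,
    frame_depth: np.ndarray,
    frame_valid: np.ndarray,
    pred_gray: np.ndarray,
    pred_valid: np.ndarray,
    T: RigidTransform,
    K: Intrinsics,
    *,
    with_jacobian: bool = True,
):
    """Direct photometric residuals ``I_frame(u) - I_pred(warp(u))``.

    The warp back-projects each valid frame pixel with its depth, applies
    ``T`` and projects into the prediction; intensity and its gradient are
    sampled bilinearly.  Out-of-bounds or invalid-target warps are dropped.
    """
    rows, cols = np.nonzero(frame_valid)
    n_cand = len(rows)
    if n_cand == 0:
        return np.zeros(0), (np.zeros((0, 6)) if with_jacobian else None), 0
    z = frame_depth[rows, cols]
    v = np.stack([(cols - K.cx) / K.fx * z, (rows - K.cy) / K.fy * z, z], axis=1)
    p = T.apply(v)
    front = p[:, 2] > 1e-6
    p = p[front]
    fr, fc = rows[front], cols[front]
    u_proj = K.fx * p[:, 0] / p[:, 2] + K.cx
    v_proj = K.fy * p[:, 1] / p[:, 2] + K.cy

    Ihat, inb = _bilinear(pred_gray, u_proj, v_proj)
    vmap, _ = _bilinear(pred_valid.astype(float), u_proj, v_proj)
    ok = inb & (vmap > 0.999)
    p, fr, fc = p[ok], fr[ok], fc[ok]
    r = frame_gray[fr, fc] - Ihat[ok]

    J = None
    if with_jacobian:
        gy, gx = np.gradient(pred_gray)
        gxs, _ = _bilinear(gx, u_proj[ok], v_proj[ok])
        gys, _ = _bilinear(gy, u_proj[ok], v_proj[ok])
        z2 = p[:, 2]
        # d pi / d p
        a = K.fx / z2
        b = K.fy / z2
        c = -K.fx * p[:, 0] / z2**2
        d = -K.fy * p[:, 1] / z2**2
        # image gradient chained through the projection
        gpx = gxs * a
        gpy = gys * b
        gpz = gxs * c + gys * d
        g = np.stack([gpx, gpy, gpz], axis=1)  # dI/dp
        # dr/d(omega, nu) = [ -(p x g)^T , -g^T ]
        Jw = np.cross(p, g)
        J = np.concatenate([-Jw, -g], axis=1)
    return r, J, n_cand


# ---------------------------------------------------------------------------
# Gauss-Newton driver
# ---------------------------------------------------------------------------


def _huber_weights(r: np.ndarray, delta: float) -> np.ndarray:
    a = np.abs(r)
    return np.where(a <= delta, 1.0, delta / np.maximum(a, 1e-300))


def _huber_energy(r: np.ndarray, delta: float) -> float:
    a = np.abs(r)
    quad = 0.5 * r**2
    lin = delta * (a - 0.5 * delta)
    return float(np.where(a <= delta, quad, lin).sum())


def estimate_pose(
    frame: Frame,
    pred: ModelPrediction,
    T_init: RigidTransform,
    cfg: TrackingConfig,
    K: Intrinsics,
) -> TrackingResult:
    """Coarse-to-fine Gauss-Newton minimisation of the joint energy.

    Returns the incremental transform taking frame-camera coordinates to
    the prediction's camera frame (compose with the prediction's pose to
    get the new absolute pose).  Raises :class:`TrackingLostError` when
    fewer than ``cfg.min_valid_fraction`` of the frame's valid pixels can
    be associated, or the normal equations are singular.
    """
    omega = cfg.icp_weight
    fpyr = _frame_pyramid(frame, K, cfg.pyramid_levels)
    ppyr = _pred_pyramid(pred, K, cfg.pyramid_levels)

    T = RigidTransform(T_init.R.copy(), T_init.t.copy(), check=False)
    # per-term scales from the finest level at the initial pose: residuals of
    # both terms are divided by their initial median absolute value so that
    # omega blends two dimensionless, comparably-sized energies
    fg0, fd0, fv0, fn0, K0 = fpyr[0]
    pg0, pd0, pv0, pn0, _ = ppyr[0]
    r_c0, _, _ = rgb_residuals(fg0, fd0, fv0, pg0, pv0, T, K0, with_jacobian=False)
    sigma_I = max(float(np.median(np.abs(r_c0))) if len(r_c0) else 0.0, 1e-3)
    r_i0, _, _ = icp_residuals(
        fd0, fv0, fn0, pd0, pv0, pn0, T, K0, cfg, with_jacobian=False
    )
    sigma_D = max(float(np.median(np.abs(r_i0))) if len(r_i0) else 0.0, 1e-3)
    total_iters = 0
    converged = False
    well_conditioned = True
    last_stats = (0.0, 0.0, 0.0, 0.0)  # E, E_icp, E_rgb, inlier_fraction

    def evaluate(level: int, Tcur: RigidTransform, with_jac: bool):
        fg, fd, fv, fn, Kl = fpyr[level]
        pg, pd, pv, pn, _ = ppyr[level]
        r_i, J_i, n_i = icp_residuals(
            fd, fv, fn, pd, pv, pn, Tcur, Kl, cfg, with_jacobian=with_jac
        )
        r_c, J_c, n_c = rgb_residuals(
            fg, fd, fv, pg, pv, Tcur, Kl, with_jacobian=with_jac
        )
        r_c = r_c / sigma_I
        if J_c is not None:
            J_c = J_c / sigma_I
        r_i = r_i / sigma_D
        if J_i is not None:
            J_i = J_i / sigma_D
        n_frame = max(int(fv.sum()), 1)
        frac = (len(r_i) if omega > 0 else len(r_c)) / n_frame
        if frac < cfg.min_valid_fraction:
            raise TrackingLostError(
                f"only {frac:.1%} of pixels associated at pyramid level {level}"
            )
        return r_i, J_i, r_c, J_c, frac

    for level in range(cfg.pyramid_levels - 1, -1, -1):
        lam = 0.0
        bad_steps = 0
        for _ in range(cfg.iterations_per_level[level]):
            r_i, J_i, r_c, J_c, frac = evaluate(level, T, True)
            w_i = _huber_weights(r_i, cfg.huber_delta_icp / sigma_D)
            w_c = _huber_weights(r_c, cfg.huber_delta_rgb / sigma_I)
            n_i = max(len(r_i), 1)
            n_c = max(len(r_c), 1)
            E_icp = _huber_energy(r_i, cfg.huber_delta_icp / sigma_D) / n_i
            E_rgb = _huber_energy(r_c, cfg.huber_delta_rgb / sigma_I) / n_c
            E = omega * E_icp + (1 - omega) * E_rgb
            last_stats = (E, E_icp, E_rgb, frac)

            H = np.zeros((6, 6))
            g = np.zeros(6)
            if omega > 0 and len(r_i):
                Jw = J_i * w_i[:, None]
                H += omega / n_i * (Jw.T @ J_i)
                g += omega / n_i * (Jw.T @ r_i)
            if omega < 1 and len(r_c):
                Jw = J_c * w_c[:, None]
                H += (1 - omega) / n_c * (Jw.T @ J_c)
                g += (1 - omega) / n_c * (Jw.T @ r_c)

            evals = np.linalg.eigvalsh(H)
            if evals[-1] <= 0 or not np.isfinite(evals).all():
                raise TrackingLostError("singular normal equations")
            if evals[0] <= 0 or evals[-1] / max(evals[0], 1e-300) > cfg.condition_limit:
                well_conditioned = False

            try:
                delta = np.linalg.solve(
                    H + lam * np.diag(np.diag(H)) + 1e-12 * np.eye(6), -g
                )
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise TrackingLostError("singular normal equations") from exc
            # trust region: a direct method only holds near the optimum
            rot_n = np.linalg.norm(delta[:3])
            tr_n = np.linalg.norm(delta[3:])
            scale = min(1.0, 0.3 / max(rot_n, 1e-12), 0.05 / max(tr_n, 1e-12))
            delta = delta * scale
            T_new = se3_exp(delta) @ T
            total_iters += 1

            # accept only energy-decreasing steps; damp otherwise (a step
            # that destroys the association is likewise rejected)
            try:
                r_i2, _, r_c2, _, _ = evaluate(level, T_new, False)
                E2 = omega * _huber_energy(r_i2, cfg.huber_delta_icp / sigma_D) / max(
                    len(r_i2), 1
                ) + (1 - omega) * _huber_energy(
                    r_c2, cfg.huber_delta_rgb / sigma_I
                ) / max(len(r_c2), 1)
            except TrackingLostError:
                E2 = np.inf
            if E2 <= E + 1e-15:
                T = T_new
                lam = max(lam / 4.0, 0.0)
                bad_steps = 0
                if np.linalg.norm(delta) < cfg.update_tol:
                    converged = True
                    break
            else:
                lam = 10.0 * lam if lam > 0 else 1e-3
                bad_steps += 1
                if bad_steps >= 3:
                    break

    # converged: the update dropped below tolerance, or the finest level
    # used its full budget of accepted (energy-decreasing) steps — only an
    # abort on consecutive rejected steps counts as non-convergence
    if not converged:
        converged = bad_steps < 3

    E, E_icp, E_rgb, frac = last_stats
    return TrackingResult(
        pose_update=T,
        final_energy=E,
        e_icp=E_icp,
        e_rgb=E_rgb,
        inlier_fraction=frac,
        converged=converged,
        iterations_used=total_iters,
        well_conditioned=well_conditioned,
    )
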