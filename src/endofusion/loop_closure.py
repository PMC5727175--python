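"""Loop closure: revisit detection, active-to-inactive registration, fusion.

When the camera re-enters surface that aged out of the active window, the
inactive model becomes visible in the current frustum.  Closure proceeds in
three steps:

1. *detect* — splat the inactive model at the current pose and measure its
   valid-pixel overlap with the frame;
2. *register* — run the joint photometric-geometric alignment of the
   tracking module with the active prediction as the "frame" and the
   inactive prediction as the model, yielding a relative transform
   (active -> inactive) plus surface constraints sampled from inlier
   correspondences;
3. *apply* — optimise the deformation graph under those constraints, warp
   every surfel, reactivate the inactive surfels that fell inside the
   registered view, and hand the pose correction back to the pipeline.

There is no pose graph: global consistency comes only from the deformation
graph, and drift accumulated since the surface was last seen is absorbed
non-rigidly into the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from endofusion.geometry import Intrinsics, RigidTransform
from endofusion.preprocess import Frame
from endofusion.surfels import ModelPrediction, SurfelMap
from endofusion.deformation import (
    DeformationGraph,
    SurfaceConstraint,
    deform_points,
    optimize_graph,
)
from endofusion.tracking import (
    TrackingConfig,
    TrackingLostError,
    estimate_pose,
    icp_residuals,
)

__all__ = [
    "LoopClosureConfig",
    "RegistrationResult",
    "detect_loop_candidate",
    "register_active_to_inactive",
    "apply_loop_closure",
]


@dataclass
class LoopClosureConfig:
    """Thresholds of the closure decision chain."""

    min_overlap: float = 0.3  # fraction of valid frame pixels
    max_residual_rms: float = 0.005  # metres
    min_inlier_fraction: float = 0.6
    constraint_stride: int = 8  # pixel grid stride for constraint sampling
    #: tracking configuration used for the registration step
    tracking: TrackingConfig = field(
        default_factory=lambda: TrackingConfig(min_valid_fraction=0.02)
    )


@dataclass
class RegistrationResult:
    relative_transform: RigidTransform  # active -> inactive (camera frame)
    residual_rms: float
    inlier_fraction: float
    constraints: list[SurfaceConstraint]
    accepted: bool


def detect_loop_candidate(
    surfel_map: SurfelMap,
    frame: Frame,
    pose: RigidTransform,
    cfg: LoopClosureConfig,
) -> ModelPrediction | None:
    """Splat the inactive model at ``pose``; a candidate exists when its
    valid pixels cover more than ``cfg.min_overlap`` of the frame's valid
    domain.  Returns the inactive prediction, or None."""
    if not surfel_map.inactive_mask.any():
        return None
    pred = surfel_map.predict_view(pose, subset="inactive")
    fv = frame.valid_mask & (frame.depth > 0)
    denom = max(int(fv.sum()), 1)
    overlap = float((pred.valid_mask & fv).sum()) / denom
    if overlap < cfg.min_overlap:
        return None
    return pred


def _prediction_as_frame(pred: ModelPrediction, timestamp: float) -> Frame:
    from endofusion.preprocess import luminance

    return Frame(
        timestamp=timestamp,
        rgb=pred.color,
        gray=luminance(pred.color),
        depth=pred.depth,
        valid_mask=pred.valid_mask,
    )


def _coarse_align(
    active_pred: ModelPrediction,
    inactive_pred: ModelPrediction,
    K: Intrinsics,
    *,
    stride: int = 2,
    iterations: int = 20,
) -> RigidTransform:
    """Translation-only closest-point ICP between the two predictions.

    Projective association cannot bootstrap a registration across the large
    drift a loop closure must absorb.  The coarse stage estimates only a
    translation: on the smooth, near-spherical cavity geometry a full rigid
    closest-point ICP slides along the rotational near-symmetry, whereas
    translation is well constrained; rotation is left to the dense joint
    refinement where the texture pins it.
    """
    from scipy.spatial import cKDTree

    from endofusion.geometry import back_project_map

    def cloud(pred):
        pts = back_project_map(np.where(pred.valid_mask, pred.depth, 1.0), K)
        return pts[pred.valid_mask][::stride]

    src = cloud(active_pred)
    dst = cloud(inactive_pred)
    if len(src) < 10 or len(dst) < 10:
        return RigidTransform.identity()
    tree = cKDTree(dst)
    t_tot = np.zeros(3)
    for _ in range(iterations):
        cur = src + t_tot
        d, j = tree.query(cur)
        gate = 3.0 * max(np.median(d), 1e-6)
        keep = d < gate
        if keep.sum() < 10:
            break
        step = (dst[j[keep]] - cur[keep]).mean(axis=0)
        t_tot = t_tot + step
        if np.linalg.norm(step) < 1e-9:
            break
    return RigidTransform(np.eye(3), t_tot, check=False)


def register_active_to_inactive(
    active_pred: ModelPrediction,
    inactive_pred: ModelPrediction,
    pose: RigidTransform,
    K: Intrinsics,
    cfg: LoopClosureConfig,
) -> RegistrationResult:
    """Register the active model to the inactive model in the current view.

    Both inputs are predictions rendered at ``pose``; the estimated
    ``relative_transform`` maps active-model camera points onto the
    inactive model.  Surface constraints are sampled on a uniform pixel
    grid over inlier correspondences, with source/target expressed in world
    coordinates via ``pose``.
    """
    reject = RegistrationResult(
        RigidTransform.identity(), np.inf, 0.0, [], accepted=False
    )
    frame = _prediction_as_frame(active_pred, timestamp=0.0)
    # two starts (identity, translation-only coarse ICP); keep the lower
    # final energy — wide-baseline registration has real local minima
    inits = [RigidTransform.identity(), _coarse_align(active_pred, inactive_pred, K)]
    result = None
    for T_init in inits:
        try:
            cand = estimate_pose(frame, inactive_pred, T_init, cfg.tracking, K)
        except TrackingLostError:
            continue
        if result is None or cand.final_energy < result.final_energy:
            result = cand
    if result is None:
        return reject
    T_rel = result.pose_update

    # evaluate registration quality on point-to-plane residuals at T_rel
    from endofusion.surfels import compute_normals

    fv = active_pred.valid_mask
    fn = compute_normals(active_pred.depth, K, fv)
    r, _, n_cand = icp_residuals(
        active_pred.depth,
        fv,
        fn,
        inactive_pred.depth,
        inactive_pred.valid_mask,
        inactive_pred.normals,
        T_rel,
        K,
        cfg.tracking,
        with_jacobian=False,
    )
    if n_cand == 0 or len(r) == 0:
        return reject
    rms = float(np.sqrt(np.mean(r**2)))
    # inliers measured against attempted correspondences: active pixels
    # whose warped projection lands on valid inactive coverage
    rows, cols = np.nonzero(fv)
    z = active_pred.depth[rows, cols]
    pts = np.stack(
        [(cols - K.cx) / K.fx * z, (rows - K.cy) / K.fy * z, z], axis=1
    )
    p = T_rel.apply(pts)
    ok = p[:, 2] > 1e-6
    u = np.round(K.fx * p[ok, 0] / p[ok, 2] + K.cx).astype(int)
    v = np.round(K.fy * p[ok, 1] / p[ok, 2] + K.cy).astype(int)
    inb = (u >= 0) & (u < K.width) & (v >= 0) & (v < K.height)
    attempted = int(inactive_pred.valid_mask[v[inb], u[inb]].sum())
    inlier_fraction = len(r) / max(attempted, 1)
    accepted = (rms < cfg.max_residual_rms) and (
        inlier_fraction > cfg.min_inlier_fraction
    )

    constraints: list[SurfaceConstraint] = []
    if accepted:
        stride = cfg.constraint_stride
        H, W = fv.shape
        rows, cols = np.meshgrid(
            np.arange(0, H, stride), np.arange(0, W, stride), indexing="ij"
        )
        rows, cols = rows.ravel(), cols.ravel()
        keep = fv[rows, cols]
        r_a, c_a = rows[keep], cols[keep]
        z = active_pred.depth[r_a, c_a]
        pts_cam = np.stack(
            [(c_a - K.cx) / K.fx * z, (r_a - K.cy) / K.fy * z, z], axis=1
        )
        src_world = pose.apply(pts_cam)
        tgt_world = pose.apply(T_rel.apply(pts_cam))
        constraints = [
            SurfaceConstraint(s, t) for s, t in zip(src_world, tgt_world)
        ]
    return RegistrationResult(
        relative_transform=T_rel,
        residual_rms=rms,
        inlier_fraction=inlier_fraction,
        constraints=constraints,
        accepted=accepted,
    )


def apply_loop_closure(
    surfel_map: SurfelMap,
    graph: DeformationGraph,
    reg: RegistrationResult,
    pose: RigidTransform,
    now: float,
    *,
    graph_weights: tuple[float, float, float] = (1.0, 10.0, 100.0),
) -> tuple[DeformationGraph, RigidTransform, dict]:
    """Warp the map under the registration constraints and reactivate.

    Optimises the graph with ``reg.constraints``, deforms every surfel
    (positions and normals) in place, stamps ``t_last = now`` on inactive
    surfels visible in the registered view (reactivation), and returns the
    updated graph, the corrected camera pose ``pose @ T_rel`` and an info
    dict.  Surfel count never changes here.  On optimisation failure the
    map is left untouched.
    """
    if not reg.accepted:
        raise ValueError("cannot apply a rejected registration")
    w_rot, w_reg, w_con = graph_weights
    try:
        new_graph, info = optimize_graph(
            graph, reg.constraints, w_rot=w_rot, w_reg=w_reg, w_con=w_con
        )
    except np.linalg.LinAlgError:
        return graph, pose, {"applied": False, "reason": "graph optimisation failed"}

    # only the active (recent, drift-carrying) surface is warped; the
    # inactive model is the reference the registration aligned to
    act = surfel_map.active_mask
    pos, nrm = deform_points(
        surfel_map.positions[act], new_graph, surfel_map.normals[act]
    )
    surfel_map.positions[act] = pos
    surfel_map.normals[act] = nrm

    corrected = pose @ reg.relative_transform

    # reactivate inactive surfels now visible in the corrected view
    K = surfel_map.K
    inact = np.nonzero(surfel_map.inactive_mask)[0]
    if len(inact):
        p_cam = corrected.inverse().apply(surfel_map.positions[inact])
        z = p_cam[:, 2]
        front = z > 1e-4
        u = K.fx * p_cam[front, 0] / z[front] + K.cx
        v = K.fy * p_cam[front, 1] / z[front] + K.cy
        inview = (u >= 0) & (u <= K.width - 1) & (v >= 0) & (v <= K.height - 1)
        surfel_map.t_last[inact[front][inview]] = now
    surfel_map.advance_time(max(now, surfel_map.current_time))

    info = dict(info)
    info["applied"] = True
    info["n_reactivated"] = int(len(inact[front][inview])) if len(inact) else 0
    return new_graph, corrected, info
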