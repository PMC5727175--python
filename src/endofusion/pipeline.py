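"""The per-frame SLAM loop: preprocess, track, fuse, close loops.

For every frame the pipeline (i) creates a depth image (shape-from-shading,
or ground-truth depth in oracle mode), (ii) estimates the pose against a
splatted prediction of the active model (or the previous frame, per the
ablation mode), (iii) fuses the frame into the surfel map and refreshes the
active/inactive partition, and (iv) when enabled, attempts loop closure
against the inactive model.  Runs are deterministic given the config.

Tracking failure stops the run (no relocalisation); the failure frame index
is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from endofusion.config import RunConfig
from endofusion.geometry import RigidTransform, se3_exp
from endofusion.io import Trajectory
from endofusion.loop_closure import (
    apply_loop_closure,
    detect_loop_candidate,
    register_active_to_inactive,
)
from endofusion.deformation import build_graph
from endofusion.preprocess import Frame, luminance, preprocess_frame
from endofusion.surfels import SurfelMap
from endofusion.tracking import (
    TrackingConfig,
    TrackingLostError,
    estimate_pose,
    prediction_from_frame,
)

__all__ = ["SlamResult", "run_slam", "run_slam_arrays"]


@dataclass
class SlamResult:
    trajectory: Trajectory
    surfel_map: SurfelMap
    log: list[dict] = field(default_factory=list)
    closure_events: list[dict] = field(default_factory=list)
    failed_at: int | None = None  # frame index of tracking loss, if any

    @property
    def completed(self) -> bool:
        return self.failed_at is None

    @property
    def converged_fraction(self) -> float:
        tracked = [rec for rec in self.log if "converged" in rec]
        if not tracked:
            return 1.0
        return sum(rec["converged"] for rec in tracked) / len(tracked)


def _make_frame(
    rgb: np.ndarray, timestamp: float, cfg: RunConfig, depth: np.ndarray | None
) -> Frame:
    if cfg.depth_source == "ground_truth":
        if depth is None:
            raise ValueError("depth_source=ground_truth but no depth provided")
        valid = depth > 0
        m = cfg.border_margin
        if m > 0:
            valid = valid.copy()
            valid[:m, :] = valid[-m:, :] = False
            valid[:, :m] = valid[:, -m:] = False
        return Frame(timestamp, rgb, luminance(rgb), depth, valid)
    return preprocess_frame(
        rgb, timestamp, cfg.shading, border_margin=cfg.border_margin
    )


def run_slam_arrays(
    timestamps: np.ndarray,
    images: list[np.ndarray],
    config: RunConfig,
    *,
    depths: list[np.ndarray] | None = None,
) -> SlamResult:
    """Run the full pipeline on in-memory frames.

    ``depths`` supplies per-frame metric depth for the ground-truth depth
    mode (renderer output or decoded depth PNGs).
    """
    cfg = config
    K = cfg.intrinsics
    if K is None:
        raise ValueError("config.intrinsics is required")
    track_cfg = cfg.tracking
    if cfg.ablation_mode == "rgb_only":
        track_cfg = TrackingConfig(
            **{**track_cfg.__dict__, "icp_weight": 0.0}
        )

    surfel_map = SurfelMap(
        K,
        delta_t=cfg.delta_t,
        depth_gate=cfg.depth_gate,
        normal_gate_deg=cfg.normal_gate_deg,
    )
    graph = None
    pose = RigidTransform.identity()
    drift = se3_exp(np.asarray(cfg.inject_drift)) if cfg.inject_drift else None

    est_t: list[float] = []
    est_poses: list[RigidTransform] = []
    log: list[dict] = []
    closures: list[dict] = []
    failed_at = None
    prev_frame: Frame | None = None
    cooldown = 0

    for i, (t, rgb) in enumerate(zip(timestamps, images)):
        frame = _make_frame(rgb, float(t), cfg, depths[i] if depths else None)
        rec: dict = {"frame": i, "timestamp": float(t)}
        if i == 0:
            surfel_map.fuse_frame(frame, pose)
        else:
            try:
                if cfg.ablation_mode == "frame2frame":
                    pred = prediction_from_frame(prev_frame, K)
                else:
                    pred = surfel_map.predict_view(pose, subset="active")
                result = estimate_pose(
                    frame, pred, RigidTransform.identity(), track_cfg, K
                )
            except TrackingLostError as exc:
                failed_at = i
                rec["error"] = str(exc)
                log.append(rec)
                break
            pose = pose @ result.pose_update
            if drift is not None and (
                cfg.inject_drift_at is None or i == cfg.inject_drift_at
            ):
                pose = pose @ drift
            rec.update(
                converged=result.converged,
                energy=result.final_energy,
                e_icp=result.e_icp,
                e_rgb=result.e_rgb,
                inliers=result.inlier_fraction,
                well_conditioned=result.well_conditioned,
            )
            surfel_map.fuse_frame(frame, pose)
        surfel_map.advance_time(float(t))

        # ---- loop closure ----
        if (
            cfg.loop_closure
            and i > 0
            and cooldown == 0
            and i % cfg.closure_interval == 0
            and surfel_map.inactive_mask.any()
        ):
            inactive_pred = detect_loop_candidate(surfel_map, frame, pose, cfg.loop)
            if inactive_pred is not None:
                active_pred = surfel_map.predict_view(pose, subset="active")
                reg = register_active_to_inactive(
                    active_pred, inactive_pred, pose, K, cfg.loop
                )
                if reg.accepted and reg.constraints:
                    # the graph is rebuilt over the current surfels at each
                    # closure so node coverage follows the grown map
                    try:
                        graph = build_graph(
                            surfel_map,
                            node_count=min(
                                cfg.graph_node_count,
                                int(surfel_map.active_mask.sum()),
                            ),
                            k=cfg.graph_k,
                            mask=surfel_map.active_mask,
                        )
                    except ValueError:
                        graph = None
                    if graph is not None:
                        graph, corrected, info = apply_loop_closure(
                            surfel_map,
                            graph,
                            reg,
                            pose,
                            float(t),
                            graph_weights=cfg.graph_weights,
                        )
                        if cfg.use_corrected_pose:
                            pose = corrected
                        cooldown = cfg.closure_cooldown
                        closures.append(
                            {
                                "frame": i,
                                "residual_rms": reg.residual_rms,
                                "inlier_fraction": reg.inlier_fraction,
                                "n_constraints": len(reg.constraints),
                                **{
                                    k: v
                                    for k, v in info.items()
                                    if k in ("applied", "n_reactivated", "constraint_rms")
                                },
                            }
                        )
        cooldown = max(cooldown - 1, 0)

        rec.update(
            surfels=len(surfel_map),
            active_fraction=float(surfel_map.active_mask.mean())
            if len(surfel_map)
            else 0.0,
        )
        log.append(rec)
        est_t.append(float(t))
        est_poses.append(RigidTransform(pose.R.copy(), pose.t.copy(), check=False))
        prev_frame = frame

    return SlamResult(
        trajectory=Trajectory(np.array(est_t), est_poses),
        surfel_map=surfel_map,
        log=log,
        closure_events=closures,
        failed_at=failed_at,
    )


def run_slam(sequence_dir, config: RunConfig) -> SlamResult:
    """Run the pipeline on a directory of PNG/JPEG frames.

    Ground-truth depth mode reads ``depth_*.png`` companions (16-bit,
    0.1 mm units) from the same directory.
    """
    import os

    from endofusion.io import read_depth_png, read_image_sequence

    timestamps, images = read_image_sequence(sequence_dir)
    depths = None
    if config.depth_source == "ground_truth":
        depth_files = sorted(
            f for f in os.listdir(sequence_dir) if f.startswith("depth_")
        )
        if len(depth_files) != len(images):
            raise ValueError("depth_*.png count does not match frame count")
        depths = [
            read_depth_png(os.path.join(sequence_dir, f)) for f in depth_files
        ]
    return run_slam_arrays(timestamps, images, config, depths=depths)
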