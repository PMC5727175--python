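"""Shared fixtures: rendered synthetic sequences are expensive enough to
build once per session and reuse across test modules."""

from __future__ import annotations

import pytest

from endofusion.config import RunConfig
from endofusion.io import Trajectory
from endofusion.pipeline import run_slam_arrays
from endofusion.synthetic import (
    SyntheticScene,
    render_sequence,
    standard_fixtures,
)
from endofusion.tracking import TrackingConfig


@pytest.fixture(scope="session")
def slow_seq():
    return render_sequence(standard_fixtures()["SLOW_SCAN"])


@pytest.fixture(scope="session")
def loopy_seq():
    return render_sequence(standard_fixtures()["LOOPY"])


@pytest.fixture(scope="session")
def single_frame_seq():
    """One rendered cavity frame with ground truth (cheap tracking target)."""
    return render_sequence(SyntheticScene(seed=3, n_frames=1))


@pytest.fixture(scope="session")
def slow_gt(slow_seq):
    return Trajectory(slow_seq.timestamps, slow_seq.ground_truth.poses)


@pytest.fixture(scope="session")
def loopy_gt(loopy_seq):
    return Trajectory(loopy_seq.timestamps, loopy_seq.ground_truth.poses)


def shading_run_config(seq, mode="frame2model", omega=None):
    """The standard configuration for full (shading-depth) synthetic runs:
    association gates widened to match shading-depth noise."""
    tracking = TrackingConfig(depth_gate=0.02)
    if omega is not None:
        tracking = TrackingConfig(depth_gate=0.02, icp_weight=omega)
    return RunConfig(
        intrinsics=seq.intrinsics,
        depth_source="shading",
        loop_closure=False,
        ablation_mode=mode,
        depth_gate=0.02,
        normal_gate_deg=30,
        tracking=tracking,
    )


@pytest.fixture(scope="session")
def slow_shading_result(slow_seq):
    """Full-pipeline (shape-from-shading depth) run on SLOW_SCAN, reused by
    the completion, accuracy and ablation checks."""
    cfg = shading_run_config(slow_seq)
    return run_slam_arrays(slow_seq.timestamps, slow_seq.images, cfg)
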