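"""Run configuration: one validated object bundling every module's knobs.

Configs load from YAML (or a plain dict); unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import yaml

from endofusion.geometry import Intrinsics
from endofusion.loop_closure import LoopClosureConfig
from endofusion.preprocess import ShadingParams
from endofusion.tracking import TrackingConfig

__all__ = ["RunConfig", "load_config"]

ABLATION_MODES = ("frame2model", "frame2frame", "rgb_only")
DEPTH_SOURCES = ("shading", "ground_truth")


@dataclass
class RunConfig:
    """Everything a SLAM run needs besides the frames themselves."""

    intrinsics: Intrinsics | None = None
    shading: ShadingParams = field(default_factory=ShadingParams)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    loop: LoopClosureConfig = field(default_factory=LoopClosureConfig)
    seed: int = 0
    #: pose-estimation strategy (the rgb_only mode drops the geometric term)
    ablation_mode: str = "frame2model"
    depth_source: str = "shading"
    loop_closure: bool = True
    #: frames between loop-closure detection attempts
    closure_interval: int = 1
    #: after an accepted closure, detection pauses this many frames
    closure_cooldown: int = 20
    #: corrected pose seeds the next frame's tracking
    use_corrected_pose: bool = True
    #: surfel map parameters
    delta_t: float = 10.0
    depth_gate: float = 0.005
    normal_gate_deg: float = 20.0
    #: deformation graph parameters
    graph_node_count: int = 32
    graph_k: int = 4
    graph_weights: tuple[float, float, float] = (1.0, 10.0, 100.0)
    #: twist bias for drift-injection experiments (6 floats or None); applied
    #: every frame, or once at ``inject_drift_at`` when that is set
    inject_drift: tuple[float, ...] | None = None
    inject_drift_at: int | None = None
    #: border margin excluded from the valid pixel domain
    border_margin: int = 2

    def __post_init__(self) -> None:
        if self.ablation_mode not in ABLATION_MODES:
            raise ValueError(f"ablation_mode must be one of {ABLATION_MODES}")
        if self.depth_source not in DEPTH_SOURCES:
            raise ValueError(f"depth_source must be one of {DEPTH_SOURCES}")
        if self.inject_drift is not None:
            self.inject_drift = tuple(float(v) for v in self.inject_drift)
            if len(self.inject_drift) != 6:
                raise ValueError("inject_drift must have 6 components")

    @staticmethod
    def from_dict(d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in fields(RunConfig)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "intrinsics" in d and isinstance(d["intrinsics"], dict):
            d["intrinsics"] = Intrinsics.from_dict(d["intrinsics"])
        for key, cls in (
            ("shading", ShadingParams),
            ("tracking", TrackingConfig),
            ("loop", LoopClosureConfig),
        ):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                sub_known = {f.name for f in fields(cls)}
                sub_unknown = set(sub) - sub_known
                if sub_unknown:
                    raise ValueError(
                        f"unknown {key} config keys: {sorted(sub_unknown)}"
                    )
                if key == "shading" and "light_direction" in sub:
                    sub["light_direction"] = np.asarray(sub["light_direction"], float)
                if key == "tracking" and "iterations_per_level" in sub:
                    sub["iterations_per_level"] = tuple(sub["iterations_per_level"])
                if key == "loop" and "tracking" in sub and isinstance(sub["tracking"], dict):
                    sub["tracking"] = TrackingConfig(**sub["tracking"])
                d[key] = cls(**sub)
        if "graph_weights" in d:
            d["graph_weights"] = tuple(d["graph_weights"])
        return RunConfig(**d)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)
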