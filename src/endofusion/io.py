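"""File I/O: TUM trajectories, PNG sequences, depth images, run configs.

The TUM trajectory format is one pose per line,
``timestamp tx ty tz qx qy qz qw`` (quaternion scalar-last), the only place
where rotations leave their matrix form.  Depth images are stored as 16-bit
PNG with 0.1 mm per unit (value = metres * 10000); zero means no depth.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from scipy.spatial.transform import Rotation

from endofusion.geometry import RigidTransform

__all__ = [
    "Trajectory",
    "read_tum",
    "write_tum",
    "read_image_sequence",
    "write_image_sequence",
    "read_depth_png",
    "write_depth_png",
]

DEPTH_PNG_SCALE = 10000.0  # units per metre (0.1 mm resolution)


@dataclass
class Trajectory:
    """Ordered (timestamp, pose) pairs with strictly increasing timestamps."""

    timestamps: np.ndarray  # (N,)
    poses: list[RigidTransform]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if len(self.timestamps) != len(self.poses):
            raise ValueError("timestamp/pose count mismatch")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.poses)

    def positions(self) -> np.ndarray:
        return np.array([p.t for p in self.poses])


def write_tum(traj: Trajectory, path) -> None:
    with open(path, "w") as fh:
        for t, pose in zip(traj.timestamps, traj.poses):
            q = Rotation.from_matrix(pose.R).as_quat()  # (x, y, z, w)
            tx, ty, tz = pose.t
            fh.write(
                f"{t:.9f} {tx:.9f} {ty:.9f} {tz:.9f} "
                f"{q[0]:.9f} {q[1]:.9f} {q[2]:.9f} {q[3]:.9f}\n"
            )


def read_tum(path) -> Trajectory:
    timestamps = []
    poses = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 8:
                raise ValueError(
                    f"{path}:{lineno}: expected 8 fields, got {len(parts)}"
                )
            try:
                vals = [float(p) for p in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
            t, tx, ty, tz, qx, qy, qz, qw = vals
            R = Rotation.from_quat([qx, qy, qz, qw]).as_matrix()
            timestamps.append(t)
            poses.append(RigidTransform(R, [tx, ty, tz]))
    return Trajectory(np.array(timestamps), poses)


_NUM_RE = re.compile(r"(\d+(?:\.\d+)?)")


def read_image_sequence(directory):
    """Read a directory of PNG/JPEG frames sorted by filename.

    Timestamps come from an ``index.txt`` two-column file (name, seconds) if
    present, else from the first number in each filename, else the frame
    index.  Returns ``(timestamps, images)`` with images as float arrays in
    [0, 1].
    """
    names = sorted(
        f
        for f in os.listdir(directory)
        if f.lower().endswith((".png", ".jpg", ".jpeg"))
        and not f.startswith("depth_")
    )
    if not names:
        raise FileNotFoundError(f"no image frames found in {directory}")
    index_path = os.path.join(directory, "index.txt")
    stamps: dict[str, float] = {}
    if os.path.exists(index_path):
        with open(index_path) as fh:
            for line in fh:
                if line.strip():
                    name, sec = line.split()
                    stamps[name] = float(sec)
    timestamps = []
    images = []
    for i, name in enumerate(names):
        if name in stamps:
            t = stamps[name]
        else:
            m = _NUM_RE.search(name)
            t = float(m.group(1)) if m else float(i)
        img = np.asarray(iio.imread(os.path.join(directory, name)), dtype=float)
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        timestamps.append(t)
        images.append(img[..., :3] / 255.0)
    return np.array(timestamps), images


def write_image_sequence(directory, timestamps, images, *, depths=None) -> None:
    """Write frames (and optional depth maps) as PNGs plus an index file."""
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "index.txt"), "w") as fh:
        for i, t in enumerate(timestamps):
            name = f"frame_{i:05d}.png"
            iio.imwrite(
                os.path.join(directory, name),
                (np.clip(images[i], 0, 1) * 255).round().astype(np.uint8),
            )
            if depths is not None:
                write_depth_png(
                    os.path.join(directory, f"depth_{i:05d}.png"), depths[i]
                )
            fh.write(f"{name} {t:.9f}\n")


def write_depth_png(path, depth) -> None:
    iio.imwrite(
        path,
        np.clip(np.asarray(depth) * DEPTH_PNG_SCALE, 0, 65535)
        .round()
        .astype(np.uint16),
    )


def read_depth_png(path) -> np.ndarray:
    return np.asarray(iio.imread(path), dtype=float) / DEPTH_PNG_SCALE
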