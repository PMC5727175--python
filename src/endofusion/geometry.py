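"""Camera model and SE(3)/se(3) machinery shared by all other modules.

Conventions (fixed here, used everywhere):

* Right-handed camera frame, +z into the scene.
* Pixel ``(0, 0)`` is the centre of the top-left pixel; a pixel coordinate
  ``u`` is the pair ``(column, row)``.
* A twist ``xi`` is a 6-vector ordered ``(omega_x, omega_y, omega_z,
  nu_x, nu_y, nu_z)`` — rotational part first, translational part second.
* Rotations are stored as 3x3 matrices; quaternions appear only at the
  TUM-trajectory file boundary (see :mod:`endofusion.io`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Intrinsics",
    "RigidTransform",
    "se3_exp",
    "se3_log",
    "so3_exp",
    "so3_log",
    "hat",
    "back_project",
    "back_project_map",
    "project",
]


@dataclass(frozen=True)
class Intrinsics:
    """Pinhole camera intrinsics (no distortion model).

    Parameters are in pixel units; ``width``/``height`` give the image size
    the intrinsics refer to.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int

    def __post_init__(self) -> None:
        if not (self.fx > 0 and self.fy > 0):
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    @property
    def matrix(self) -> np.ndarray:
        """The 3x3 camera matrix K."""
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    def scaled(self, factor: float) -> "Intrinsics":
        """Intrinsics of the image down-scaled by ``factor`` (pyramids)."""
        return Intrinsics(
            fx=self.fx * factor,
            fy=self.fy * factor,
            cx=(self.cx + 0.5) * factor - 0.5,
            cy=(self.cy + 0.5) * factor - 0.5,
            width=int(round(self.width * factor)),
            height=int(round(self.height * factor)),
        )

    @staticmethod
    def from_dict(d: dict) -> "Intrinsics":
        return Intrinsics(
            fx=float(d["fx"]),
            fy=float(d["fy"]),
            cx=float(d["cx"]),
            cy=float(d["cy"]),
            width=int(d["width"]),
            height=int(d["height"]),
        )


class RigidTransform:
    """An element of SE(3): rotation ``R`` (3x3) and translation ``t`` (metres)."""

    __slots__ = ("R", "t")

    def __init__(self, R: np.ndarray, t: np.ndarray, *, check: bool = True):
        R = np.asarray(R, dtype=float).reshape(3, 3)
        t = np.asarray(t, dtype=float).reshape(3)
        if check:
            if not np.allclose(R.T @ R, np.eye(3), atol=1e-7):
                raise ValueError("R is not orthonormal")
            if not np.isclose(np.linalg.det(R), 1.0, atol=1e-7):
                raise ValueError("R must have determinant +1")
        self.R = R
        self.t = t

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3), check=False)

    @property
    def matrix(self) -> np.ndarray:
        """4x4 homogeneous matrix."""
        M = np.eye(4)
        M[:3, :3] = self.R
        M[:3, 3] = self.t
        return M

    @staticmethod
    def from_matrix(M: np.ndarray) -> "RigidTransform":
        M = np.asarray(M, dtype=float)
        return RigidTransform(M[:3, :3], M[:3, 3])

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Transform one 3-vector or an (N, 3) array of points."""
        p = np.asarray(points, dtype=float)
        return p @ self.R.T + self.t

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self @ other`` — apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.R @ other.R, self.R @ other.t + self.t, check=False
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.R.T
        return RigidTransform(Rt, -Rt @ self.t, check=False)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"RigidTransform(R={self.R.tolist()}, t={self.t.tolist()})"


def hat(v: np.ndarray) -> np.ndarray:
    """Skew-symmetric matrix of a 3-vector: ``hat(v) @ x == cross(v, x)``."""
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def so3_exp(omega: np.ndarray) -> np.ndarray:
    """Rodrigues formula: matrix exponential of ``hat(omega)``."""
    omega = np.asarray(omega, dtype=float)
    theta = np.linalg.norm(omega)
    W = hat(omega)
    if theta < 1e-10:
        # second-order series keeps the result orthonormal to machine precision
        return np.eye(3) + W + 0.5 * (W @ W)
    A = np.sin(theta) / theta
    B = (1.0 - np.cos(theta)) / theta**2
    return np.eye(3) + A * W + B * (W @ W)


def so3_log(R: np.ndarray) -> np.ndarray:
    """Inverse of :func:`so3_exp`; requires rotation angle < pi."""
    cos_theta = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    theta = np.arccos(cos_theta)
    if theta < 1e-10:
        # first-order: R ~ I + hat(omega)
        return np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]) / 2.0
    if abs(np.pi - theta) < 1e-9:
        raise ValueError("rotation angle at the log-map branch cut (theta ~ pi)")
    axis = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    return theta / (2.0 * np.sin(theta)) * axis


def se3_exp(xi: np.ndarray) -> RigidTransform:
    """Closed-form exponential map se(3) -> SE(3).

    ``xi = (omega, nu)`` with the rotational part first.  Exact for pure
    translations (``omega = 0``).
    """
    xi = np.asarray(xi, dtype=float).reshape(6)
    if not np.all(np.isfinite(xi)):
        raise ValueError("twist must be finite")
    omega, nu = xi[:3], xi[3:]
    theta = np.linalg.norm(omega)
    W = hat(omega)
    R = so3_exp(omega)
    if theta < 1e-10:
        V = np.eye(3) + 0.5 * W + (W @ W) / 6.0
    else:
        A = np.sin(theta) / theta
        B = (1.0 - np.cos(theta)) / theta**2
        C = (1.0 - A) / theta**2
        V = np.eye(3) + B * W + C * (W @ W)
    return RigidTransform(R, V @ nu, check=False)


def se3_log(T: RigidTransform) -> np.ndarray:
    """Inverse of :func:`se3_exp`; requires rotation angle < pi."""
    omega = so3_log(T.R)
    theta = np.linalg.norm(omega)
    W = hat(omega)
    if theta < 1e-10:
        Vinv = np.eye(3) - 0.5 * W + (W @ W) / 12.0
    else:
        A = np.sin(theta) / theta
        B = (1.0 - np.cos(theta)) / theta**2
        Vinv = np.eye(3) - 0.5 * W + (1.0 / theta**2) * (1.0 - A / (2.0 * B)) * (W @ W)
    return np.concatenate([omega, Vinv @ T.t])


def back_project(u: np.ndarray, depth, K: Intrinsics) -> np.ndarray:
    """Back-project pixel(s) ``u = (column, row)`` at ``depth`` metres.

    ``u`` may be a single pair or an (N, 2) array; ``depth`` a scalar or an
    (N,) array.  Returns 3-vector(s) whose z component equals ``depth``.
    """
    u = np.asarray(u, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if np.any(depth <= 0):
        raise ValueError("depth must be positive")
    x = (u[..., 0] - K.cx) / K.fx * depth
    y = (u[..., 1] - K.cy) / K.fy * depth
    return np.stack([x, y, depth * np.ones_like(x)], axis=-1)


def back_project_map(depth: np.ndarray, K: Intrinsics) -> np.ndarray:
    """Back-project a full H x W depth image to an H x W x 3 point map.

    Pixels with non-positive depth yield undefined points (caller masks).
    """
    H, W = depth.shape
    cols, rows = np.meshgrid(np.arange(W, dtype=float), np.arange(H, dtype=float))
    x = (cols - K.cx) / K.fx * depth
    y = (rows - K.cy) / K.fy * depth
    return np.stack([x, y, depth], axis=-1)


def project(p: np.ndarray, K: Intrinsics) -> np.ndarray:
    """Pinhole projection of 3D point(s) to pixel coordinates (column, row).

    The result may fall outside the image bounds; the caller filters.
    """
    p = np.asarray(p, dtype=float)
    z = p[..., 2]
    if np.any(z <= 0):
        raise ValueError("point behind the camera (z <= 0)")
    return np.stack(
        [K.fx * p[..., 0] / z + K.cx, K.fy * p[..., 1] / z + K.cy], axis=-1
    )
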