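"""Dense surfel-based scene model.

Each surfel is an oriented disc: position, normal, color, confidence
weight, radius and two timestamps (initialisation, last update).  The map
is partitioned by a time window into an *active* set (surfels seen within
``delta_t`` of the current time — the only ones used for tracking and
fusion) and an *inactive* set (older surface, kept for loop closure).

Fusion uses projective data association against a splatted prediction of
the active model: each valid frame pixel either merges into the surfel it
lands on (weighted running averages, weight + 1) or inserts a new surfel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from endofusion.geometry import (
    Intrinsics,
    RigidTransform,
    back_project_map,
)
from endofusion.preprocess import Frame

__all__ = ["SurfelMap", "ModelPrediction", "compute_normals"]


@dataclass
class ModelPrediction:
    """Splatted view of (a subset of) the surfel map at a camera pose.

    Images are in the camera frame of the rendering pose; ``index`` maps
    each valid pixel to the surfel that won the depth buffer.
    """

    depth: np.ndarray  # H x W metres
    color: np.ndarray  # H x W x 3 in [0, 1]
    normals: np.ndarray  # H x W x 3 unit vectors (camera frame)
    valid_mask: np.ndarray  # H x W bool
    index: np.ndarray  # H x W int, -1 where invalid

    @property
    def gray(self) -> np.ndarray:
        from endofusion.preprocess import luminance

        return luminance(self.color)


def compute_normals(depth: np.ndarray, K: Intrinsics, valid: np.ndarray) -> np.ndarray:
    """Per-pixel normals of a depth image by central-difference cross products.

    Normals are oriented to face the camera (n_z < 0 for a wall seen
    frontally at +z ... i.e. ``n . p < 0``).
    """
    pts = back_project_map(np.where(valid, depth, np.nan), K)
    dx = np.empty_like(pts)
    dy = np.empty_like(pts)
    dx[:, 1:-1] = (pts[:, 2:] - pts[:, :-2]) / 2.0
    dx[:, 0] = pts[:, 1] - pts[:, 0]
    dx[:, -1] = pts[:, -1] - pts[:, -2]
    dy[1:-1, :] = (pts[2:, :] - pts[:-2, :]) / 2.0
    dy[0, :] = pts[1, :] - pts[0, :]
    dy[-1, :] = pts[-1, :] - pts[-2, :]
    n = np.cross(dx, dy)
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):
        n = n / np.where(norm > 1e-12, norm, np.nan)
    # orient towards the camera
    flip = np.einsum("ijk,ijk->ij", n, pts) > 0
    n[flip] *= -1.0
    bad = ~np.isfinite(n).all(axis=-1)
    n[bad] = 0.0
    return n


class SurfelMap:
    """Growable surfel collection with active/inactive time windowing.

    ``delta_t`` is the inactivity window in the same units as the frame
    timestamps (seconds for real sequences).
    """

    def __init__(
        self,
        K: Intrinsics,
        *,
        delta_t: float = 10.0,
        depth_gate: float = 0.005,
        normal_gate_deg: float = 20.0,
        max_radius: float = 0.02,
        min_projected_radius_px: float = 2.0,
        max_projected_radius_px: float = 5.0,
    ):
        self.K = K
        self.delta_t = delta_t
        self.depth_gate = depth_gate
        self.normal_gate_deg = normal_gate_deg
        self.max_radius = max_radius
        self.min_projected_radius_px = min_projected_radius_px
        self.max_projected_radius_px = max_projected_radius_px
        self.current_time = -np.inf

        self.positions = np.zeros((0, 3))
        self.normals = np.zeros((0, 3))
        self.colors = np.zeros((0, 3))
        self.weights = np.zeros(0)
        self.radii = np.zeros(0)
        self.t_init = np.zeros(0)
        self.t_last = np.zeros(0)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def active_mask(self) -> np.ndarray:
        return (self.current_time - self.t_last) <= self.delta_t

    @property
    def inactive_mask(self) -> np.ndarray:
        return ~self.active_mask

    def advance_time(self, t: float) -> None:
        """Move the map clock forward; the active partition follows t_last."""
        if t < self.current_time:
            raise ValueError("time cannot move backwards")
        self.current_time = t

    # -- fusion ------------------------------------------------------------

    def fuse_frame(
        self,
        frame: Frame,
        pose: RigidTransform,
        *,
        prediction: ModelPrediction | None = None,
    ) -> None:
        """Fuse one tracked frame into the map.

        Pixels that land (within the depth/normal gates) on an active surfel
        of the splatted prediction are merged by confidence-weighted
        averaging; all others insert new surfels.  ``prediction`` may be the
        prediction already rendered for tracking at this pose; otherwise one
        is rendered here.
        """
        K = self.K
        t = frame.timestamp
        valid = frame.valid_mask & (frame.depth > 0)
        if len(self) and prediction is None:
            prediction = self.predict_view(pose, subset="active")

        pts_cam = back_project_map(np.where(valid, frame.depth, 1.0), K)
        nrm_cam = compute_normals(frame.depth, K, valid)
        valid = valid & (np.linalg.norm(nrm_cam, axis=-1) > 0.5)

        pts_w = pose.apply(pts_cam[valid])
        nrm_w = nrm_cam[valid] @ pose.R.T
        cols = frame.rgb[valid]
        # radius from depth and slant: disc large enough to cover its pixel
        z = frame.depth[valid]
        nz = np.abs(nrm_cam[valid][:, 2])
        radius = np.clip(z * np.sqrt(2.0) / (K.fx * np.maximum(nz, 0.15)), 0, self.max_radius)

        merged = np.zeros(len(pts_w), dtype=bool)
        if prediction is not None and len(self):
            rows, cols_px = np.nonzero(valid)
            cos_gate = np.cos(np.radians(self.normal_gate_deg))
            match = np.full(len(pts_w), -1, dtype=np.int64)
            # the projected pixel first, then its 8 neighbours: the depth
            # buffer often hands a pixel to a surfel splatted from the cell
            # next door, which is the same surface
            for dy, dx in ((0, 0), (0, 1), (0, -1), (1, 0), (-1, 0),
                           (1, 1), (1, -1), (-1, 1), (-1, -1)):
                todo = match < 0
                if not todo.any():
                    break
                rr = rows[todo] + dy
                cc = cols_px[todo] + dx
                inb = (rr >= 0) & (rr < prediction.index.shape[0]) & (
                    cc >= 0
                ) & (cc < prediction.index.shape[1])
                cand = np.full(todo.sum(), -1, dtype=np.int64)
                cand[inb] = prediction.index[rr[inb], cc[inb]]
                has = cand >= 0
                sidx = cand[has]
                p_s = self.positions[sidx]
                n_s = self.normals[sidx]
                sub = np.nonzero(todo)[0][has]
                plane_dist = np.abs(
                    np.einsum("ij,ij->i", n_s, pts_w[sub] - p_s)
                )
                cosang = np.einsum("ij,ij->i", n_s, nrm_w[sub])
                ok = (plane_dist < self.depth_gate) & (cosang > cos_gate)
                match[sub[ok]] = sidx[ok]
            merged = match >= 0
            self._merge(
                match[merged], pts_w[merged], nrm_w[merged], cols[merged],
                radius[merged], t,
            )

        self._insert(pts_w[~merged], nrm_w[~merged], cols[~merged], radius[~merged], t)
        if t > self.current_time:
            self.advance_time(t)

    def _merge(self, idx, pts, nrms, cols, radii, t) -> None:
        if len(idx) == 0:
            return
        # several pixels may hit the same surfel: accumulate sums first
        uniq, inv = np.unique(idx, return_inverse=True)
        cnt = np.bincount(inv).astype(float)
        sum_p = np.zeros((len(uniq), 3))
        sum_n = np.zeros((len(uniq), 3))
        sum_c = np.zeros((len(uniq), 3))
        np.add.at(sum_p, inv, pts)
        np.add.at(sum_n, inv, nrms)
        np.add.at(sum_c, inv, cols)
        min_r = np.full(len(uniq), np.inf)
        np.minimum.at(min_r, inv, radii)

        w = self.weights[uniq]
        tot = w + cnt
        self.positions[uniq] = (w[:, None] * self.positions[uniq] + sum_p) / tot[:, None]
        n_new = w[:, None] * self.normals[uniq] + sum_n
        n_new /= np.maximum(np.linalg.norm(n_new, axis=1, keepdims=True), 1e-12)
        self.normals[uniq] = n_new
        self.colors[uniq] = (w[:, None] * self.colors[uniq] + sum_c) / tot[:, None]
        self.weights[uniq] = tot
        self.radii[uniq] = np.minimum(self.radii[uniq], min_r)
        self.t_last[uniq] = np.maximum(self.t_last[uniq], t)

    def _insert(self, pts, nrms, cols, radii, t) -> None:
        if len(pts) == 0:
            return
        self.positions = np.vstack([self.positions, pts])
        self.normals = np.vstack([self.normals, nrms])
        self.colors = np.vstack([self.colors, cols])
        self.weights = np.concatenate([self.weights, np.ones(len(pts))])
        self.radii = np.concatenate([self.radii, radii])
        self.t_init = np.concatenate([self.t_init, np.full(len(pts), t)])
        self.t_last = np.concatenate([self.t_last, np.full(len(pts), t)])

    # -- splatting ---------------------------------------------------------

    def predict_view(
        self, pose: RigidTransform, subset: str = "active"
    ) -> ModelPrediction:
        """Forward-splat the requested subset as depth-buffered discs.

        ``subset`` is ``"active"``, ``"inactive"`` or ``"all"``.  Images are
        expressed in the camera frame of ``pose``; an empty subset yields an
        all-invalid prediction.
        """
        K = self.K
        H, W = K.height, K.width
        if subset == "active":
            sel = np.nonzero(self.active_mask)[0]
        elif subset == "inactive":
            sel = np.nonzero(self.inactive_mask)[0]
        elif subset == "all":
            sel = np.arange(len(self))
        else:
            raise ValueError(f"unknown subset {subset!r}")

        depth = np.full((H, W), np.inf)
        index = np.full((H, W), -1, dtype=np.int64)
        color = np.zeros((H, W, 3))
        normals = np.zeros((H, W, 3))

        if len(sel):
            inv = pose.inverse()
            p_cam = inv.apply(self.positions[sel])
            z = p_cam[:, 2]
            front = z > 1e-4
            sel = sel[front]
            p_cam = p_cam[front]
            z = z[front]
        if len(sel):
            u = K.fx * p_cam[:, 0] / z + K.cx
            v = K.fy * p_cam[:, 1] / z + K.cy
            r_px = np.clip(
                self.radii[sel] * K.fx / z,
                self.min_projected_radius_px,
                self.max_projected_radius_px,
            )
            inb = (
                (u > -self.max_projected_radius_px)
                & (u < W - 1 + self.max_projected_radius_px)
                & (v > -self.max_projected_radius_px)
                & (v < H - 1 + self.max_projected_radius_px)
            )
            sel, u, v, z, r_px = sel[inb], u[inb], v[inb], z[inb], r_px[inb]
            p_cam = p_cam[inb]
            ui = np.round(u).astype(int)
            vi = np.round(v).astype(int)

            # disc plane in camera coordinates: depth varies across the
            # splat footprint as the ray-plane intersection, avoiding the
            # fronto-parallel bias of constant-depth discs
            n_cam_s = self.normals[sel] @ pose.R
            ndotp = np.einsum("ij,ij->i", n_cam_s, p_cam)

            rmax = int(np.ceil(self.max_projected_radius_px))
            offsets = [
                (dy, dx)
                for dy in range(-rmax, rmax + 1)
                for dx in range(-rmax, rmax + 1)
            ]

            def plane_depth(dy, dx, ok):
                dxr = (ui[ok] + dx - K.cx) / K.fx
                dyr = (vi[ok] + dy - K.cy) / K.fy
                denom = n_cam_s[ok, 0] * dxr + n_cam_s[ok, 1] * dyr + n_cam_s[ok, 2]
                zc = np.where(
                    np.abs(denom) > 0.2, ndotp[ok] / np.where(np.abs(denom) > 0.2, denom, 1.0), z[ok]
                )
                # grazing or degenerate planes fall back to the centre depth
                bad = (zc <= 0) | (np.abs(zc - z[ok]) > 0.5 * z[ok])
                return np.where(bad, z[ok], zc)

            flat_depth = depth.ravel()
            zbuf_vals = {}
            # pass 1: depth buffer with plane-corrected depths
            for dy, dx in offsets:
                rr, cc = vi + dy, ui + dx
                ok = (
                    (rr >= 0)
                    & (rr < H)
                    & (cc >= 0)
                    & (cc < W)
                    & (dy * dy + dx * dx <= r_px * r_px)
                )
                if not ok.any():
                    continue
                zc = plane_depth(dy, dx, ok)
                zbuf_vals[(dy, dx)] = (ok, zc)
                np.minimum.at(flat_depth, rr[ok] * W + cc[ok], zc)
            # pass 2: winning surfel index (lowest index among depth winners)
            flat_index = np.full(H * W, np.iinfo(np.int64).max)
            for (dy, dx), (ok, zc) in zbuf_vals.items():
                rr, cc = vi + dy, ui + dx
                lin = rr[ok] * W + cc[ok]
                win = zc == flat_depth[lin]
                np.minimum.at(flat_index, lin[win], sel[np.nonzero(ok)[0][win]])
            got = flat_index < np.iinfo(np.int64).max
            index.ravel()[got] = flat_index[got]

            hit = index >= 0
            sidx = index[hit]
            color[hit] = self.colors[sidx]
            normals[hit] = self.normals[sidx] @ pose.R  # world->camera

        valid = (index >= 0) & np.isfinite(depth)
        depth = np.where(valid, depth, 0.0)
        return ModelPrediction(
            depth=depth, color=color, normals=normals, valid_mask=valid, index=index
        )

    # -- I/O ---------------------------------------------------------------

    _PLY_PROPS = [
        ("x", "positions", 0), ("y", "positions", 1), ("z", "positions", 2),
        ("nx", "normals", 0), ("ny", "normals", 1), ("nz", "normals", 2),
        ("red", "colors", 0), ("green", "colors", 1), ("blue", "colors", 2),
        ("weight", "weights", None), ("radius", "radii", None),
        ("t_init", "t_init", None), ("t_last", "t_last", None),
    ]

    def save_ply(self, path) -> None:
        """Write the map as ascii PLY (properties x y z nx ny nz red green
        blue weight radius t_init t_last; colors as float in [0, 1])."""
        cols = []
        for _, attr, comp in self._PLY_PROPS:
            a = getattr(self, attr)
            cols.append(a[:, comp] if comp is not None else a)
        data = np.stack(cols, axis=1) if len(self) else np.zeros((0, len(cols)))
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(self)}\n")
            for name, _, _ in self._PLY_PROPS:
                fh.write(f"property float {name}\n")
            fh.write("end_header\n")
            for row in data:
                fh.write(" ".join(f"{v:.9g}" for v in row) + "\n")

    @classmethod
    def load_ply(cls, path, K: Intrinsics, **kwargs) -> "SurfelMap":
        with open(path) as fh:
            line = fh.readline().strip()
            if line != "ply":
                raise ValueError("not a PLY file")
            n = None
            names = []
            while True:
                line = fh.readline()
                if not line:
                    raise ValueError("unterminated PLY header")
                line = line.strip()
                if line.startswith("element vertex"):
                    n = int(line.split()[-1])
                elif line.startswith("property"):
                    names.append(line.split()[-1])
                elif line == "end_header":
                    break
            rows = [
                [float(v) for v in fh.readline().split()] for _ in range(n or 0)
            ]
        data = np.asarray(rows, dtype=float).reshape(n or 0, len(names))
        m = cls(K, **kwargs)
        col = {name: data[:, i] for i, name in enumerate(names)}
        m.positions = np.stack([col["x"], col["y"], col["z"]], axis=1)
        m.normals = np.stack([col["nx"], col["ny"], col["nz"]], axis=1)
        m.colors = np.stack([col["red"], col["green"], col["blue"]], axis=1)
        m.weights = col["weight"]
        m.radii = col["radius"]
        m.t_init = col["t_init"]
        m.t_last = col["t_last"]
        if len(m):
            m.current_time = m.t_last.max()
        return m
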