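"""Trajectory and surface evaluation metrics.

The trajectory metric is the absolute trajectory error (ATE): the
root-mean-square of the Euclidean distances between matched estimated and
ground-truth camera positions, optionally after a least-squares rigid or
similarity alignment (Umeyama).  Similarity alignment is the default for
full monocular runs, since shading-based depth fixes scale only by
convention; rigid alignment suits depth-oracle runs.

The surface metric aligns the reconstruction to a ground-truth mesh by
point-to-point ICP and reports the RMS of point-to-mesh distances.  The
rotational metric is the RMS geodesic rotation angle between matched pose
pairs.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from endofusion.io import Trajectory

__all__ = [
    "associate",
    "umeyama",
    "ate_rmse",
    "rotational_rmse",
    "surface_rmse",
    "point_mesh_distance",
]


def associate(
    est: Trajectory, gt: Trajectory, max_dt: float = 0.02
) -> tuple[np.ndarray, np.ndarray]:
    """Match trajectory entries by nearest timestamp within ``max_dt``."""
    gi = np.searchsorted(gt.timestamps, est.timestamps)
    pairs = []
    for i, t in enumerate(est.timestamps):
        best, bdt = None, max_dt
        for j in (gi[i] - 1, gi[i]):
            if 0 <= j < len(gt.timestamps):
                dt = abs(gt.timestamps[j] - t)
                if dt <= bdt:
                    best, bdt = j, dt
        if best is not None:
            pairs.append((i, best))
    if len(pairs) < 2:
        raise ValueError("fewer than 2 matched timestamps")
    a = np.array(pairs)
    return a[:, 0], a[:, 1]


def umeyama(
    src: np.ndarray, dst: np.ndarray, *, with_scale: bool = False
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares similarity transform: ``dst ~ s * R @ src + t``."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    xs = src - mu_s
    xd = dst - mu_d
    cov = xd.T @ xs / len(src)
    U, D, Vt = np.linalg.svd(cov)
    S = np.eye(3)
    if np.linalg.det(U) * np.linalg.det(Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    if with_scale:
        var_s = (xs**2).sum() / len(src)
        s = float(np.trace(np.diag(D) @ S) / var_s) if var_s > 0 else 1.0
    else:
        s = 1.0
    t = mu_d - s * R @ mu_s
    return s, R, t


def ate_rmse(
    est: Trajectory,
    gt: Trajectory,
    alignment: str = "none",
    max_dt: float = 0.02,
) -> float:
    """Absolute trajectory error: RMS Euclidean distance of camera centres.

    ``alignment`` is ``"none"``, ``"rigid"`` or ``"similarity"``
    (least-squares, scale-including).
    """
    ei, gi = associate(est, gt, max_dt)
    p_est = est.positions()[ei]
    p_gt = gt.positions()[gi]
    if alignment == "none":
        pass
    elif alignment in ("rigid", "similarity"):
        s, R, t = umeyama(p_est, p_gt, with_scale=(alignment == "similarity"))
        p_est = s * p_est @ R.T + t
    else:
        raise ValueError(f"unknown alignment {alignment!r}")
    return float(np.sqrt(np.mean(np.sum((p_est - p_gt) ** 2, axis=1))))


def rotational_rmse(est: Trajectory, gt: Trajectory, max_dt: float = 0.02) -> float:
    """RMS geodesic rotation angle (degrees) between matched pose pairs."""
    ei, gi = associate(est, gt, max_dt)
    angles = []
    for i, j in zip(ei, gi):
        Rd = est.poses[i].R.T @ gt.poses[j].R
        c = np.clip((np.trace(Rd) - 1.0) / 2.0, -1.0, 1.0)
        angles.append(np.degrees(np.arccos(c)))
    return float(np.sqrt(np.mean(np.square(angles))))


def point_mesh_distance(points: np.ndarray, mesh: trimesh.Trimesh, k: int = 8):
    """Exact unsigned point-to-mesh distances via nearest-triangle search.

    Candidate triangles come from a k-d tree over triangle centroids; the
    exact point-to-triangle distance is evaluated on the ``k`` nearest
    candidates per point.
    """
    tris = mesh.triangles  # (F, 3, 3)
    centroids = tris.mean(axis=1)
    tree = cKDTree(centroids)
    _, cand = tree.query(points, k=min(k, len(tris)))
    cand = np.atleast_2d(cand)
    d = np.full(len(points), np.inf)
    for col in range(cand.shape[1]):
        d = np.minimum(d, _point_triangle_distance(points, tris[cand[:, col]]))
    return d


def _point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Distance from each point to its own triangle (vectorised)."""
    return np.linalg.norm(p - _closest_on_triangle(p, tri), axis=1)


def surface_rmse(
    points: np.ndarray,
    mesh: trimesh.Trimesh,
    alignment: str = "rigid",
    *,
    max_iterations: int = 30,
    tol: float = 1e-9,
    sample_count: int = 4000,
) -> float:
    """ICP-align a reconstruction to a ground-truth mesh, then RMS distance.

    Alignment is point-to-point ICP against the mesh vertices (subsampled
    reconstruction), rigid or similarity; the final error is the RMS of
    exact point-to-mesh distances of all input points.  Raises on ICP
    divergence (error growing without recovery).
    """
    points = np.asarray(points, dtype=float)
    if len(points) == 0 or len(mesh.faces) == 0:
        raise ValueError("empty reconstruction or mesh")
    if alignment not in ("none", "rigid", "similarity"):
        raise ValueError(f"unknown alignment {alignment!r}")

    aligned = points
    if alignment != "none":
        sub = points[:: max(len(points) // sample_count, 1)]
        s_tot, R_tot, t_tot = 1.0, np.eye(3), np.zeros(3)
        prev = np.inf
        diverged = 0
        cur = sub
        for _ in range(max_iterations):
            d = point_mesh_distance(cur, mesh)
            err = float(np.sqrt(np.mean(d**2)))
            if err > prev * 1.5:
                diverged += 1
                if diverged >= 3:
                    raise RuntimeError(
                        f"ICP diverged: error {err:.6g} (previous {prev:.6g})"
                    )
            if abs(prev - err) < tol:
                break
            prev = err
            # closest mesh points as targets
            tgt = _closest_points(cur, mesh)
            s, R, t = umeyama(cur, tgt, with_scale=(alignment == "similarity"))
            cur = s * cur @ R.T + t
            s_tot = s * s_tot
            R_tot = R @ R_tot
            t_tot = s * R @ t_tot + t
        aligned = s_tot * points @ R_tot.T + t_tot
    d = point_mesh_distance(aligned, mesh)
    return float(np.sqrt(np.mean(d**2)))


def _closest_points(points: np.ndarray, mesh: trimesh.Trimesh, k: int = 8):
    """Closest point on the mesh surface for each query point."""
    tris = mesh.triangles
    centroids = tris.mean(axis=1)
    tree = cKDTree(centroids)
    _, cand = tree.query(points, k=min(k, len(tris)))
    cand = np.atleast_2d(cand)
    best_d = np.full(len(points), np.inf)
    best_p = np.zeros_like(points)
    for col in range(cand.shape[1]):
        tri = tris[cand[:, col]]
        cp = _closest_on_triangle(points, tri)
        d = np.linalg.norm(points - cp, axis=1)
        m = d < best_d
        best_d[m] = d[m]
        best_p[m] = cp[m]
    return best_p


def _closest_on_triangle(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    # same branch structure as _point_triangle_distance but returns points
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp_ = p - c
    d5 = np.einsum("ij,ij->i", ab, cp_)
    d6 = np.einsum("ij,ij->i", ac, cp_)
    closest = np.empty_like(p)
    done = np.zeros(len(p), dtype=bool)
    m = (d1 <= 0) & (d2 <= 0)
    closest[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    closest[m] = b[m]
    done |= m
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    v = np.divide(d1, d1 - d3, out=np.zeros_like(d1), where=(d1 - d3) != 0)
    closest[m] = a[m] + v[m, None] * ab[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    closest[m] = c[m]
    done |= m
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    w = np.divide(d2, d2 - d6, out=np.zeros_like(d2), where=(d2 - d6) != 0)
    closest[m] = a[m] + w[m, None] * ac[m]
    done |= m
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & ((d4 - d3) >= 0) & ((d5 - d6) >= 0)
    w = np.divide(
        d4 - d3,
        (d4 - d3) + (d5 - d6),
        out=np.zeros_like(d4),
        where=((d4 - d3) + (d5 - d6)) != 0,
    )
    closest[m] = b[m] + w[m, None] * (c[m] - b[m])
    done |= m
    m = ~done
    denom = np.where(va + vb + vc != 0, va + vb + vc, 1.0)
    v = vb / denom
    w = vc / denom
    closest[m] = (a + v[:, None] * ab + w[:, None] * ac)[m]
    return closest
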