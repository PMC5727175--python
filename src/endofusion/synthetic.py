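"""Ground-truthed synthetic endoscopy sequences.

Emulates an endoscopic capsule moving inside a closed, smoothly deforming,
near-Lambertian organ-like cavity: a lobed deformed sphere with a smooth
albedo pattern, lit by a point light co-located with the camera, with
optional wet specular (Phong) highlights and Gaussian image noise.  Every
rendered frame comes with ground-truth pose, depth image, specular mask and
the deformed mesh, so the whole SLAM pipeline and its evaluation run with
no external data.

Rendering is a plain z-buffered triangle rasteriser with perspective-correct
attribute interpolation; depth obeys exactly the pinhole model of
:mod:`endofusion.geometry` (same intrinsics both ways).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from endofusion.geometry import Intrinsics, RigidTransform, so3_exp

__all__ = [
    "SyntheticScene",
    "GroundTruth",
    "RenderedSequence",
    "render_sequence",
    "render_view",
    "standard_fixtures",
    "scene_intrinsics",
]


@dataclass
class SyntheticScene:
    """Parametric deformable cavity + light model + scripted trajectory.

    All lengths are metres.  ``seed`` fully determines the output.
    """

    seed: int = 0
    width: int = 64
    height: int = 64
    fov_deg: float = 70.0
    n_frames: int = 60
    fps: float = 10.0
    #: mean cavity radius and amplitude of the lobed shape perturbation
    base_radius: float = 0.05
    lobe_amplitude: float = 0.012
    #: peak-to-mean contrast of the smooth albedo pattern
    texture_contrast: float = 0.3
    #: time-dependent smooth radial displacement field
    deform_amplitude: float = 0.0
    deform_frequency: float = 0.4  # Hz
    #: co-located point light; inverse-square falloff optional (off: the
    #: shape-from-shading front-end assumes a distant light)
    light_falloff: bool = False
    specular_spots: int = 0
    shininess: float = 80.0
    specular_strength: float = 1.5
    noise_sigma: float = 0.0
    trajectory: str = "slow_scan"  # slow_scan | loopy | static
    trajectory_scale: float = 0.012
    icosphere_subdivisions: int = 3


@dataclass
class GroundTruth:
    """Per-frame ground truth emitted alongside the rendered frames."""

    timestamps: np.ndarray  # (N,)
    poses: list[RigidTransform]  # camera-to-world
    depths: list[np.ndarray]  # H x W metres, 0 where no surface hit
    specular_masks: list[np.ndarray]  # H x W bool
    vertices: list[np.ndarray]  # deformed mesh vertices per frame
    faces: np.ndarray  # shared face indices


@dataclass
class RenderedSequence:
    scene: SyntheticScene
    intrinsics: Intrinsics
    timestamps: np.ndarray
    images: list[np.ndarray]  # H x W x 3 in [0, 1]
    ground_truth: GroundTruth


def scene_intrinsics(scene: SyntheticScene) -> Intrinsics:
    f = 0.5 * scene.width / np.tan(np.radians(scene.fov_deg) / 2.0)
    return Intrinsics(
        fx=f,
        fy=f,
        cx=(scene.width - 1) / 2.0,
        cy=(scene.height - 1) / 2.0,
        width=scene.width,
        height=scene.height,
    )


# ---------------------------------------------------------------------------
# cavity geometry, texture, deformation
# ---------------------------------------------------------------------------


def _build_cavity(scene: SyntheticScene, rng: np.random.Generator):
    """Lobed star-shaped cavity: radius is a smooth function of direction."""
    sphere = trimesh.creation.icosphere(
        subdivisions=scene.icosphere_subdivisions, radius=1.0
    )
    dirs = np.asarray(sphere.vertices)  # unit directions
    faces = np.asarray(sphere.faces)

    # smooth lobes: sum of cosines of random directional harmonics
    axes = rng.normal(size=(4, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    freqs = rng.uniform(1.5, 3.5, size=4)
    phases = rng.uniform(0, 2 * np.pi, size=4)
    lobes = np.zeros(len(dirs))
    for a, f, ph in zip(axes, freqs, phases):
        lobes += np.cos(dirs @ a * f * np.pi + ph)
    lobes /= np.abs(lobes).max() + 1e-12
    radii = scene.base_radius + scene.lobe_amplitude * lobes

    # smooth albedo pattern (vascular-ish mottling), clipped away from 0/1
    taxes = rng.normal(size=(6, 3))
    taxes /= np.linalg.norm(taxes, axis=1, keepdims=True)
    tfreqs = rng.uniform(2.0, 6.0, size=6)
    tphases = rng.uniform(0, 2 * np.pi, size=6)
    pattern = np.zeros(len(dirs))
    for a, f, ph in zip(taxes, tfreqs, tphases):
        pattern += np.sin(dirs @ a * f * np.pi + ph)
    pattern /= np.abs(pattern).max() + 1e-12
    albedo = np.clip(0.65 + scene.texture_contrast * pattern, 0.1, 0.98)

    # wet specular spots: per-vertex Phong strength, Gaussian in angle
    spec = np.zeros(len(dirs))
    for _ in range(scene.specular_spots):
        c = rng.normal(size=3)
        c /= np.linalg.norm(c)
        ang = np.arccos(np.clip(dirs @ c, -1, 1))
        spec += scene.specular_strength * np.exp(-((ang / 0.18) ** 2))

    # radial deformation phase field (smooth over the surface)
    b = rng.normal(size=3)
    b /= np.linalg.norm(b)
    deform_phase = 2.0 * (dirs @ b)

    return dirs, faces, radii, albedo, spec, deform_phase


def _deformed_vertices(
    dirs: np.ndarray, radii: np.ndarray, phase: np.ndarray, scene: SyntheticScene, t: float
) -> np.ndarray:
    r = radii + scene.deform_amplitude * np.sin(
        2 * np.pi * scene.deform_frequency * t + phase
    )
    return dirs * r[:, None]


def _vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Area-weighted inward vertex normals (the camera sees the inside)."""
    v0, v1, v2 = vertices[faces[:, 0]], vertices[faces[:, 1]], vertices[faces[:, 2]]
    fn = np.cross(v1 - v0, v2 - v0)
    normals = np.zeros_like(vertices)
    for i in range(3):
        np.add.at(normals, faces[:, i], fn)
    # orient towards the cavity interior (origin side)
    flip = np.einsum("ij,ij->i", normals, vertices) > 0
    normals[flip] *= -1.0
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    return normals / np.maximum(norms, 1e-12)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def _trajectory_poses(scene: SyntheticScene) -> list[RigidTransform]:
    """Scripted camera-to-world poses, camera well inside the cavity."""
    n = scene.n_frames
    rho = scene.trajectory_scale
    poses: list[RigidTransform] = []
    if scene.trajectory == "static":
        for _ in range(n):
            poses.append(RigidTransform.identity())
    elif scene.trajectory == "slow_scan":
        # slow incremental translation + rotation along an open arc
        for i in range(n):
            s = i / max(n - 1, 1)
            theta = 0.9 * np.pi * s
            pos = rho * np.array(
                [np.cos(theta) - 1.0, np.sin(theta), 0.3 * np.sin(2 * theta)]
            )
            R = so3_exp(np.array([0.08 * np.sin(2 * np.pi * s), 0.35 * s, 0.0]))
            poses.append(RigidTransform(R, pos, check=False))
    elif scene.trajectory == "loopy":
        # closed loop with a full look-around: the view direction sweeps a
        # complete turn so early surface leaves the frustum mid-run and is
        # genuinely revisited when the final frame returns to the first pose
        for i in range(n):
            s = i / max(n - 1, 1)
            theta = 2 * np.pi * s
            pos = rho * np.array(
                [np.sin(theta), 1.0 - np.cos(theta), 0.25 * np.sin(theta)]
            )
            yaw = so3_exp(np.array([0.0, theta, 0.0]))
            wobble = so3_exp(np.array([0.12 * np.sin(theta), 0.0, 0.08 * np.sin(theta)]))
            poses.append(RigidTransform(yaw @ wobble, pos, check=False))
    else:
        raise ValueError(f"unknown trajectory script: {scene.trajectory!r}")
    return poses


# ---------------------------------------------------------------------------
# rasteriser
# ---------------------------------------------------------------------------


def render_view(
    vertices: np.ndarray,
    faces: np.ndarray,
    vertex_attrs: dict[str, np.ndarray],
    pose: RigidTransform,
    K: Intrinsics,
    *,
    near: float = 1e-3,
):
    """Z-buffered rasterisation of a mesh from camera pose ``pose``.

    Returns ``(depth, attrs, hit_mask)`` where ``depth`` is the camera-space
    z in metres (0 where nothing was hit) and ``attrs`` maps each input
    attribute name to its perspective-correct per-pixel interpolation.
    """
    H, W = K.height, K.width
    inv = pose.inverse()
    v_cam = inv.apply(vertices)

    names = list(vertex_attrs)
    flat_attrs = []
    for name in names:
        a = np.asarray(vertex_attrs[name], dtype=float)
        flat_attrs.append(a[:, None] if a.ndim == 1 else a)
    A = np.concatenate(flat_attrs, axis=1)  # (V, C)
    C = A.shape[1]

    z = v_cam[:, 2]
    u = K.fx * v_cam[:, 0] / np.where(z > near, z, np.inf) + K.cx
    v = K.fy * v_cam[:, 1] / np.where(z > near, z, np.inf) + K.cy

    depth = np.full((H, W), np.inf)
    attr_buf = np.zeros((H, W, C))

    tri_z = z[faces]
    ok = np.all(tri_z > near, axis=1)
    # frustum reject with margin (vertices project finitely since z > near)
    tu, tv = u[faces], v[faces]
    ok &= (tu.max(axis=1) >= 0) & (tu.min(axis=1) <= W - 1)
    ok &= (tv.max(axis=1) >= 0) & (tv.min(axis=1) <= H - 1)

    safe_z = np.where(z > near, z, np.inf)
    inv_z = 1.0 / safe_z[:, None]
    A_over_z = A * inv_z

    for fi in np.nonzero(ok)[0]:
        i0, i1, i2 = faces[fi]
        x0, y0, x1, y1, x2, y2 = u[i0], v[i0], u[i1], v[i1], u[i2], v[i2]
        xmin = max(int(np.floor(min(x0, x1, x2))), 0)
        xmax = min(int(np.ceil(max(x0, x1, x2))), W - 1)
        ymin = max(int(np.floor(min(y0, y1, y2))), 0)
        ymax = min(int(np.ceil(max(y0, y1, y2))), H - 1)
        if xmin > xmax or ymin > ymax:
            continue
        area = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        if abs(area) < 1e-12:
            continue
        xs = np.arange(xmin, xmax + 1)
        ys = np.arange(ymin, ymax + 1)
        gx, gy = np.meshgrid(xs, ys)
        w0 = ((x1 - gx) * (y2 - gy) - (x2 - gx) * (y1 - gy)) / area
        w1 = ((x2 - gx) * (y0 - gy) - (x0 - gx) * (y2 - gy)) / area
        w2 = 1.0 - w0 - w1
        inside = (w0 >= 0) & (w1 >= 0) & (w2 >= 0)
        if not inside.any():
            continue
        iz = w0 * inv_z[i0, 0] + w1 * inv_z[i1, 0] + w2 * inv_z[i2, 0]
        zpix = 1.0 / iz
        rows, cols = gy[inside], gx[inside]
        zc = zpix[inside]
        closer = zc < depth[rows, cols]
        if not closer.any():
            continue
        rows, cols, zc = rows[closer], cols[closer], zc[closer]
        wa = np.stack([w0[inside][closer], w1[inside][closer], w2[inside][closer]], axis=1)
        ac = (
            wa[:, 0:1] * A_over_z[i0] + wa[:, 1:2] * A_over_z[i1] + wa[:, 2:3] * A_over_z[i2]
        ) * zc[:, None]
        depth[rows, cols] = zc
        attr_buf[rows, cols] = ac

    hit = np.isfinite(depth)
    depth = np.where(hit, depth, 0.0)

    out: dict[str, np.ndarray] = {}
    off = 0
    for name, fa in zip(names, flat_attrs):
        w = fa.shape[1]
        block = attr_buf[..., off : off + w]
        out[name] = block[..., 0] if w == 1 else block
        off += w
    return depth, out, hit


# ---------------------------------------------------------------------------
# shading + sequence rendering
# ---------------------------------------------------------------------------

#: base tissue tint applied to the scalar albedo pattern
_TISSUE_RGB = np.array([0.95, 0.55, 0.45])


def _shade(
    depth: np.ndarray,
    attrs: dict[str, np.ndarray],
    hit: np.ndarray,
    pose: RigidTransform,
    K: Intrinsics,
    scene: SyntheticScene,
):
    """Co-located-light Lambertian + Phong shading of a rasterised view.

    Returns ``(rgb, specular_mask)``; the mask marks pixels where the
    specular term exceeds the Lambertian term.
    """
    from endofusion.geometry import back_project_map

    p_cam = back_project_map(np.where(hit, depth, 1.0), K)
    n_world = attrs["normal"]
    n_cam = n_world @ pose.R  # world->camera rotation of direction vectors
    n_cam /= np.maximum(np.linalg.norm(n_cam, axis=-1, keepdims=True), 1e-12)

    dist = np.linalg.norm(p_cam, axis=-1)
    ldir = -p_cam / np.maximum(dist[..., None], 1e-12)  # surface -> camera/light
    ndotl = np.clip(np.einsum("ijk,ijk->ij", n_cam, ldir), 0.0, None)

    lambert = attrs["albedo"] * ndotl
    if scene.light_falloff:
        ref = scene.base_radius
        lambert = lambert * (ref / np.maximum(dist, 1e-6)) ** 2
    # co-located viewer and light: the Phong lobe peaks where n points back
    spec = attrs["spec"] * np.maximum(ndotl, 0.0) ** scene.shininess

    intensity = lambert[..., None] * _TISSUE_RGB + spec[..., None]
    rgb = np.clip(np.where(hit[..., None], intensity, 0.0), 0.0, 1.0)
    mask = hit & (spec > lambert)
    return rgb, mask


def render_sequence(scene: SyntheticScene) -> RenderedSequence:
    """Render the scripted sequence with full ground truth.

    Deterministic given ``scene.seed``.  Raises if any scripted pose puts
    the camera outside (or dangerously close to) the cavity wall.
    """
    rng = np.random.default_rng(scene.seed)
    dirs, faces, radii, albedo, spec, dphase = _build_cavity(scene, rng)
    K = scene_intrinsics(scene)
    poses = _trajectory_poses(scene)
    timestamps = np.arange(scene.n_frames) / scene.fps

    min_r = radii.min() - abs(scene.deform_amplitude)
    for i, P in enumerate(poses):
        if np.linalg.norm(P.t) > 0.75 * min_r:
            raise ValueError(f"camera outside the cavity safe zone at frame {i}")

    images, depths, masks, verts_per_frame = [], [], [], []
    for i, (t, P) in enumerate(zip(timestamps, poses)):
        V = _deformed_vertices(dirs, radii, dphase, scene, t)
        N = _vertex_normals(V, faces)
        depth, attrs, hit = render_view(
            V, faces, {"normal": N, "albedo": albedo, "spec": spec}, P, K
        )
        rgb, smask = _shade(depth, attrs, hit, P, K, scene)
        if scene.noise_sigma > 0:
            rgb = np.clip(rgb + rng.normal(0, scene.noise_sigma, rgb.shape), 0, 1)
        images.append(rgb)
        depths.append(depth)
        masks.append(smask)
        verts_per_frame.append(V)

    gt = GroundTruth(
        timestamps=timestamps,
        poses=poses,
        depths=depths,
        specular_masks=masks,
        vertices=verts_per_frame,
        faces=faces,
    )
    return RenderedSequence(
        scene=scene, intrinsics=K, timestamps=timestamps, images=images, ground_truth=gt
    )


def render_hemisphere(
    size: int = 64,
    *,
    bump_radius_px: float | None = None,
    base_depth: float = 0.06,
    bump_height: float = 0.02,
    albedo: float = 0.9,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic render of a Lambertian spherical bump facing the camera.

    A fronto-parallel plane at ``base_depth`` carries a spherical cap of
    height ``bump_height`` bulging towards the camera, lit by a co-located
    light with uniform albedo — the canonical shape-from-shading test
    surface.  Returns ``(gray_image, depth)`` computed in closed form
    (orthographic shading: intensity = albedo * n_z).
    """
    if bump_radius_px is None:
        # the canonical test image: the bump fills most of the frame
        bump_radius_px = 0.55 * size
    ys, xs = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    c = (size - 1) / 2.0
    rho = np.hypot(xs - c, ys - c)
    # spherical bump expressed in pixel units so the surface slopes are O(1)
    # on the pixel grid, exactly the gradients the shading model sees; the
    # rim is trimmed to avoid near-vertical slopes
    R_px = bump_radius_px
    rim = 0.92 * R_px
    h_px = np.zeros((size, size))
    inside = rho < rim
    h_px[inside] = np.sqrt(R_px**2 - rho[inside] ** 2) - np.sqrt(R_px**2 - rim**2)
    # shading from the pixel-grid gradients (forward differences, matching
    # the reflectance discretisation of the depth front-end)
    p = h_px - np.hstack([h_px[:, :1], h_px[:, :-1]])
    q = h_px - np.vstack([h_px[:1, :], h_px[:-1, :]])
    nz = 1.0 / np.sqrt(1.0 + p**2 + q**2)
    gray = np.clip(albedo * nz, 0.0, 1.0)
    # metric depth: peak rises bump_height above the base plane
    depth = base_depth - h_px / h_px.max() * bump_height
    return gray, depth


def standard_fixtures() -> dict[str, SyntheticScene]:
    """Canned scene configurations mirroring the main recording styles:
    a slow incremental scan, a loopy revisit (clean / noisy / reflective)."""
    slow = SyntheticScene(
        seed=7, n_frames=60, trajectory="slow_scan", deform_amplitude=0.0
    )
    loopy = SyntheticScene(
        seed=11, n_frames=80, trajectory="loopy", trajectory_scale=0.010
    )
    return {
        "SLOW_SCAN": slow,
        "LOOPY": loopy,
        "LOOPY_NOISY": replace(loopy, noise_sigma=0.02),
        "LOOPY_SPECULAR": replace(
            loopy, specular_spots=25, shininess=60.0, specular_strength=2.0
        ),
    }
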