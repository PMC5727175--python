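"""Frame preprocessing: specular suppression and shape-from-shading depth.

Endoscopic images of wet tissue show saturated specular highlights from the
capsule's own light.  Highlights are detected by combining an adaptive
luminance threshold with the image gradient map, removed by harmonic
inpainting, and the cleaned luminance image is converted to a relative depth
image by the iterative linear-approximation scheme of Tsai and Shah, which
linearises the Lambertian reflectance map about the current surface-gradient
estimate and applies one Newton step per pixel per iteration.

The recovered depth is relative; it is affinely rescaled to a configured
metric range (defaults chosen at stomach scale).  Absolute scale is fixed
only by this convention — evaluation uses similarity alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Frame",
    "ShadingParams",
    "detect_specular_mask",
    "inpaint_specular",
    "shape_from_shading",
    "preprocess_frame",
    "luminance",
]

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class Frame:
    """One time-stamped RGB frame and its derived depth image.

    ``valid_mask`` is the pixel domain Omega over which tracking residuals
    are evaluated; ``depth`` is positive wherever ``valid_mask`` is true.
    """

    timestamp: float
    rgb: np.ndarray  # H x W x 3, values in [0, 1]
    gray: np.ndarray  # H x W luminance in [0, 1]
    depth: np.ndarray | None = None  # H x W metres
    valid_mask: np.ndarray | None = None  # H x W bool


@dataclass
class ShadingParams:
    """Parameters of the shape-from-shading depth front-end.

    light_direction
        Unit vector towards the light (slant/tilt parameterisation); the
        default ``(0, 0, 1)`` is a light co-located with the camera, the
        geometry of a capsule endoscope.
    albedo
        Surface albedo assumed by the reflectance model.
    n_iterations
        Newton-update sweeps of the Tsai-Shah scheme.
    depth_range
        ``(d_min, d_max)`` metres the relative depth is rescaled to.
    estimate_light
        If true, slant/tilt/albedo are re-estimated per frame from image
        statistics instead of taken from this object.
    """

    light_direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0])
    )
    albedo: float = 1.0
    n_iterations: int = 200
    depth_range: tuple[float, float] = (0.02, 0.15)
    estimate_light: bool = False

    def __post_init__(self) -> None:
        self.light_direction = np.asarray(self.light_direction, dtype=float)
        n = np.linalg.norm(self.light_direction)
        if n == 0:
            raise ValueError("light_direction must be nonzero")
        self.light_direction = self.light_direction / n
        if self.depth_range[0] >= self.depth_range[1]:
            raise ValueError("depth_range must satisfy d_min < d_max")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def luminance(rgb: np.ndarray) -> np.ndarray:
    """BT.601 luminance of an H x W x 3 image in [0, 1]."""
    return np.asarray(rgb, dtype=float) @ _LUMA


def detect_specular_mask(
    rgb: np.ndarray,
    *,
    k_std: float = 2.5,
    gradient_percentile: float = 95.0,
    dilate_radius: int = 2,
) -> np.ndarray:
    """Detect specular-highlight pixels.

    A pixel is flagged when its luminance exceeds an adaptive threshold
    (``mean + k_std * std``) AND it lies within a small dilation of the
    high-gradient regions (gradient magnitude above ``gradient_percentile``).
    The combined mask is dilated by ``dilate_radius`` pixels so highlight
    fringes are included.
    """
    gray = luminance(rgb) if rgb.ndim == 3 else np.asarray(rgb, dtype=float)
    thresh = gray.mean() + k_std * gray.std()
    peaks = gray > thresh

    gy, gx = np.gradient(gray)
    grad = np.hypot(gx, gy)
    if grad.max() > 0:
        high_grad = grad >= np.percentile(grad, gradient_percentile)
        near_edges = ndimage.binary_dilation(
            high_grad, structure=_disk(dilate_radius)
        )
    else:
        near_edges = np.zeros_like(peaks)

    mask = peaks & near_edges
    if dilate_radius > 0 and mask.any():
        mask = ndimage.binary_dilation(mask, structure=_disk(dilate_radius))
    if mask.all():
        logger.warning("specular mask covers the entire image")
    return mask


def _disk(radius: int) -> np.ndarray:
    if radius < 1:
        return np.ones((1, 1), dtype=bool)
    y, x = np.ogrid[-radius : radius + 1, -radius : radius + 1]
    return x * x + y * y <= radius * radius


def inpaint_specular(
    rgb: np.ndarray,
    mask: np.ndarray,
    *,
    max_iterations: int = 500,
    tol: float = 1e-6,
) -> np.ndarray:
    """Fill masked pixels by harmonic (diffusion) inpainting.

    Solves the discrete Laplace equation on the masked region with Dirichlet
    boundary values from the surrounding pixels, by Jacobi iteration
    (``max_iterations`` sweeps or max update below ``tol``).  Unmasked
    pixels are returned unchanged bit-for-bit.
    """
    rgb = np.asarray(rgb, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return rgb.copy()
    if mask.all():
        raise ValueError("cannot inpaint: mask covers the whole image")

    single = rgb.ndim == 2
    img = rgb[..., None] if single else rgb
    out = img.copy()
    # seed masked pixels with the unmasked mean for faster diffusion
    out[mask] = img[~mask].mean(axis=0)

    for _ in range(max_iterations):
        p = np.pad(out, ((1, 1), (1, 1), (0, 0)), mode="edge")
        neigh = (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:]) / 4.0
        delta = np.abs(neigh[mask] - out[mask]).max()
        out[mask] = neigh[mask]
        if delta < tol:
            break
    return out[..., 0] if single else out


def _reflectance_and_derivative(
    p: np.ndarray, q: np.ndarray, light: np.ndarray, albedo: float
) -> tuple[np.ndarray, np.ndarray]:
    """Lambertian reflectance R(p, q) and dR/dZ for forward-difference p, q.

    With surface normal proportional to (-p, -q, 1) and unit light
    (lx, ly, lz):  R = albedo * (-p*lx - q*ly + lz) / sqrt(1 + p^2 + q^2).
    Both p and q increase by 1 per unit increase of Z at the pixel, so
    dR/dZ = dR/dp + dR/dq.
    """
    lx, ly, lz = light
    norm2 = 1.0 + p * p + q * q
    norm = np.sqrt(norm2)
    num = -p * lx - q * ly + lz
    R = albedo * num / norm
    dR_dp = albedo * (-lx / norm - num * p / (norm2 * norm))
    dR_dq = albedo * (-ly / norm - num * q / (norm2 * norm))
    return R, dR_dp + dR_dq


def _estimate_light(gray: np.ndarray) -> tuple[np.ndarray, float]:
    """Estimate light direction and albedo from image statistics.

    Uses the classical moment-based estimator: tilt from the average image
    gradient direction, slant from the intensity moment ratio.  Falls back
    to a frontal light when gradients vanish.
    """
    gy, gx = np.gradient(gray)
    mx, my = gx.mean(), gy.mean()
    if np.hypot(mx, my) < 1e-12:
        tilt = 0.0
    else:
        tilt = float(np.arctan2(my, mx))
    mu1 = gray.mean()
    mu2 = (gray**2).mean()
    gamma = np.sqrt(max(6.0 * np.pi**2 * mu2 - 48.0 * mu1**2, 0.0))
    albedo = gamma / np.pi if gamma > 0 else 1.0
    cos_slant = np.clip(4.0 * mu1 / gamma if gamma > 0 else 1.0, -1.0, 1.0)
    slant = float(np.arccos(cos_slant))
    light = np.array(
        [np.cos(tilt) * np.sin(slant), np.sin(tilt) * np.sin(slant), np.cos(slant)]
    )
    return light, float(albedo) if albedo > 0 else 1.0


def shape_from_shading(
    gray: np.ndarray, params: ShadingParams
) -> tuple[np.ndarray, np.ndarray]:
    """Tsai-Shah iterative shape-from-shading.

    Starting from a flat surface, each iteration forms the surface gradients
    (p, q) by forward differences of the current height field, linearises the
    Lambertian reflectance about them, and applies a per-pixel Newton
    correction towards the observed intensity.  The recovered relative
    height is converted to depth with the convention *brighter = nearer*
    (co-located light) and affinely rescaled to ``params.depth_range``.

    Returns ``(depth, valid_mask)``; the mask is all-true here (border
    trimming happens in :func:`preprocess_frame`).
    """
    gray = np.asarray(gray, dtype=float)
    if params.estimate_light:
        light, albedo = _estimate_light(gray)
    else:
        light, albedo = params.light_direction, params.albedo

    # Height is seeded from luminance rather than a flat field: for a
    # frontal (co-located) light the reflectance derivative vanishes on a
    # flat surface, making zero a degenerate fixed point of the update.
    Z = gray.copy()
    eps = 1e-6
    for it in range(params.n_iterations):
        # forward differences; replicate at the leading edge so the border
        # does not act as a step
        p = Z - np.hstack([Z[:, :1], Z[:, :-1]])
        q = Z - np.vstack([Z[:1, :], Z[:-1, :]])
        R, dR_dZ = _reflectance_and_derivative(p, q, light, albedo)
        f = gray - np.maximum(R, 0.0)
        # Levenberg-style regularised Newton step; the clamp bounds pixels
        # whose reflectance derivative is near-degenerate (for a frontal
        # light dR/dZ ~ p + q, which vanishes on whole level sets)
        Z = Z + np.clip(f * dR_dZ / (dR_dZ * dR_dZ + eps), -0.2, 0.2)
        if not np.all(np.isfinite(Z)):
            raise FloatingPointError(
                f"shape-from-shading diverged at iteration {it}"
            )

    d_min, d_max = params.depth_range
    # robust affine rescale: the 1st/99th percentiles define the range so a
    # handful of outlier pixels cannot jitter the per-frame scale, which
    # would otherwise leak into the estimated trajectory
    z_lo, z_hi = np.percentile(Z, [1.0, 99.0])
    if z_hi - z_lo < 1e-12:
        depth = np.full_like(Z, 0.5 * (d_min + d_max))
    else:
        # higher Z = taller surface = nearer camera -> smaller depth
        depth = d_min + (z_hi - Z) / (z_hi - z_lo) * (d_max - d_min)
        depth = np.clip(depth, d_min, d_max)
    return depth, np.ones_like(depth, dtype=bool)


def preprocess_frame(
    rgb: np.ndarray,
    timestamp: float,
    params: ShadingParams,
    *,
    border_margin: int = 2,
    max_inpaint_fraction: float = 0.25,
    exclude_specular: bool = False,
) -> Frame:
    """Full preprocessing chain: specular mask -> inpaint -> depth.

    ``valid_mask`` excludes a ``border_margin``-pixel frame border.  If the
    specular mask covers more than ``max_inpaint_fraction`` of the image the
    inpainted region is additionally removed from the valid domain;
    ``exclude_specular`` removes it unconditionally.
    """
    rgb = np.asarray(rgb, dtype=float)
    mask = detect_specular_mask(rgb)
    clean = inpaint_specular(rgb, mask) if mask.any() else rgb.copy()
    gray = luminance(clean)
    depth, valid = shape_from_shading(gray, params)

    if border_margin > 0:
        valid = valid.copy()
        valid[:border_margin, :] = False
        valid[-border_margin:, :] = False
        valid[:, :border_margin] = False
        valid[:, -border_margin:] = False
    if exclude_specular or mask.mean() > max_inpaint_fraction:
        valid = valid & ~mask
    return Frame(timestamp=timestamp, rgb=clean, gray=gray, depth=depth, valid_mask=valid)
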