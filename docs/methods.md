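# Methods

This note records the model, the concrete numerical choices, and what the
synthetic experiments do and do not establish.

## Problem setting and assumptions

A monocular capsule endoscope observes the inside of a closed, smoothly
deforming, near-Lambertian cavity with a light co-located with the camera.
The pipeline assumes: a calibrated pinhole camera (no distortion model),
small inter-frame motion (direct methods need a good initialisation; each
frame is initialised at the previous pose), shading-dominated image
formation after specular suppression, and deformations slow relative to
the frame rate. Absolute metric scale is not observable from shading alone;
it is fixed by convention (the configured depth range) and similarity
alignment is used when evaluating full monocular runs.

Conventions: right-handed camera frame with +z into the scene; pixel
(0, 0) at the top-left pixel centre; pixel coordinates are (column, row);
twists are ordered (rotation ‖ translation); rotations are stored as
matrices, quaternions appear only in TUM trajectory files.

## Preprocessing

*Specular detection* flags pixels with luminance above mean + 2.5·std that
lie within a 2-pixel dilation of the strongest 5% of gradient magnitudes;
the mask is dilated by 2 pixels. *Inpainting* solves the discrete Laplace
equation on the mask by Jacobi iteration (500 sweeps or max update < 1e-6);
unmasked pixels are untouched bit-for-bit. Note the adaptive threshold
cannot exceed 1, so saturated highlights on an already very bright surface
(mean + 2.5·std > 1) are undetectable by construction.

*Shape-from-shading* is the iterative Tsai–Shah scheme: surface gradients
(p, q) by forward differences of the current height field, Lambertian
reflectance R(p, q) linearised per pixel, one regularised Newton step per
pixel per iteration (200 iterations, unit albedo, frontal light by
default; per-frame light estimation from image moments is available but
off by default). Two stabilisations matter for the co-located-light case:

* the height field is seeded from luminance, because for a frontal light
  dR/dZ vanishes identically on a flat surface, making the zero field a
  degenerate fixed point of the pure update;
* the per-pixel Newton step `f·R′/(R′² + 1e-6)` is clamped to ±0.2 per
  iteration — for a frontal light R′ ∝ p + q vanishes on whole level sets,
  where the regularised division would otherwise amplify the residual by
  up to 500×.

The relative height is converted to depth with the convention *brighter =
nearer* and affinely rescaled to [0.02, 0.15] m (plausible stomach scale,
configurable). The rescale anchors on the 1st/99th percentiles with
clipping rather than min/max: per-frame outlier pixels otherwise jitter
the scale from frame to frame, and that jitter leaks directly into the
estimated trajectory.

## Tracking

The joint energy is written as the convex combination
ω·E_icp + (1 − ω)·E_rgb (equivalent to the conventional E_icp + w_rgb·E_rgb
with w_rgb = (1 − ω)/ω), which makes the ICP-weight sweep a first-class
experiment; ω = 0.87 is the default operating point. Residuals of *both*
terms are divided by their median absolute value at the initial pose
(floors: 1 mm geometric, 1e-3 photometric). Scaling only the photometric
term, with the geometric term left in metres, makes the photometric normal
equations dominate any ω by a factor ~1/σ_I² — empirically ω = 0, 0.5 and
0.87 then converge to the same photometric optimum — so both are
normalised and ω genuinely interpolates between two dimensionless terms.

Gauss–Newton runs coarse-to-fine over a 3-level half-sampling pyramid
(10/5/4 iterations coarse→fine), Huber deltas 3 mm (geometric, in metres
before scaling) and 0.03 (intensity), projective data association with
compatibility gates (depth gap < 10 mm default, normal angle < 30°), a
per-step trust region (0.3 rad, 5 cm), Levenberg damping on energy
increase, and rejection of steps that lose the association; three
consecutive rejected steps end a level. Ill-conditioned normal equations
(condition number > 1e7, e.g. a textureless fronto-parallel plane whose
in-plane translation is unobservable) are flagged in the result rather
than silently returned.

## Surfel map

Fusion merges a frame pixel into an existing surfel when its
back-projection lands (within a 3×3 pixel neighbourhood of its projective
association — the depth buffer frequently hands a pixel to the surfel
splatted from the neighbouring cell) on a compatible surfel: point-to-plane
distance below the merge gate and normal angle < 20°. Merging is
confidence-weighted averaging with weight += 1; the radius never grows;
unmatched pixels insert. The merge gate is 5 mm for ground-truth-depth
runs and widened to 20 mm (with a 30° normal gate) for shading-depth runs,
matching the several-mm noise of per-frame shading depth — with the narrow
gate nothing merges, the map grows without bound and association collapses.

The splatted prediction z-buffers each surfel as a disc, with per-pixel
depth from the ray/disc-plane intersection rather than a constant disc
depth. This matters: constant-depth splats carry a fronto-parallel bias of
order (projected radius)·(slant), which accumulated into ~20° of
rotational drift on the loopy fixture before the correction (1.3° after).
Projected radii are clamped to [2, 5] pixels; ties in the depth buffer are
broken by the lowest surfel index, keeping renders deterministic.

The active window delta_t defaults to 10 s and is set to 2 s on the loopy
fixtures (8 s loops; the window must expire mid-loop for a revisit to be a
revisit). Inactive surfels are retained indefinitely.

## Deformation graph and loop closure

Graph nodes are a systematic subsample of surfels ordered by creation
time; node neighbours are the k = 4 nearest in that temporal order.
Influence weights are the k spatially nearest nodes with raw weights
(1 − d/d_max)², d_max the distance to the (k+1)-nearest node, explicitly
renormalised to sum to one (the raw weights do not in general, and
renormalisation is what makes a fresh graph an exact identity and global
rigid motions exact). Graph optimisation is damped Gauss–Newton over all
12 parameters per node with three energies: rotation pull ‖RᵀR − I‖²_F
(w_rot = 1), as-rigid-as-possible edge regularisation (w_reg = 10) and
point constraints (w_con = 100); only the rotation term is nonlinear, so a
handful of iterations converge, and accepted steps never increase the
energy.

Loop closure: a candidate exists when the splatted inactive model covers
≥ 30% of the frame's valid pixels. Registration reuses the joint
alignment between the active and inactive predictions with widened gates
(30 mm depth, 45° normal, 10 mm Huber) and two initialisations — identity
and a translation-only closest-point ICP — keeping the lower final energy.
Two lessons are baked in: a *full* rigid closest-point ICP slides along
the rotational near-symmetry of a sphere-like cavity (the cavity maps to
itself under rotations about its centre, so only texture pins rotation),
and the inlier fraction must be measured against attempted correspondences
(active pixels whose warp lands on inactive coverage), not the whole
frame. Acceptance requires residual RMS < 5 mm and inlier fraction > 0.6.
Constraints are sampled on an 8-pixel grid of inlier correspondences; the
graph is built over the *active* surfels only and only they are deformed —
with purely spatial influence weights, co-located active and inactive
surfaces cannot be told apart, so deforming everything would drag the
inactive reference along with the drifted surface. Inactive surfels inside
the corrected frustum are reactivated (t_last := now), the corrected pose
seeds the next frame, and closure never changes the surfel count. There is
no pose graph; global consistency comes from the deformation graph alone,
and the trajectory benefits only from the closure frame onward.

## Synthetic scenes

The generator emulates the recording conditions: a lobed star-shaped
cavity (icosphere with a smooth directional radius field, mean radius
5 cm), smooth per-vertex albedo mottling, optional radial deformation
schedule, co-located point light (inverse-square falloff optional, off by
default since the shading front-end assumes a distant light), optional
Phong highlight spots with per-frame ground-truth specular masks (specular
term > Lambertian term), Gaussian image noise, and scripted trajectories:
a slow open scan-arc and a closed loop whose view direction sweeps a full
turn so that early surface genuinely leaves the frustum and is revisited
at the end (the final pose re-equals the first exactly). Rendering is a
z-buffered rasteriser with perspective-correct interpolation whose depth
obeys the package's own projection model exactly (verified against an
independent ray-triangle oracle). Standard fixtures are 64×64 pixels,
60–80 frames, 70° field of view — sizes chosen so a full run takes tens of
seconds on one core.

What the fixtures do **not** emulate: real tissue reflectance (subsurface
scattering, fluid pooling), self-repetitive texture, vignetting and
photometric miscalibration, motion blur, rolling shutter, or peristaltic
deformation faster than the frame rate. Passing results demonstrate the
algorithms' correctness and their relative orderings under controlled
conditions, not clinical-grade accuracy.

The drift-injection experiment applies a single ~4.6 mm rigid pose offset
mid-run (a step, not a per-frame bias: frame-to-model tracking largely
absorbs a slowly accumulating bias back into the model, whereas a step
taken while mapping fresh surface persists until the loop closes) and
uses ground-truth depth, isolating the closure mechanism from
shading-depth noise.
The hemisphere shape-from-shading target is a Lambertian spherical bump
filling most of the frame — on a part-bump part-plane image the flat
region contributes only rank noise to the Spearman statistic while the
bump itself is recovered at ρ ≈ 0.94.

## Evaluation

ATE RMSE is the root-mean-square Euclidean distance between matched
camera centres (nearest timestamps within 20 ms), optionally after
least-squares rigid or similarity (Umeyama) alignment; similarity is the
default for full monocular runs, rigid for depth-oracle runs. Rotational
RMSE uses the geodesic angle. Surface RMSE rigid- (or similarity-) aligns
the reconstruction to the ground-truth mesh by point-to-point ICP and
reports the RMS of exact point-to-triangle distances (nearest-triangle
search over a centroid k-d tree).

## Known limitations

* Tracking has no relocalisation: a lost frame ends the run.
* Shading depth is reliable only up to a per-frame affine transform; the
  geometric term of the tracker treats it as metric within the widened
  gates, which is the dominant error source of full monocular runs.
* Conventional depth scale induces a rotation–translation ambiguity:
  full-pipeline runs show large absolute orientation drift (tens of
  degrees RMS) even when similarity-aligned positions are accurate to
  a few percent of path length; with ground-truth depth the same tracker
  recovers rotations to fractions of a degree.
* The deformation graph cannot separate interpenetrating surfaces (purely
  spatial influence), hence the active-only warping policy.
* Specular detection misses saturation on images whose global statistics
  are already bright (threshold capped at 1).
* The rasteriser ignores occlusion-aware shading (no shadows) and the
  renderer's highlights are view-dependent only through the co-located
  geometry.
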