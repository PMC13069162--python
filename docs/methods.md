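# Methods

`canalshape` builds a statistical shape model (SSM) of the proximal femoral
medullary canal from stacks of endosteal contours, measures five geometric
features per canal, evaluates the model's quality, and relates the model's
modes to the features. This note records the model, its assumptions, the
parameters that matter, and the numerical choices made where the design was
genuinely open.

## Input model and conventions

A specimen is a stack of 15–30 axial slices (5–10 mm apart), each a closed
polygon of ~50 endosteal perimeter points, plus metadata: sex, age, side,
femur length `L_femur` (mm), and the z-height `gt_z` of the greater-trochanter
(GT) landmark. Units are millimetres. z increases distal→proximal; +x is
pseudo-lateral, +y pseudo-anterior, so posterior = −y. Contours are stored
counter-clockwise viewed from proximal (+z); the source protocol does not fix
an orientation, so this one is enforced by a signed-area test on input.

## Preprocessing and correspondence

1. **Slice interpolation.** The stack is densified to 100 slices spanning
   [min z, max z]. Each slice is first resampled to the common 50-point
   parameterization (below); an output contour is the pointwise linear blend
   of its two bracketing input contours. How contours were blended during the
   original reslicing is not documented; correspondence-then-blend is this
   package's choice, and it is exact for geometries whose cross-section
   varies linearly between slices.
2. **Trimming.** The retained window is
   `z ∈ [gt_z − 0.321·L_femur, gt_z − 0.10·L_femur]`: the segment starts 10%
   of femur length distal to the GT and retains 22.1% of femur length
   (`L = 0.221·L_femur`). Boundary contours are synthesized by interpolation
   at the exact cut heights. Trimming happens before alignment, in the raw
   z frame.
3. **Mirroring.** Left femora are reflected (x → −x, point order reversed to
   restore the orientation convention) so all canals are right-sided.
4. **Centering and MVEE alignment.** The point cloud is translated so its
   centroid is at the origin, a minimum-volume enclosing ellipsoid (MVEE) is
   fitted, and coordinates are expressed in the ellipsoid's principal frame.
   This is a landmark-free orientation proxy (anatomical axes are
   unavailable without the distal femur). Axis assignment: the longest
   ellipsoid axis becomes z; the transverse pair goes to x and y so as to
   maximize absolute dot products with the incoming axes; each axis is
   sign-flipped if it opposes its old namesake; det = +1 is enforced by
   flipping y. Without these rules mode signs and x/y labels would be
   arbitrary. A consequence worth knowing: specimens whose transverse MVEE
   axis sits near the 45° diagonal can flip x/y assignment under small
   perturbations — the orientation standardization is only defined up to
   that convention. Near-isotropic ellipsoids (radii within 0.1%) keep the
   incoming frame, with a warning.
5. **Reslicing.** Alignment tilts the original CT planes, so 30 planar
   sections at uniform z are re-cut in the aligned frame, labeled 0 (distal)
   to 29 (proximal). Each tilted ring is first put into the common 50-point
   parameterization (carrying z per point); a cut section is the linear
   interpolation in z along each corresponded point trajectory, over the
   z-range common to all 50 trajectories.
6. **Correspondence.** Each section is resampled to 50 points on the
   periodic cubic spline through its points (chord-length parameterized,
   4096-sample arc-length tables): point 0 is the spline's crossing of the
   posterior (−y) ray from the section's polygon area centroid — for a
   non-convex section, the crossing farthest along −y, which is unique and
   stable for near-elliptical canals — and subsequent points sit at equal
   arc length, counter-clockwise. The area centroid (not the vertex mean) is
   used both here and for the centroid path, because it is invariant to
   uneven vertex spacing.

The result is a 30 × 50 × 3 point-correspondent shape per specimen.

### MVEE algorithm

Khachiyan-type barycentric ascent with away steps (Todd–Yıldırım) and
Kumar–Yıldırım initialization, capped at 10 000 iterations. Stopping: duality
gap ≤ tol·(d+1), or weight-change norm < tol (the stopping rule of the
standard reference implementation, default tol 1e-6), or stagnation of the
dual objective log det X(u) at float64 resolution for 100 iterations —
smooth, elongated clouds of several thousand points reach machine precision
before a 1e-6 duality gap. Whatever the stopping path, the returned ellipsoid
is inflated by the worst quadratic form so every input point is inside
exactly; the residual volume suboptimality at these tolerances is far below
anything the downstream alignment can resolve.

## Geometric features

Per section k = 0..29:

* contour area `A_k` (shoelace formula on the ordered perimeter points) and
  equivalent radius `r_eq = sqrt(A/π)`; the normalized radius is `r_eq/L`;
* roundness `MRI = a/b ≥ 1` from a direct least-squares ellipse fit
  (Halíř–Flusser partitioning of the Fitzgibbon conic fit — non-iterative,
  ellipse-specific, exact on noiseless samples);
* major-axis angle `φ` (degrees from +x, modulo 180°), a per-contour torsion
  proxy. φ sequences are unwrapped so successive jumps lie in (−90°, +90°];
  near-circular sections (MRI within 1e-3 of 1) have no meaningful axis and
  inherit the previous section's unwrapped value (0 for section 0), flagged.

Per specimen: mean `r_eq/L`, mean MRI, overall torsion `Δφ = φ_29 − φ_0`
(unwrapped; positive = counter-clockwise viewed from proximal), flare index
`max(r_eq)/min(r_eq)`, and curvature `1/R` of the least-squares sphere
through the 30 section area-centroids, reported dimensionless as `L/R`.

**Sphere fit.** The algebraic sphere system `[2x 2y 2z 1]·[c, R²−|c|²] = |p|²`
is solved in centered coordinates. A sphere through coplanar points is
ill-posed — any sphere containing their circle fits — and canal centroid
paths are planar to ~1e-5 mm, so an unregularized solve is dominated by
numerically meaningless out-of-plane structure. When the out-of-plane extent
is below 10% of the secondary in-plane extent, the points are projected onto
their best-fit plane and an algebraic Kåsa circle fit supplies the radius
(center constrained to the plane); otherwise the full system is solved.
Both branches are exact on their noiseless fixtures. Collinear centroids
(straight canal) return R = ∞ and zero curvature.

Features are computed on the aligned, *unscaled* shape: `r_eq/L` already
normalizes size, and the z-extent scaling below is a modeling step, not a
measurement step.

## Statistical shape model

Each shape is standardized — centroid to the origin, isotropic scale so the
z-extent spans 1 — and flattened to a 4500-vector (section-major,
point-minor, xyz). Standardization is deliberately *not* per-variable
unit-variance scaling, which would destroy the shape semantics of
coordinates; the z-normalization suppresses a global size mode, so leading
components are shape rather than size. PCA of the n × 4500 matrix uses SVD
of the centered data (or, for n ≪ 4500, the equivalent n × n Gram
eigen-decomposition), eigenvalues are sample variances (divisor n−1), and
each eigenvector's sign is fixed so its largest-magnitude entry is positive,
making synthesized figures reproducible. Scores are `υ_iᵀ(x − μ̄)`; shapes
are synthesized as `μ̄ + Σ c_i·sqrt(λ_i)·υ_i` with coefficients in SD units
(|c| ≤ 3 by default). Three components are retained by default
(scree/elbow); the count is configurable.

## Model evaluation

* **Specificity.** 1000 synthetic shapes with coefficients drawn uniformly
  and independently in [−2, +2] SD along the first three modes (the bounded
  "within ±2 SD" sampling does not specify a distribution; uniform is this
  package's choice). Each sample's nearest-neighbor Euclidean distance (full
  4500-vector norm) to the training set is compared with the leave-one-out
  real-to-real baseline; the headline number is the fraction of samples
  beyond the real 95th percentile (linear-interpolation percentile
  estimator). All distances are stored so the fraction is recomputable.
* **Generalization.** 10-fold cross-validation (seeded shuffle, near-equal
  folds): fit on 90%, project the held-out 10% on the retained modes,
  reconstruct, and record scaled MSE = mean over shapes of
  (squared residual norm / 4500) — a per-coordinate variance in
  standardized space — for both training and held-out rows.

Both reports are fully reproducible from (cohort, seed, config).

## Score-versus-feature regression

Each specimen-level feature is regressed on each retained PC score by simple
OLS (feature = intercept + slope·score, scores in raw units), reporting R²,
the two-sided p of the slope (t statistic, n−2 df) and its 95% CI, as a
5-feature × 3-PC table. A constant feature yields slope 0, R² 0, p 1,
flagged, rather than aborting the table. The regression direction and score
units are recorded in the table metadata; with scores in other conventions
the slopes and CIs rescale while R² and p are unchanged.

## Synthetic canals: what they emulate, and what they do not

Real canal data are not publicly available, so a parametric generator
supplies cohorts with exact ground truth. Cross-sections are ellipses with
area-preserving aspect ratio (semi-axes `a = r√ρ`, `b = r/√ρ` — the key
device that makes `r_eq` and MRI independently controllable and ground
truth exact), equivalent-radius profile `r(t) = r0·(1 + (F−1)·h(t))` with
the smoothstep `h(t) = 3t² − 2t³`, linear twist `φ(t) = φ0 + Δφ·t`, and
section centroids on a circular arc of radius `R_c` in the x–z plane with
sections kept perpendicular to z (matching the planar-section pipeline and
keeping the sphere-fit truth exact for small `L/R_c`). Slices extend beyond
the trim window with constant-profile margins, and GT sits so the generated
segment is exactly the retained window, so trimming is genuinely exercised.
Generation is deterministic given the parameters; the seed drives only point
noise.

Default study conditions (chosen once as realistic for a THA-age cohort and
not revisited): femur length 420 ± 25 mm, distal equivalent radius
7 ± 0.8 mm, flare 1.6 ± 0.15, roundness 1.3 ± 0.1, twist 15 ± 5°, centerline
radius 1000 mm, slice spacing uniform in 5–10 mm, in-plane contour noise
0.3 mm (CT in-plane pixels are ~0.7–1 mm and semi-automatic spline
segmentation is good to roughly half a pixel). Three-factor experiments fix
twist and femur-length spread at zero so exactly r0, ρ and F vary.

What the generator does **not** emulate: trochanteric/calcar detail (no
lesser-trochanter bulge), non-elliptical cross-sections, within-specimen
profile irregularity, density, or biologically structured sex/age effects
beyond optional mean offsets. Passing tests therefore demonstrate that the
pipeline measures what it claims on smooth canal-like geometry and that the
model algebra is correct — not that anatomical canals are elliptical, nor
that real-cohort variance splits the way the synthetic one does.

For cohort-scale model experiments the generator can also emit idealized
corresponded shapes directly (30 analytic sections, no preprocessing); the
preprocessing chain's fidelity is validated separately on full stacks, where
noiseless recovery of flare/roundness/curvature is within 2% and twist
within 0.5°.

The regression-recovery experiment uses a single radius factor plus
measurement error on the feature calibrated so the population R² is exactly
the target (0.9): with only coordinate noise instead, the high-dimensional
PCA estimation error (spiked-covariance eigenvector rotation at p/n ≈ 15)
would shift the realized R² well below any closed-form coordinate-noise
calibration, making the target ill-defined.

## Problem sizes and numerical tolerances

Worked-example sizes: one specimen end-to-end in well under a second;
spectrum/specificity cohorts n = 300, cross-validation n = 500, regression
recovery 50 seeds × n = 300. MVEE tol 1e-6 (cap 10 000 iterations);
spline arc-length tables 4096 samples (equal-arc spacing good to ≪0.1%);
eigenvector orthonormality and full-rank reconstruction hold to 1e-8;
collinearity/coplanarity thresholds as above; percentiles use NumPy's
linear-interpolation estimator.

## Known limitations

* The MVEE frame is a proxy, not an anatomical frame; alignment choices are
  known to reorder early modes, so spectra are comparable only within one
  alignment convention. The x/y assignment can flip for specimens near the
  45° transverse diagonal.
* φ is an ellipse-orientation proxy for torsion, undefined at circular
  sections; Δφ through near-circular regions depends on the inheritance
  rule.
* The interchange formats carry one contour per slice; multi-contour slices
  (e.g., at the trochanteric fossa) are out of scope, as are DICOM reading,
  segmentation and surface meshing.
* Self-intersecting contours are not detected; garbage contours produce
  garbage features.
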