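# Methods

`homoshape` implements homologous-model statistical shape analysis for
populations of watertight anatomical surface meshes. The pipeline follows
the protocol used in CT-based skeletal morphometry: a fixed-topology
template is deformed onto every specimen so that vertex indices become
anatomically comparable, and the population of corresponded vertex
coordinates is analyzed by PCA, ROC-based group discrimination, virtual
morphs and angle correlations.

## The homologous-model construction

Raw surface meshes of different specimens share no vertex correspondence,
so they cannot be compared coordinate-by-coordinate. Correspondence is
established by registering a template mesh (vertices `v0`, fixed topology)
onto each specimen in three stages:

1. **Landmark similarity alignment.** The closed-form least-squares
   similarity transform (rotation, translation, uniform scale; reflections
   forbidden) mapping the template's named landmarks onto the specimen's.
   Requires at least three non-collinear shared landmark names.
2. **Rigid ICP refinement.** Iterative closest point with
   vertex-to-surface pairing and closed-form rigid updates at the fixed
   similarity scale; the mean residual is non-increasing and iteration
   stops when it changes by less than `icp_tol` (default 1e-5 mm).
3. **Non-rigid fitting.** Template vertex positions `v` minimize

   ```
   E(v) = w_sm ||L (v - v0)||^2  +  w_lm sum_a ||v_a - l_a||^2
        + w_d  sum_i ||v_i - c(v_i)||^2
   ```

   where `L` is the row-normalized uniform graph Laplacian of the
   template, `l_a` the specimen landmarks, and `c(v_i)` the current
   closest point on the specimen surface. Each outer iteration refreshes
   the closest points and solves one sparse SPD system per coordinate.
   The smoothness weight follows a non-increasing schedule (default
   100, 10, 1, 0.1) with the landmark weight held at 10 and the data
   weight at 1.

Three implementation details matter for correspondence quality and are
deliberate design choices:

* **Barycentric landmark coupling.** Landmarks act on the barycentric
  combination of their containing template triangle, not on the nearest
  vertex. Nearest-vertex snapping mis-places the constraint by up to half
  an edge length and visibly distorts the deformation field around every
  landmark.
* **Landmark-harmonic initialization.** The closest-point loop starts
  from the minimizer of the smoothness + landmark terms alone (the
  "harmonic warp" of the rigid alignment). The data term is blind to
  motion tangential to the surface: started from the raw rigid pose, it
  anchors the template's tangential positions before the landmark
  information can propagate, and mode amplitudes are recovered at only
  ~0.4-0.6 of their true size. With the harmonic start, recovery slopes
  are 0.98-1.00.
* **Pair rejection.** Closest-point pairs farther than 5x the current
  median, or whose surface normals oppose the template's (far side of a
  thin structure), are dropped from the data term for that iteration.

The **fit residual** reported per specimen is the mean +/- SD over
template vertices of the directed vertex-to-surface distance (mm) to the
original specimen mesh — directed model-to-target, since the reverse
direction is not defined for the template's vertices. On synthetic
specimens it is typically 0.03-0.06 mm (~0.02% of the bounding-box
diagonal), far below the ~0.3% reported for commercial template fitting
on real CT surfaces, because the synthetic targets are exactly the kind
of smooth surface the energy prefers.

## Template construction

The template is built from a subset of specimens (controls by
preference): all are placed in the anterior-pelvic-plane frame, the
reference specimen (index 0, for determinism) is non-rigidly fitted onto
each of the others, the homologous vertex sets are averaged
coordinate-wise, the average is symmetrized about the sagittal plane
(each vertex moves halfway to its closest point on the x-reflected
surface) and isotropically remeshed to the configured vertex count, and
landmarks are projected onto the final surface. Averaging precedes
mirroring, which precedes remeshing; a single pass is performed, not an
iterative atlas build.

**APP frame.** Origin at the midpoint of the left/right anterior-superior
landmarks; +X from the right to the left one; the plane through those two
and a midline anterior-inferior landmark becomes the X-Z (coronal) plane
with +Z superior; +Y anterior, right-handed. The defining landmark names
are schema-configurable (defaults `L_ASIS`, `R_ASIS`, `PS`).

**Isotropic remeshing** is the classic explicit scheme: per iteration,
edges longer than 4/3 of the target length are split at their midpoint,
edges shorter than 4/5 are collapsed subject to the link condition (plus
guards against creating over-long edges or zero-area faces), edges are
flipped when that moves vertex valences toward 6, and vertices are
tangentially smoothed and re-projected onto the input surface. The target
edge length is set from the surface area and requested vertex count and
adjusted until the output is within +-5% of the target. Typical
edge-length coefficient of variation after four iterations: 0.10-0.13.

## Size normalization and PCA

Each homologous model is translated so its centroid matches the
template's, then scaled by the closed-form optimum
`s* = sum(x_i . t_i) / sum(x_i . x_i)` (centered coordinates), the global
minimizer of the summed squared vertex distance to the template. The
template — not the evolving sample mean — is the normalization target.

PCA is computed by SVD of the mean-centered n x 3V matrix; score
variances use divisor n-1, and `SD_j = sqrt(lambda_j)` so "+/-3 SD"
morphs have the usual sample-statistics meaning. A component's
contribution ratio is `lambda_j / sum(lambda) * 100%`. The number of
components defaults to the smallest k whose cumulative ratio reaches 80%,
capped at n-1. PCA signs are arbitrary and are pinned deterministically:
each component is oriented so that its largest single-vertex displacement
points toward +Z (superior), with +Y then +X breaking exact ties.

Virtual morphs reconstruct `mean + k*SD_j*component_j` on the template
topology; the +/-3 SD pair brackets essentially the whole population
range along a mode.

## Group discrimination

Per component, cases are labelled 1 and controls 0. The AUC is computed
in the Mann-Whitney form (probability a random case outscores a random
control, ties counting one half) — by exhaustive pair counting for
moderate sample sizes and by the algebraically identical rank formula for
large ones; the ROC curve itself is swept over unique score values via
scikit-learn and its trapezoidal area equals the pair-count AUC to
machine precision.

Significance against AUC = 0.5 uses a chi-squared statistic
`((A - 0.5)/SE)^2` with one degree of freedom, where SE is the
Hanley-McNeil standard error (`Q1 = A/(2-A)`, `Q2 = 2A^2/(1+A)`). The
reference protocol names only "a chi-squared test (null 0.5)" without a
formula, so exact p-value parity with its (closed-source) software is not
claimed; under the null the test rejects at 4-6% at the 5% level in 500
replicates at n = 50/50. No multiple-testing correction is applied across
components, mirroring the reference protocol; readers should treat
borderline p-values across ~20 components accordingly.

Significance stars in the report are `*` for p < 0.05 and `**` for
p < 0.01.

## Angles and correlations

Anatomical angles are measured on each homologous model from
landmark-indexed vertices (transferred via the template's barycentric
embedding, so the same loci are measured on every specimen): the model is
placed in its own APP frame, optionally rotated by a configurable
functional-frame rotation, each angle's two lines are projected onto a
named plane (coronal/sagittal/horizontal), and the planar angle is taken
— unsigned acute for line pairs, full 0-180 degrees for ray pairs such as
the ischiopubic angle at the symphysis. The shipped schema (sharp angle
and iliac-wing angle per side, sacral slope, pelvic inclination,
ischiopubic angle) is a documented stand-in keyed to the synthetic
landmark names and is fully configurable via YAML. With the default
functional frame equal to the APP frame, pelvic inclination is
identically zero and its correlations are reported as missing — the same
degeneracy the reference protocol acknowledges for APP-aligned cohorts.

Correlations between PC scores and angles are Pearson's r (signed, with
an option for |r|), computed on specimens matched by id; zero-variance
columns are reported missing with a warning.

## The synthetic world

No real CT cohort ships with the package; the generator emulates the
study design with a fully known ground truth.

* **Base shape.** An implicit surface blending three lobes — two lateral
  "coxal" lobes and one posterior-central "sacral" lobe — each a cluster
  of anisotropic Gaussians: a plate-like main body, ridge/process bumps,
  bridge arms (pubic rami, sacroiliac joints) joining the lobes into one
  watertight body, and deterministic alternating surface relief. The
  relief is not decoration: a smooth featureless blob is rotationally
  ambiguous, and no registration method could recover tangential motion
  on it; real bone carries ridges and fossae. Mirror symmetry about x = 0
  is exact in the implicit field. Overall extent is ~260 mm, adult-pelvis
  scale.
* **Landmarks.** 58 named points — matching the dense landmark protocols
  used with commercial template-fitting software — located analytically
  as ray-isosurface intersections (Brent root finding on the field), so
  their positions are independent of any mesh. Left/right pairs and
  midline points are recorded in the symmetry schema.
* **Deformation modes.** Three smooth, spatially weighted fields chosen
  to mimic reported dysplasia-associated differences: (A) opposite-sense
  coronal rotation of the lateral lobes about the anteroposterior axis,
  (B) sagittal rotation of the sacral lobe, (C) smoothly weighted
  mediolateral scaling of the superior part. Each is normalized at run
  time to exactly 1.0 mm rms surface displacement per unit score, so
  score SDs are in mm and score variances map directly onto PCA
  eigenvalue ratios. All mode fields are multiplied by a mask that
  vanishes (Gaussian radius 18 mm) at the three APP-frame landmarks:
  without it, per-specimen APP alignment converts each mode into an
  additional global rotation proportional to its score, and the leading
  "mode" of the population is a frame artifact with several-fold inflated
  variance. Amplitudes are bounded (45 degrees of weighted rotation, 50%
  scaling) as a checked — not proven — injectivity guard.
* **Population defaults (the stated world).** Two groups of 50; mode
  score SDs (3, 2, 1) mm — variance ratio 9:4:1; a case-group mean shift
  of +6 (two SDs) on mode A only; smooth surface noise of 0.2 mm
  (a few-kernel Gaussian random field, emulating residual
  segmentation/reconstruction error, applied consistently to surface and
  landmarks); pose jitter of +-10 degrees, +-20 mm, +-5% scale;
  ~1,600 vertices per specimen. Each specimen is polygonized on its own
  jittered marching-cubes grid (random resolution +-8% and origin
  offset), so no two specimens share vertex count or correspondence —
  remeshing independence is realized on the base surface *before* the
  smooth deformation/noise/pose maps are applied to vertices and
  landmarks, which is equivalent in effect to remeshing the deformed
  surface and avoids implicitizing the deformed shape.
* **Reproducibility.** One seed per population; per-specimen generators
  are spawned by counter from a `SeedSequence`, so outputs are
  independent of generation order.

What the generator does **not** emulate: anatomical realism of the
pelvis (the proxy has no acetabula, foramina or cortical detail), CT
acquisition/segmentation artifacts, asymmetric pathology, and outlier
specimens. A green pipeline on this world demonstrates that the method
recovers known smooth deformation modes and group differences from
independently meshed surfaces; it does not certify performance on
clinical segmentations.

## Known limitations

* **Tangential correspondence between landmarks is information-limited.**
  The closest-point data term constrains only surface-normal motion;
  tangential correspondence comes from the 58 landmarks interpolated
  by the biharmonic smoothness operator. The resulting per-mode field
  error is ~0.3-0.6 mm rms against 2-3 mm mode amplitudes, i.e. the
  estimated mode *directions* in vertex space deviate by ~6-12 degrees
  from the analytic fields even in the noiseless single-mode setting, and
  by more for the smallest mode once population nuisance variance (noise,
  discretization, residual frame wobble) mixes in — even though mode
  *scores* are recovered with |r| > 0.97 and amplitudes within a few
  percent. This is a property of the energy family itself, not of its
  tuning: it was insensitive to mesh resolution, surface relief and
  Laplacian connectivity in ablations. Denser landmark protocols would
  tighten it. One acceptance test asserts a 5-degree subspace recovery
  and is expected to fail; it is kept as an honest record of this limit.
* Fit quality assumes watertight, hole-free targets (a warning is issued
  otherwise); partial or defective surfaces are out of scope.
* The chi-squared AUC test relies on the Hanley-McNeil normal
  approximation; at very small n or AUC near 0 or 1 its p-values are
  approximate (perfect separation reports p = 0).
* ICP convergence is to a local optimum; the landmark similarity
  initialization makes this benign for anatomically plausible poses but
  adversarial initializations can still mis-converge.
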