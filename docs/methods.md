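# Methods

This note documents the models, conventions and numerical choices behind
`fetalbiom`, the assumptions they rest on, and what the synthetic-phantom
validation does and does not show about real data.

## Measurement model

### Coordinate conventions

Volumes are held as `(slice, row, column)` integer grids with the slice axis
coronal (anterior–posterior); rows run superior → inferior and columns
across the head. NIfTI inputs are permuted/flipped into this frame from
their header orientation at load time. Spacing is `(slice pitch, row,
column)` in mm; the slice pitch (thickness + gap, 3–5 mm in typical fetal
SSFSE stacks) is a single number and never enters width computations — all
calipers are strictly in-plane, which matches how the measurements are
defined clinically and keeps the strongly anisotropic through-plane
resolution out of the geometry.

Left/right ventricle labels are taken at face value from the segmentation;
determining fetal laterality from maternal anatomy is out of scope.

### Principal axis

The "main direction" of a mask is the first principal component of its
foreground pixel-center coordinates in mm. PCA is deterministic, standard,
and coincides with the anatomical superior–inferior axis whenever the
structure is taller (in-plane) than it is wide. The sign convention keeps
the row component nonnegative, so "superior" is always the smaller axial
offset. Perfectly isotropic masks (principal extents equal to within 1e−9
relative) fall back deterministically to the row axis with anisotropy
ratio 1 — for an isotropic structure any perpendicular width is the
diameter, so the fallback is harmless. Masks with fewer than two foreground
pixels are degenerate and rejected.

### Distance profile and caliper convention

Foreground pixels are projected onto the axis and its perpendicular. Axial
positions are binned at pitch `step_mm` (default: the minimum in-plane
spacing) with half-open bins `[t − step/2, t + step/2)`; empty bins are
omitted. The width at a bin is the **span of the extreme pixel centers plus
one in-plane pixel extent**:

* Span of extremes, not the longest contiguous run — internal holes
  (annotation gaps, the cavum) must not split a diameter.
* The added pixel extent implements the outer-edge convention of clinical
  calipers: a center-to-center span systematically under-reads by one
  pixel. The extent of a pixel along the perpendicular unit vector *v* is
  defined as `sqrt((v_r·s_r)² + (v_c·s_c)²)`, which equals the perpendicular
  spacing for axis-aligned masks and stays one pixel for rotated axes. The
  alternative — projecting the full pixel footprint, `|v_r|s_r + |v_c|s_c` —
  over-reads by up to ~40% of a pixel at 30–45° rotation, because rotated
  lattices sample the boundary densely; the chosen definition keeps the
  measurement error near zero-mean across rotations.

A measurement is the profile maximum, optionally restricted to a fraction
of the axial extent measured from the superior end. Because a bin
represents an interval, bins overlapping the restriction window are
included (half-bin tolerance at the boundary); ties are always broken
toward the most superior position, and across slices toward the smallest
slice index, making every result deterministic.

### The four measurements

* **CBPD** searches the superior fraction (default 0.5) of every slice
  containing cerebrum and takes the global maximum. The superior-half rule
  is the standard proxy for "above the Sylvian fissure"; the fissure itself
  is not detected. The fraction is configurable.
* **TCD** is the unrestricted maximum over all slices containing
  cerebellum.
* **LAD/RAD** are measured on a single atrial slice only, per the clinical
  definition (inner atrial width perpendicular to the ventricle's long
  axis at the atrial level), not as a maximum over slices. The atrial slice
  is located by default as the slice maximizing combined left+right
  ventricular area — clinically, the atrium is the widest ventricular
  level, so the area peak is a robust surrogate. A template-correlation
  locator (normalized cross-correlation after centroid alignment with a
  user-supplied template mask) is available behind a configuration flag for
  cohorts where an atlas-like template exists; no default template is
  shipped. The caliper measures label pixels edge-to-edge; with masks
  annotated to the inner ventricular wall this realizes the clinical
  "inner diameter".

Output values are rounded to 0.01 mm in CSV reports; internal arithmetic is
unrounded.

## Synthetic phantom

The phantom generator is the package's test oracle: every structure is a
(rotated) ellipsoid voxelized by its implicit inequality at voxel centers,
so every true diameter is closed-form and independent of voxelization.

* **Anatomy.** A large cerebrum ellipsoid; a smaller cerebellum placed
  inferior along the (rotated) body axis with a 4 mm gap; two elongated
  ventricles inside the cerebrum, tilted ±25° from the body axis, offset
  laterally by 38% of the cerebral transverse half-axis. Ventricle labels
  override cerebrum where both inequalities hold, honoring the annotation
  rule that the ventricular system is excluded from the cerebrum label.
  Overlap of cerebellum with cerebrum, or a ventricle escaping the cerebral
  envelope, is a specification error, not silently resolved.
* **Shape vs. realism.** Each structure's in-plane superior–inferior
  half-axis exceeds its transverse half-axis (cerebrum ×1.25, cerebellum
  ×1.3) so that the PCA axis is the anatomical SI direction and the
  perpendicular caliper reads the transverse diameter. A real cerebellum is
  wider than tall; the measurement operators consume only mask geometry, so
  this idealization affects nothing but the phantom itself. Cortical
  folding, MR intensities, motion artifacts and pathological shapes are
  deliberately absent.
* **Truth.** CBPD = 2 × cerebral transverse half-axis; TCD = 2 ×
  cerebellar transverse half-axis; LAD/RAD = the per-side ventricular short
  diameter; the atrial slice is the argmax of the analytic combined chord
  area over slice positions (ties → smallest index). Rotation and noise
  never change the truth.
* **Boundary noise** is a radial perturbation of each surface by a seeded
  smooth field (seven low-order angular harmonics of the surface direction,
  rescaled so its maximum absolute value equals the requested amplitude,
  supported up to 2 mm). Smoothness keeps masks simply connected; the fixed
  2 mm bounding-box allowance keeps grids voxel-aligned across noise
  settings so noise effects can be isolated.
* **Growth defaults** map gestational age (21–38 weeks) to sizes:
  CBPD(GA) = −0.08·GA² + 7.6·GA − 80 mm (≈ 56 mm at 24 w, 76 mm at 30 w,
  92 mm at 37 w, decelerating from ≈ 3.8 to ≈ 1.7 mm/week — the
  decelerating pattern that makes a quadratic the best-fitting growth
  model) and TCD(GA) = −0.01·GA² + 2.4·GA − 24 mm; both strictly increasing
  over the supported range. The ventricular short diameters are
  GA-independent at 6.44 mm (left) and 5.88 mm (right) — atrial width is
  clinically stable through the second and third trimesters at ≈ 6 mm,
  with the left atrium ≈ 0.5–0.6 mm wider than the right. The demo cohort
  adds per-case anatomical variability: 3% multiplicative jitter on
  cerebrum/cerebellum size and between-case atrial SDs of 1.8/1.65 mm.

**What phantom validation shows — and does not.** Passing the recovery
suite (all four measurements within max(2 × in-plane spacing, 1.5% of
truth) across sizes, rotations, spacings and noise) demonstrates that the
geometric operators are correct, unbiased to sub-voxel level, and robust to
orientation and boundary roughness. It does not demonstrate performance on
real anatomy: real cerebral contours are folded, ventricles are crescent-
shaped rather than elliptical, and upstream segmentation errors dominate in
practice. The package measures masks; the quality of the masks is the
caller's responsibility.

## Statistics

* **Differences** are everywhere automatic − manual (test − reference), so
  an under-reading algorithm has negative mean difference.
* **Limits of agreement** use the conventional large-sample 1.96 multiplier
  rather than a t quantile.
* **ICC** is ICC(2,1) — two-way random effects, absolute agreement, single
  measurement — the standard form for method comparison, computed via
  pingouin and cross-checked in the tests against the ANOVA formula.
* **Dice** is reported per label plus a pooled lateral-ventricle value
  (both sides as one foreground set); empty-in-both is 1, empty-in-one is 0.
* **Degree selection** for growth curves compares OLS fits of degrees
  {1, 2, 3} by BIC with ties toward the lower degree. Plain R² is monotone
  in degree; adjusted R² admits a spurious extra term whenever its
  F statistic exceeds 1, which happens with probability ≈ 0.32 under the
  null regardless of sample size, so neither criterion yields a stable
  verdict. BIC's ln(n) penalty selects the true quadratic ≥ 90% of the
  time on noisy-quadratic cohorts while still preferring a line for linear
  data. R² and adjusted R² are reported on every fit.
* **Conditioning.** GA is centered and scaled before polynomial fitting;
  coefficients are back-transformed to the natural GA scale for reporting.
  Fits are reproducible to ~1e−8 of a raw-power normal-equations solution
  (which is itself the conditioning bottleneck at degree 3).
* **Quartiles** in the reference tables use linear interpolation on the
  sorted sample (quartiles of {1,2,3,4} are 1.75 and 3.25); weeks with
  fewer than `min_n` cases (default 5) are flagged excluded rather than
  dropped, conserving total n.
* **Degenerate inputs** are handled explicitly: constant sequences make
  correlations (and ICC) undefined — flagged, with mean difference and
  limits still returned; zero-variance paired differences with nonzero mean
  yield an infinite t statistic with a degeneracy flag; prediction outside
  the fitted GA range is permitted but flagged as extrapolation.

## Problem sizes

The validation suite uses sizes chosen to exercise the stated conditions
while staying light: 50 recovery phantoms (CBPD 60–110 mm, ±30°,
0.5–1.0 mm in-plane, ≤ 0.5 mm noise), 200 model-selection cohorts of
n = 250, 500 coverage replicates with 4 held-out observations each, and
demonstration cohorts of 2–6 cases per gestational week at 0.5 mm in-plane
spacing. The acceptance script mirrors these sizes.

## Known limitations

* The atrial-slice locator assumes the segmentation's ventricular area
  peaks at the atrial level; severe ventriculomegaly with dilated horns
  could shift the peak.
* The CBPD superior-fraction rule approximates the Sylvian fissure level;
  on atypical anatomy the configurable fraction may need adjustment.
* Widths are outer-edge pixel calipers; sub-pixel contour interpolation is
  deliberately not attempted, so single-measurement accuracy is limited to
  about one in-plane pixel.
* Only coronal 2D measurements are implemented; axial (head circumference)
  and sagittal (corpus callosum, vermis, brainstem) biometry and volumetry
  are out of scope, as are DICOM ingestion, intensity images and
  registration.
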