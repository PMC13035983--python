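# Methods

This note records the models, conventions and numerical choices behind
`labyrinthometry`, and what the synthetic phantoms do and do not establish
about real data.

## Problem setting

The bony inner ear comprises five substructures segmentable on
ultra-high-resolution CT of the temporal bone: the cochlea, the vestibule,
and the posterior/lateral/superior semicircular canals (PSC/LSC/SSC). The
package measures, from a labeled voxel volume (nominally 0.1 mm isotropic):

* cochlear size — volume, basal long/short diameter (BLD/BSD), cochlear
  height (CH), and regression-derived duct lengths (CDL, 2TL, BTL);
* cochlear orientation — the modiolar axis and its angles to the three
  canal planes;
* vestibular size and orientation — voxel volume, the principal diameters
  A ≥ B ≥ C of a least-squares ellipsoid, the three central cross-section
  areas, and the nine angles between the ellipsoid's central planes
  (AB/AC/BC) and the canal planes.

These metrics support case–control comparisons in Menière's disease, where
cochlear height and several inter-structure angles differ between affected
ears, unaffected ears and controls, and some angles track the ordinal
severity of endolymphatic hydrops (EH).

## Coordinate conventions

Voxel centers are at `origin + (index + 1/2) · spacing` with 0-based
indices; `origin` is the corner of voxel (0,0,0). NIfTI affines address
voxel centers directly, so the half-voxel shift is applied symmetrically on
read and write and lives in exactly one module (`volume_io`). All
measurement operates on millimetre voxel-center coordinates.

## Cochlear measurement chain

1. **Spatial calibration.** PCA of the cochlear voxel coordinates defines
   the cochlear coordinate system: the spiral lies in the plane of the
   first two principal axes and the third (least-variance) axis is taken as
   the modiolar axis. PCA sign ambiguity is resolved by flipping each axis
   so its largest-magnitude component is positive, then restoring
   right-handedness via the third axis; every scalar metric downstream is
   invariant to the underlying ± ambiguity (angles are folded, distances are
   symmetric), and an optional `basal_plus_x` flag instead orients +x toward
   the larger in-plane extreme so the basal turn lands on positive x
   deterministically under arbitrary pose.
2. **Round window.** In the planar coordinates the point with the largest
   x-coordinate; exact ties broken by largest y.
3. **BLD.** The largest distance from the round-window point to any planar
   point (first point encountered wins exact ties). On densely sampled
   convex sets this agrees with the true maximum chord to within sampling
   resolution (pinned by a brute-force all-pairs oracle in tests).
4. **BSD.** Coordinates are rotated so the round-window → far-point line is
   the +x axis; x is binned (default bin = voxel spacing, since continuous
   coordinates almost never coincide exactly) and BSD is the largest
   y-extent within any bin holding ≥ 2 points. Halving the bin on dense
   data moves BSD by less than two bin widths.
5. **CH.** Default is the full axial extent max(Z) − min(Z) of the
   calibrated coordinates, which matches reported cochlear heights of
   ~4 mm. The literal form max|Z| − min|Z| is retained as
   `mode="absolute"`; with centered coordinates it returns roughly half the
   extent and exists only for fidelity experiments.
6. **Duct lengths.** CDL = 4.16·BLD − 4, 2TL = 3.65·(BLD − 1),
   BTL = 2.43·(BLD − 1). The CDL slope is sometimes quoted negated, which
   would make every length negative; the package refuses that literal form
   with an explanatory error rather than silently producing it. BLD ≤ 1 mm
   is rejected.
7. **Modiolus–canal angles.** Each canal is summarized by a total
   least-squares plane (normal = smallest-eigenvalue eigenvector; no
   privileged axis, hence orthogonal rather than z-regression). The angle
   between the modiolar axis and each canal normal is folded to [0°, 90°],
   consistent with all reported inter-structure angles being ≤ 90°.

## Vestibular measurement

The vestibule is approximated by an ellipsoid. The printed linearized form
A'X + B'Y + C'Z = 1 (X = x², …, A' = 1/a²) has no cross terms, i.e. it
presumes an axis-aligned ellipsoid; the package therefore rotates the
points into their PCA frame first and fits the 3-coefficient form by
ordinary least squares. A 9-parameter general quadric (cross and linear
terms, eigendecomposition of the quadratic form) is available behind
`model="general"` for sensitivity analysis. Nonpositive solved coefficients
raise a "non-ellipsoidal fit" error.

**Surface sampling.** Fitting all solid voxels biases the semi-axes low by
~15% (interior points pull the algebraic fit inward), so the fit uses
surface-representative samples. Boundary-voxel *centers* lie on average
half a voxel inside the true surface, which still biases the smallest
diameter by about −4% at 0.1 mm spacing; the default therefore samples the
*midpoints of exposed voxel faces* (faces whose 6-neighbor is outside the
structure). These straddle the surface symmetrically, cancelling the
half-voxel bias to first order; the measured diameter error on voxelized
phantoms is ≤ 0.3%, versus the ≤ 2% budget. `surface_centers` and `solid`
sampling remain selectable, and a test pins the bias ordering. Because
posed clouds are not axis-aligned, the extractor first recovers the voxel
lattice axes from face-neighbor displacement directions (pairs at exactly
one spacing), indexes the occupancy in that lattice, and emits midpoints
along the true lattice directions — making surface extraction rigid-pose
invariant.

Diameters are full axes (2× semi-axis), matching reported vestibular
lengths (C ≈ 2.2 mm ≈ twice a ~1.1 mm semi-axis). Central-section areas are
π/4 × the product of the two spanning diameters; plane AB's normal is the
C-axis direction (AC ↔ B, BC ↔ A), and plane–canal angles are folded to
[0°, 90°]. The reported vestibular *volume* always comes from the voxel
count (N × spacing³), never from the fit.

## Synthetic labyrinth phantoms

The phantom generator replaces segmentation output with voxelized shapes of
known geometry; it exists to test the measurement chain, not to model
anatomy exactly.

* **Cochlea** — a conical helical tube: an elliptical spiral centerline
  (radius constant over the basal turn, then tapering linearly to the
  apex) swept by a circular tube whose radius tapers from 0.92 mm to
  0.55 mm. Defaults: BLD 9.0 mm, BSD 6.5 mm, height 4.0 mm, 2.5 turns —
  the adult scale, giving a voxel volume of ~77 mm³ (the reported cochlear
  scale is ~75 mm³). The constructed basal diameters are exact because the
  taper and the two orientation modulations below vanish at the diameter
  extremes, and the axial extent is rescaled to the requested height.
  A raw conical helix has nonzero cov(y, z) and cov(x, y) second moments
  (the axial advance couples to the sin φ in-plane term within every turn),
  which would tilt the principal axes ~5° away from the construction frame
  and defeat PCA-based recovery. The generator therefore solves two small
  modulation amplitudes — a turn inclination ∝ sin φ and an in-plane radial
  modulation ∝ sin 2φ — by Newton iteration on the covariance of a coarse
  (0.2 mm) voxelization, zeroing both cross-moments. With them the
  least-variance axis of the voxelized tube aligns with the constructed
  modiolar axis to ~0.4°, and recovery errors are: BLD 0.08 mm, CH
  0.13 mm, planar round-window position 0.07 mm. The analytic ground-truth
  tube volume uses the swept-tube line integral, which overcounts near the
  apex where the tube radius exceeds the centerline curvature radius; it is
  accurate to ~5–10% and the voxel count is the operative volume.
* **Vestibule** — a solid ellipsoid, default semi-axes 3.07/2.295/1.095 mm
  (diameters at the reported adult scale), optionally perturbed by a
  smooth random radial field (fixed quadratic directional basis with
  seed-drawn coefficients, normalized to a requested RMS amplitude in mm).
  Note a pure ellipsoid with these diameters has volume 32.3 mm³, whereas
  real vestibules (which are not ellipsoids) show voxel volumes near
  54 mm³; the phantom cannot exhibit both numbers at once, and the cohort
  simulator draws volumes at the realistic scale directly.
* **Canals** — partial tori (default major radius 2.8 mm, minor 0.6 mm,
  3/4 arc) lying exactly in configurable planes. Default plane normals put
  the modiolus–LSC/PSC/SSC angles near the reported adult means
  (58°/74°/41.5°).

The assembly voxelizes all five shapes on one grid (membership tests in
world coordinates through the inverse rigid pose — no resampling), resolves
overlaps by the fixed priority cochlea > vestibule > PSC > LSC > SSC (the
default layout is disjoint), and records all ground truth in world
coordinates after the pose.

**What phantoms do not show.** They contain no scala structure, no
membranous labyrinth, no CT noise or partial-volume effects, and no
anatomical irregularity beyond the optional smooth surface perturbation.
Passing recovery tests demonstrates correctness of the measurement chain on
idealized geometry at the stated resolution, not segmentation robustness or
anatomical validity on patient scans.

## Cohort simulation

The measurement-level simulator draws per-ear metric values directly
(Gaussian, group mean = healthy baseline + additive shift), which makes
thousands of replicate cohorts cheap. Defaults are the reported adult
means/SDs and group shifts for every metric; the two MD ears of a patient
share a random effect (default within-patient correlation 0.5); disease
duration is a two-component mixture (P(>5 y) = 58/105; uniform 0.2–5 y
below, 5 y + Exp(mean 5 y) above) with additive long-duration enlargement
of vestibular volume (+2.73 mm³), length B (+0.19 mm) and AB/BC areas on
the affected ear. CDL/2TL/BTL are computed exactly from the drawn BLD;
other geometric identities (areas vs diameters) are *not* enforced at
metric level — a phantom-level route (generate spec → voxelize → measure)
exists through the same measurement API when identities matter.

**EH grades** use a thresholded-latent link: a unit-normal latent equal to
a weighted sum of the z-scored driver metrics plus independent noise is cut
at the normal quantiles of the marginal grade distribution. Weights are
target rank correlation ÷ 0.90, where 0.90 is the discretization
attenuation (Spearman of metric vs 4-level grade relative to the latent
Pearson correlation) measured once by simulation and frozen. Default
targets: vestibular grade vs modiolus–SSC +0.243, vs AB–PSC −0.251, vs
AB–SSC −0.251; the cochlear grade has no metric driver. Marginals: cochlear
grades 0–3 at 7.6/40.0/36.2/16.2%, vestibular at 14.3/47.6/25.7/12.4% (the
grade-2/3 split is not reported and was chosen once). Vestibular grades
span 0–3: although three-grade criteria are cited for the vestibule,
grade-3 vestibular hydrops is described, so the range is configurable with
0–3 as default. Unaffected ears receive milder grades (grade-0 mass
quadrupled, renormalized) — a synthetic choice, as their distribution is
unreported.

## Statistics

One-way ANOVA across MDAE/MDUE/HC (unpaired, as reported, although the MD
ears are within-patient paired; a paired analysis would be an extension),
with post hoc pairwise comparisons. The adjustment is not named in the
source reports, so Bonferroni on pooled-error t-tests (the common
statistical-package default) is the default with Tukey HSD selectable.
Spearman correlation (average ranks, two-sided p) links ordinal EH grades
to metrics on affected ears; a constant grade vector raises rather than
returning r = 0. Duration comparisons use the pooled-variance two-sample
t-test by default (Welch selectable), with long duration defined strictly
as > 5 years (the boundary's strictness is a flag, since reports differ on
whether exactly-5-year cases are "long"). Normality is assumed throughout;
there is no automatic nonparametric fallback. The pure-tone average is the
mean of the 500/1000/2000/4000 Hz air-conduction thresholds.

Calibration checks (run by `scripts/acceptance.py` and the test suite):
under the null the ANOVA rejects at 5% ± 2% over 1,000 simulated cohorts;
with cochlear-height shifts +0.08/+0.04 mm (SD 0.22, n = 105/105/100) the
simulated power is ~62%, matching the analytic noncentral-F value of 64%.

## Problem sizes and tolerances

Default phantom grids are ~2.6 M voxels at 0.1 mm (≈10 s to assemble);
pipeline tests use 0.2 mm phantoms. The rigid-invariance experiment poses
the measurement inputs (voxel clouds and canal-plane fits) 100 times;
re-voxelization under pose is exercised separately at two poses, since the
invariance of interest is the measurement chain's and re-voxelizing 100
full-resolution assemblies would dominate runtime for no extra insight.
Statistical calibration uses 1,000 null and 500 alternative cohorts at the
single-metric level. Recovery tolerances mirrored in tests: modiolar axis
3°, canal normals 1°, cochlear height 0.15 mm, vestibular diameters 2%,
basal long diameter 0.2 mm.

## Known limitations

* The cochlear phantom is a stylized helix; BSD recovery carries a ~0.1 mm
  grid-tangency deficit (extreme surface points can fall exactly between
  voxel-center planes), and the analytic tube volume is approximate.
* CDL is regression-derived from BLD, not traced along the duct.
* The ellipsoid model discards vestibular surface detail by design; the
  general-quadric mode only relaxes axis alignment, not ellipsoidality.
* Metric-level cohorts do not enforce cross-metric geometric identities and
  model all metrics as Gaussian, including angles near their folding range.
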