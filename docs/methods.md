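# Methods

This note documents the models, numerical choices and limitations behind
`noduleseg`. Nothing here reports an empirical number that the test suite
or `scripts/acceptance.py` does not itself compute.

## Grid and unit conventions

Arrays are indexed `(z, y, x)`; spacing and origin use the same order in
millimetres, and voxel index `i` maps to physical position
`origin + i * spacing`. Only axis-aligned grids (identity direction
matrix) are supported; oblique acquisitions are out of scope. Seed points
are stored in physical mm so they are invariant to cropping. Grid equality
is checked to 1e-3 mm to absorb float metadata noise.

Physical volumes are reported in mm³. A `.ml` accessor divides by 1000;
clinical reports often print millilitres, but typical nodules measure
hundreds of mm³, so mm³ is the canonical unit everywhere in the package.

## Segmentation pipeline

`segment_nodule` is the composition: crop a ±30 mm cube about the seed
(per-axis `floor(30/spacing)` voxels each side of the seed voxel), compute
the four feature maps on the crop, min-pool them into the speed map F,
initialize the front as a 2 mm sphere per seed, evolve, keep the connected
component containing a seed, and paste the mask back onto the parent grid.
Everything is deterministic for fixed inputs and configuration.

### Feature maps

Each map lies in [0, 1]; 1 = free propagation. Min-pooling makes each an
absorbing veto. The density channel is the sigmoid-transformed member of
the pool; the others carry their own [0, 1] transforms.

* **Chest wall.** Lung = voxels below −500 HU, minus speckle components
  (< 1% of the largest), morphologically closed with a 3-voxel ball and
  hole-filled. The closing reabsorbs thin vessels and juxtapleural
  indentations into the lung; the hole filling restores isolated solid
  nodules (which lie above the threshold) as interior lung. Closing is
  implemented as dilation (border treated as background) followed by
  erosion (border treated as foreground) because a single border value for
  both passes would erode the mask at the image boundary.
* **Vesselness.** Sato-style bright-line measure from the eigenvalues of
  the scale-normalized Gaussian Hessian, maximized over 1/2/4 mm scales
  (spanning pulmonary vessel radii), normalized by the crop's maximum
  response; the map is its complement (`1 − v̂`, a linear transfer; the
  transfer is configurable). The Hessian is built from per-axis Gaussian
  derivatives with sigma in voxels = sigma_mm / spacing, so anisotropic
  grids are handled in physical units; this is also why the filter is
  implemented in-package rather than with `skimage.filters.sato`, which
  assumes isotropic voxels.
* **Interface.** 3-D Canny (SimpleITK) with hysteresis thresholds at the
  70th/90th percentiles of the Gaussian-gradient-magnitude distribution of
  the crop. Percentile thresholds adapt to any HU contrast: after 1 mm
  Gaussian smoothing, noise gradients sit far below tissue-interface
  gradients, and non-maximum suppression thins the result, so the exact
  percentile matters little over a wide range. Detected edges are dilated
  by one voxel and block the front. Consequence: the blocking shell
  straddles the true boundary and covers the outer one-to-two voxel layers
  of the nodule itself; the front recovers part of that rim through the
  advection term (below).
* **Density.** `1/(1+exp(−(I−beta)/alpha))`, alpha = 100 HU; beta = −200 HU
  for solid and −500 HU for non-solid (part-solid, ground-glass) nodules.
  Monotone in intensity, ≈0.0015 at parenchymal −850 HU, ≈0.9 at solid
  +20 HU.

### Level-set evolution

`d(phi)/dt = −w_p F |∇phi| + w_c F κ |∇phi| + w_a (∇F·∇phi)` with defaults
`w_p = 1.0, w_c = 0.3, w_a = 1.0`, 500 iteration cap, RMS tolerance 1e-3.
Discretization:

* propagation: Godunov upwind gradient for outward motion;
* curvature: mean-curvature form with central differences,
  `ε = 1e-12` guard on |∇phi|²;
* advection: per-axis upwinding against the transport velocity −∇F, with
  ∇F frozen at t = 0 (F is static);
* time step from a CFL bound combining the first-order terms (∝ 1/h) and
  the parabolic curvature term (∝ 1/h²), safety factor 0.45; an explicit
  `dt` can be forced for controlled experiments;
* phi clamped to a ±8-voxel band; convergence judged by the RMS change at
  the front itself (voxels within 1.5 voxels of the zero level) — the far
  field keeps being advected wherever ∇F ≠ 0 without the contour moving,
  so a global RMS would never converge;
* redistancing every 20 iterations by signed Euclidean distance transform,
  **preserving phi at voxels face-adjacent to the zero crossing**. A plain
  sign-based EDT quantizes the interface to voxel signs and discards
  sub-voxel motion each reinitialization, which visibly stalls fronts that
  move slowly (e.g. penetrating a low-speed shell); preserving the
  near-front values fixes this while still repairing |∇phi| ≈ 1 elsewhere.

The update is computed full-grid vectorized over the crop (a 30 mm crop is
~61³ voxels) rather than with a sparse narrow band: at this size the
vectorized sweep is faster in numpy and numerically identical inside the
band.

**Advective overshoot at hard speed cliffs.** On a discrete step of F
(1 inside, 0 outside, no intermediate values) the central-difference ∇F is
non-zero in the two voxel layers adjacent to the step, so the advection
term carries the front roughly one voxel past the last F > 0 voxel before
the force vanishes. This is the discrete width of the attraction force,
not a bug: the same mechanism is what pulls the front partway into the
(zero-speed) Canny edge shell at a real nodule boundary, recovering part
of the rim the shell covers. With advection disabled the front stops
exactly at the cliff and an ideal binary map is recovered to sub-voxel
accuracy (this regime is also cross-checked against SimpleITK's
`GeodesicActiveContourLevelSetImageFilter`, which produces a
voxel-identical result there).

## Phantom generator

The phantom defines the study conditions for all tests:

* grid 96×112×144 voxels at 1 mm isotropic; soft-tissue body (+40 HU)
  with two ellipsoidal lung cavities (−850 HU); additive Gaussian noise,
  default sd 20 HU — a typical low-dose-CT parenchymal noise level;
* vessels: per lung, two random-walk tubes of 1–3 mm radius and
  soft-tissue density, confined to the cavity. Background vessels are
  kept clear of the nodule (exclusion radius = nodule extent + tube radius
  + 2 mm) so that *isolated* means isolated; only the dedicated
  juxtavascular vessel (2.5 mm radius, tangent to the nodule surface) may
  touch it;
* nodule: base sphere (default 8 mm radius). Lobulation = union with 1–3
  offset spheres (offset and count scale with the degree); spiculation =
  radial cones (count and length scale with the degree); both provably
  reduce isoperimetric sphericity, which is how the tests check them.
  Texture: solid +20 HU; ground-glass −550 HU; part-solid = solid core
  with a −500 HU halo occupying the outer 40% of the radius (a fixed,
  documented convention);
* attachment: isolated (fully inside the cavity, enforced), juxtapleural
  (centre placed 0.55·r inside the pleural surface so the nodule overlaps
  the wall boundary), juxtavascular (tangent vessel). Ground-truth masks
  are disjoint: wall and vessel masks exclude nodule voxels.

Simulated readers threshold the truth's signed distance field at a smooth
random offset field (Gaussian noise blurred at 4 mm correlation length,
scaled to sd = variability/2, clipped to ±variability). Zero variability
reproduces the truth exactly; increasing variability monotonically
degrades pairwise Dice at fixed seed; a variant that overlaps truth with
Dice < 50% (or is empty) raises an error. A single integer seed drives all
draws.

**What the phantom does not emulate** — and hence what passing tests do
not show about clinical data: partial-volume effects at boundaries
(density steps are crisp), anisotropic slice thickness in the demo
conditions, scanner physics (beam hardening, dose-dependent noise
texture), airways, fissures, cavitation, and systematic human reader
biases (slice-wise jaggedness, consistent over/under-segmentation).
Accuracy figures on the phantom are therefore optimistic relative to real
CT, while *relative* comparisons (algorithm vs reader robustness, with vs
without a feature map) are the meaningful outputs.

## Evaluation statistics

For a four-mask set: `delta` = volume(union) − volume(intersection)
(zero iff all four masks are identical); `dsi` = mean Dice over the six
unordered pairs, in percent. For algorithm-vs-readers agreement,
`DSI_Agree` = mean Dice of the four algorithm masks against a consensus
reference; because the reference definition is ambiguous between the
readers' intersection and union, **both** values are always computed and
reported. Dice of two empty masks is 100%, of one empty vs one non-empty
0% (identity of indiscernibles); any use of this convention is flagged.

Score consolidation: a unique modal score among the four raters wins;
tied modes are broken by the score's frequency across the whole cohort
(tabulated over all individual ratings, the natural reading of
"population"); a residual tie falls back to the lowest score and is
flagged — a documented extension chosen for determinism.

Wilcoxon signed-rank: zero differences dropped; n ≤ 25 uses the exact
null distribution of W+ computed by dynamic programming over doubled
midranks (equivalent to enumerating all 2ⁿ sign assignments, ties handled
exactly); n > 25 uses the normal approximation with tie-corrected
variance, no continuity correction. Spearman's rho is the Pearson
correlation of midranks with the conventional t-test on n−2 degrees of
freedom; Kruskal–Wallis uses the tie-corrected H with a χ² reference
(k−1 df), with the all-values-identical case defined as H = 0 rather than
an error. Tests are two-sided; p-values are reported raw, without
multiple-testing correction, one per characteristic category. Categories
with nominal scales (internal structure, calcification) get
Kruskal–Wallis; ordered scales get Spearman + t.

## Problem sizes in the shipped studies

The demo pipeline evaluates three phantom nodules (solid isolated, solid
juxtapleural, ground-glass isolated); the acceptance study evaluates five
solid isolated nodules of 6.5–10 mm radius, four simulated readers at
1.5 mm variability and four seeded segmenter runs each. These sizes keep a
full run in the minutes range on one CPU while still exercising every code
path; they are configuration, not constants, and scale up by editing
`RunConfig`.

## Known limitations

* Juxtapleural nodules are deliberately under-segmented: the 3-voxel
  closing of the lung mask cannot reabsorb a 16 mm nodule-shaped bite at
  the pleural surface, so the chest-wall map blocks most of a
  wall-attached nodule. The guarantee kept is the safety property — the
  mask does not leak into the chest wall — mirroring the practical
  workflow in which pleural-attached lesions need manual adjustment.
* Ground-glass nodules segment less accurately than solid ones: at
  −550 HU the density sigmoid (beta −500) passes only ≈0.38, the
  parenchyma still passes ≈0.03, and the low-contrast boundary yields
  weaker Canny edges, so the front creeps and over-segments mildly. This
  ranking (solid ≫ part-solid/ground-glass) is the expected behavior of
  this algorithm family, not a defect of the reimplementation.
* The GAC weights shipped as defaults are declared choices, not claimed
  equivalents of any released tool's internal settings.
* No DICOM ingestion, no resampling between mismatched grids, no GPU.
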