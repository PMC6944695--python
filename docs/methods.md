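# Methods

## Device model

The analysis assumes the commercial two-media-channel microfluidic
device: a central gel channel 10 500 μm long and 1300 μm wide, flanked
by 500 μm media channels, communicating through 54 pores on the two
long edges.  The channel rectangle is the coordinate frame: x along the
length, y across the width, origin at one corner, all distances in μm.

The device vendor does not publish the pore layout, only the total
count.  We place 27 pores per long edge, evenly spaced with end margins
of half a spacing (spacing 10500/27 ≈ 388.9 μm) and mirrored across the
channel — a symmetric inlet/outlet row layout consistent with upper and
lower pore rows.  Pore numbering is 1–27 along y = 0 (increasing x),
28–54 along y = 1300.  Every routine that consumes a `DeviceGeometry`
accepts explicit pore coordinates, so a measured layout can replace the
assumption without code changes.

Anastomosis is decided per pore inside an evaluation disk of radius
75 μm centred on the pore (half of it lies inside the channel).  The
radius is on the order of the larger observed vessel diameters; it is a
parameter (`pore_window_radius`).  A pore counts as anastomosed when at
least `coverage_min` (default 0.1) of its in-image window is vessel
foreground — low enough that a thin vessel touching the pore counts,
which is what visual inspection does.

## Segmentation and shape filtering

Binarization is a global gray threshold (Otsu by default; a fixed
normalized threshold for images with known intensity calibration such
as phantoms).  Foreground is strictly above the threshold, and the
threshold actually applied is recorded on the mask.

Connected regions (8-connectivity by default) are tabulated with pixel
count, centroid, and eccentricity of the ellipse with the same second
central moments (focal distance over major axis: 0 for a circle, → 1
for a line).  A region is removed when `area_px < min_area_px` **or**
`eccentricity < min_eccentricity`.  The OR rule is deliberate: single
cells are both smaller and rounder than vessel segments, and OR is the
stricter cell rejector; an AND variant is selectable (`rule="and"`).
Defaults — `min_area_px = 200` at 2 μm/px (i.e. 800 μm²),
`min_eccentricity = 0.8` — separate round cells of radius ≤ 15 μm
(area ≤ 707 μm², e ≈ 0) from elongated vessels by a wide margin on both
axes; at other pixel sizes the area cutoff should be rescaled by
(2 μm / pixel_size)².  Debris that survives the shape filter is removed
by exclusion polygons supplied as pixel-coordinate vertex lists (a
scriptable stand-in for interactively drawn deletion regions); excluded
pixels are dropped unconditionally.

## Metrics

**Density** is retained-foreground pixels over the pixels of the
selected area (whole frame, or a polygon ROI), a decimal fraction.  The
ROI used is recorded with the result, since "area selected" is
otherwise ambiguous.

**Mean diameter** uses the medial-axis construction: skeletonize the
filtered mask (thinning), take 2 × the Euclidean distance transform at
each skeleton pixel as the local diameter, and average over skeleton
pixels (which approximates length weighting: a segment contributes
skeleton pixels in proportion to its length).  Terminal skeleton spurs
shorter than the maximum local diameter are pruned first; thinning
produces such spurs at branch points and tube ends, and their tapering
distance values bias the mean low.  An empty mask reports the sentinel
0 μm with a warning rather than an error, because fully regressed
networks are a legitimate observation.

Accuracy: on bars ≥ 4 px wide the estimate is exact to one pixel (odd
widths are overestimated by ~1 px by the discrete distance transform);
at junctions the inscribed-disk diameter exceeds the tube diameter,
which inflates the mean by a few percent in proportion to the fraction
of skeleton length near junctions.  Constant-diameter phantoms over
20–120 μm at 2 μm/px recover truth within ~3% (10% is the contract).

**Anastomosis fraction** is (pores with window coverage ≥
`coverage_min`) / 54.  All pores are weighted uniformly.

## 3D association

Channels are thresholded independently (normalized [0, 1] scale);
stromal cells are 26-connected components of the green channel above a
minimum voxel count (default 10, rejecting specks).  A cell is
associated iff its city-block (face-adjacency) distance to the vessel
mask is ≤ `contact_radius_voxels`.  The default radius 1 is direct
face contact — the tightest computable analog of scanning serial
z-sections for touching.  Contact is evaluated in voxel units by
default, matching slice-by-slice visual inspection of anisotropic
stacks; a metric (μm) radius can be emulated by passing per-axis radii
after resampling.  Zero cells is an explicit error (0/0), not zero.

With a realistic PSF the single-voxel adjacency band blurs: half-max
segmentation shrinks cell components by up to a voxel, so planted
face-contacts may be measured at distance 2.  On blurred stacks a
contact radius of 2 recovers the planted fraction; the exactness
contract (classifier = all-pairs oracle, planted 8/50 → 0.16) is stated
and tested for noiseless rendering.

## Phantom generator

Phantoms emulate the composite appearance of a labeled μVN in the gel
channel, not its biology: a jittered backbone polyline along the
channel interior, side branches (default 1 per mm of channel length),
and one straight connector from each selected pore to its nearest
backbone node.  Per-segment diameters are Normal(mean, sd) truncated to
±3 sd and ≥ 4 μm; defaults 40 ± 8 μm sit in the observed 33–120 μm
range of real networks.  Tubes are rasterized as the union of disks
swept along segments (pixel centre within radius, boundary inclusive);
single cells are disks (radius clipped strictly below the thinnest
vessel radius), debris are irregular star polygons.  Cells and debris
are placed with clearances (15 μm from vessel surfaces and each other,
10 μm outside pore windows) so ground-truth classes stay pixel-disjoint
and pore coverage is owed to vessels alone.  The interior backbone band
keeps vessel surfaces out of every pore window, so exactly the selected
pores are detected as anastomosed on noiseless phantoms.

Imaging is background level (default 0.05 of full scale) + class
amplitudes (vessel 1.0, cell 0.85, debris 0.6), Gaussian PSF blur
(default σ = 2 μm), additive Gaussian noise (default sd = 0.02), and
8/16-bit quantization.  The defaults keep foreground separable at the
default threshold (background + 3·noise ≈ 0.11 ≪ 0.6); raising them
past that guard is possible but then threshold choice, not the
pipeline, dominates the error.  One integer seed drives all stochastic
draws through explicit `numpy.random.Generator` instances; identical
parameters and seed reproduce images and truth byte for byte.

Ground truth is exact by construction: `coverage_fraction` *is* the
vessel fraction of the label map; `true_mean_diameter` is the
length-weighted segment mean; `connected_pores` the anchored pore set.
Rasterization fidelity (label map vs continuous geometry) is ~half a
pixel at boundaries: a tube whose edge falls exactly on a row of pixel
centres gains a one-pixel row by the inclusive boundary rule, which is
the worst case of the ≤ 2% area deviation verified against the
closed-form stadium area.

Z-stack phantoms voxelize a 256 μm field of view (default centred on
the longest vessel segment, 64 μm deep, isotropic 2 μm voxels) with
vessel tubes at mid-depth and spherical stromal cells placed by
rejection sampling: planted-contact cells are verified to have
city-block distance exactly 1 to the vessel mask, non-contact cells
Euclidean distance ≥ 2 voxels, cells mutually separated by ≥ 4 voxels
so blur cannot merge them, and no cell clipped by the volume border.
Placement failure raises an error instead of silently degrading truth.

What phantoms do **not** emulate: vessel self-assembly dynamics,
curvature and tapering within a segment, hollow lumens, uneven
illumination and tiling seams, shot noise, and out-of-focus haze.
Passing tests therefore demonstrate correctness of the measurement
chain under a known morphology, not robustness to every imaging
artifact of real composites.

## Statistical plumbing

Per-condition summaries are n, mean and standard deviation.  Two
groups: unpaired two-tailed Student's t-test (equal variances, the
named historical choice; Welch by flag).  More than two groups at one
time point: one-way ANOVA.  Time courses: two-way ANOVA
(condition × time, type II) via statsmodels, with post hoc pairwise
t-tests per time point adjusted by the exact Bonferroni identity
p_adj = min(1, m·p) over all m comparisons.  The two-group test's
type-I error is calibrated by simulation at the study's n = 3 devices
per condition (0.05 ± 0.02 over 1000 null draws).  Every batch output
row carries a hash of the analysis parameters so that reruns are
attributable and byte-identical for identical configs.

## Problem sizes and numerical choices

Acceptance-style checks run phantoms at 4 μm/px (full device,
2625 × 325 px) where pixel-exactness is what is tested, and 2 μm/px
(5250 × 650 px) where diameter resolution matters; z-stack fields are
128 × 128 × 32 voxels.  These sizes keep the full verification suite
around a minute on one CPU while leaving every contract
resolution-independent (the resolution-consistency test pins coverage
drift between 2 and 4 μm/px to < 2%).  Thresholds on phantom runs use
the fixed normalized value 0.3 — between background (0.05) and the
dimmest object class (0.6) — so segmentation is exact and tests isolate
the stage under study; Otsu is the default for real images.

## Known limitations

* Global thresholding only; strongly non-uniform illumination requires
  pre-correction upstream.
* The diameter estimator inherits medial-axis biases (junction
  inflation, ±1 px discretization); sub-4-px vessels are flagged, not
  measured reliably.
* The pore layout is an assumption pending vendor geometry; anastomosis
  counts are exact only relative to the supplied layout.
* Face-adjacency contact at radius 1 is strict for blurred data (see
  above); choose the radius to match the imaging PSF.
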