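# Methods

This note documents the models, conventions and numerical choices behind
`transvasc`, and what the synthetic validation does and does not show.

## Coordinate and calibration conventions

Voxel grids are indexed `(z, y, x)`, 0-based; a series has axis order
`(t, c, z, y, x)`.  Physical coordinates are in μm and are anchored at
voxel centers (`position = index × spacing`), which makes the centroid of
a single voxel unambiguous.  Bounding boxes are half-open.  The default
calibration is 1 μm laterally, 2.5 μm axially (60 sections through
150 μm) and 10 minutes per stack; channel names ("network", "cells") are
bound by configuration, not wavelength.

## Synthetic scenes

The generator emulates the tube-formation geometry this pipeline is meant
to quantify; every rendered voxel is also recorded as ground truth before
noise, so downstream stages can be validated exactly.

**Network.** A planar graph of junctions and straight branches near the
cushion plane is rendered as tubes of elliptical cross-section (default
lateral radius 8 μm, axial half-thickness 7.5 μm — a cord one to two
cells thick).  Junctions may carry a larger ellipsoidal node mass, used by
penetration scenes.  Decay follows a retained-volume schedule
(time → fraction, linearly interpolated, validated non-increasing within
(0, 1]); voxels are removed in order of *geodesic distance along the
skeleton* from RNG-seeded branch points, so erosion consumes cross-sections
outward from the seeds like retracting cords, and the retained count equals
`round(fraction × N0)` exactly.  Along-cord removal is deliberate: a
Euclidean "disk" erosion grazes branches obliquely and exposes large cut
faces, decoupling surface-area loss from volume loss, whereas perpendicular
cross-section cuts keep the two proportional (the residual cut-cap bias is
about one percentage point on the default lattice; the test suite bounds
area-vs-voxel disagreement at 5 points).

**Cells.** Bodies are spheres in physical space (default diameter 30 μm,
hence 12 axial sections at 2.5-μm steps), rendered as solid ellipsoids in
voxel space; optional filopodia are 1-voxel-radius cylinders and are
ground-truthed but not reconstructed (they sit at the resolution limit).
Per-frame step lengths are drawn from `Normal(speed_mean, speed_sd) × dt`,
truncated at zero.  Programs:

- `STATIONARY`, `RANDOM_WALK` (uniform random 3D direction; steps that
  would leave the grid or violate a minimum network distance are reflected
  or skipped);
- `DIRECTED_TO_NETWORK` — each step moves toward the nearest network
  voxel; the cell stops once its body overlaps the network by 2 μm.  This
  overshoot is deliberate: exact tangency of two voxelized surfaces can
  leave more than one voxel between nearest voxel centers and make the
  contact classification flicker, whereas adhering cells in reality deform
  onto their substrate;
- `ALONG_NETWORK` — the cell rides a branch medial axis at a configurable
  height above the plane (default 12 μm, partially overlapping the cord so
  it is in contact but never majority-inside), clamped at branch ends;
- `PENETRATE_AND_EXIT` — parked on a node surface, the body occupies the
  node interior between the programmed entry (inclusive) and exit
  (exclusive) times.

**Noise.** Foreground/background levels default to 200/10 on an 8-bit
scale with Poisson shot noise and additive Gaussian noise (σ = 5),
applied last.  At these levels boundary misclassification is negligible
(≈6σ separation at the Otsu threshold), which is intentional: the
validation isolates geometry and behavior recovery, not low-SNR
segmentation robustness.  Identical scene specifications (including the
seed) render byte-identical output; independent RNG streams drive decay
seeding, motion and noise.

**Cohorts.** Cohorts of 50–100 cells are sharded over several small scenes
with one lane or branch per cell — mirroring the several fields of view a
microscope samples per dish — so cells never merge into aggregates, and
the programmed reacher count is distributed exactly across shards.

## Segmentation

Per-volume thresholding (Otsu by default; fixed thresholds are inclusive,
Otsu foreground is strictly above the returned level, which sits at the
top of the background class).  The network mask receives *no* hole filling
and *no* morphological closing — gap preservation is contractual, since
the reticulated mesh's gaps are the object of measurement — and components
smaller than a 10-μm sphere (≈209 voxels at default calibration) are
removed as debris.  Cells are 26-connected components (8-connected within
sections); touching cells remain one object, consistent with tracking
aggregates as units.  Per-section outlines are refit as closed periodic
cubic B-splines (`splprep`, smoothing 0.5 × perimeter in pixels, 64
resampled points by default); degenerate sections fall back to raw pixel
contours.  Whether the original bitmap algorithm thresholded per-section
or per-volume is not documented anywhere we could find; per-volume is used
here for stability under sparse sections.

## Surface reconstruction

Marching cubes at iso-level 0.5 with physical spacing `(dz, dy, dx)`.
Binary-field marching cubes overestimates a sphere's area by ≈9%; one pass
of Gaussian pre-smoothing (σ = 0.5 voxel, configurable off) brings a
10-μm-radius sphere within 4% of 4πr² and suppresses terracing from
2.5-μm z-steps.  If smoothing would erase an object entirely (bodies about
one voxel across), the unsmoothed field is used instead.  Contour-based
cell surfaces rasterize the spline outlines per section and skip the
pre-smoothing (the contours are already smooth, and a body two sections
thick would be eroded); a single occupied section reconstructs as a
one-dz-thick solid because the iso-crossings sit half a step above and
below it.  Surfaces are not capped at volume boundaries by default (a
`cap` flag pads the field); percent-change analyses are insensitive to a
consistent convention.

## Network metrics

Topology is read from a 2D skeleton of the maximum-intensity z-projection
— the network is quasi-planar and 3D thinning on 2.5-μm anisotropic steps
is unstable — while areas remain fully 3D.  Junction pixels (skeleton
degree ≥3) merge into clusters when adjacent; spur branches shorter than
5 μm are pruned and junction clusters joined by branches shorter than
5 μm are contracted before the census (skeletonization artifacts would
otherwise inflate node counts — a real multicellular branch is far
longer).  A node is a junction cluster of degree ≥3.  Mask voxels are
assigned to the node nearest through the skeleton (multi-source BFS over
skeleton pixels, then nearest-skeleton-pixel lookup); connected components
containing no node are DETACHED and excluded from the analyzed area when
requested (exclusion never increases analyzed area).  Percent decrease is
computed from faceted areas against the 4-hour reference; per-node decrease
uses node correspondence by nearest reference junction within 15 μm — a
choice recorded in the run manifest, as no published convention exists —
and a network with no nodes at all falls back to whole-mask area with a
warning.  The decay-recovery experiments keep detached fragments in the
analyzed area, because the quantity being recovered is the programmed
whole-network retention schedule.

## Tracking

Greedy mutual-nearest-neighbor assignment between consecutive frames, no
link longer than 30 μm (≈3 μm/min at 10-min sampling), unmatched objects
seed new tracks, and a track missing exactly one frame may reconnect at
the same bound.  Speeds are forward differences of the 3D centroid —
deliberately unsmoothed, because programmed-speed recovery on synthetic
scenes defines correctness here; a central-difference option exists.
Mean track speed is path length over elapsed time.  Cohort statistics
exclude tracks shorter than 6 frames (single-step speeds are
noise-dominated) and support an optional persistence filter
(net displacement / path length ≥ 0.5 for "persistent" cohorts).  Cohort
comparison is a pooled-variance two-sample t-test (Welch optional) on
per-track mean speeds, reporting `100 × (1 − mean_B/mean_A)`; two
degenerate identical samples give p = 1 by convention.

## Behavior classification

Per frame, a cell's overlap fraction `f = |cell ∩ network| / |cell|` and
its anisotropy-aware Euclidean distance to the network (distance transform
sampled at the nearest cell voxel; zero when overlapping) decide the
state: `f ≥ 0.5` → INSIDE_NETWORK (the majority-inside rule, boundary
inclusive), surface distance ≤ one lateral voxel → ON_NETWORK (contact is
physical adjacency, not centroid proximity), else FREE.  An empty network
mask yields FREE with an infinite-distance sentinel.  At track level, FREE
frames on a monotone distance descent (2-μm tolerance over a 3-frame
window) toward eventual contact become APPROACHING; CONTACT fires at the
first contact frame, ADHESION once contact persists 3 frames, DETACH when
an adhered cell is free again for 3 frames, and ENTER/EXIT bound
INSIDE episodes.  Population summaries bin tracks by the distance measured
at their first frame — cell surface to network surface, a convention
recorded in output metadata since published distance bins do not state
surface vs centroid — into near (≤65 μm), far (≥80 μm) and intermediate
bins, reporting adhered fraction, detachment fraction among adhered,
approach and on-network speeds (the latter over ON_NETWORK frames only),
penetration counts, and the fraction of non-translocating tracks (net
displacement below one cell diameter, 30 μm — the displacement criterion
is configurable because no published threshold exists).  Empty bins report
n = 0 with undefined fractions, not zeros.  Movement *under* the network
is not distinguished from movement on it; both classify as ON_NETWORK.

## Recovery experiments and problem sizes

The experiments in `transvasc.experiments` program the generator with
published cohort statistics and require the full pipeline to recover them:
approach speed 0.40 ± 0.08 μm/min (n = 50), along-branch speed
0.73 ± 0.31 μm/min (n = 20, and the recovered on-network mean must exceed
the approach mean), 48-h area decreases of 28% / 90% / 42% for the
no-cell / MCF-10A / MB-231 overlay schedules, a 68/100 near-band adhered
fraction and 35/100 far-band non-translocating fraction (exact on
noise-free scenes), zero detachment, ENTER/EXIT within one frame, and a
programmed 70% velocity reduction recovered by cohort comparison.  Scenes
use 13–18 frames on grids of roughly 20×130–220×250–400 voxels (velocity
and cohort scenes) and 12×400×400 (decay lattices) — sizes chosen so a
full recovery suite completes in minutes on a single core while every
cohort keeps its published n.  Bare p-values are recomputable via
`compare_cohorts` but are sample-realization dependent and are not used as
recovery anchors.

## Known limitations

- The generator validates geometry and kinematics, not mechanism: no
  chemoattractant fields, no reciprocal endothelial projections, no cell
  aggregation mechanics, no tube lumens (consistent with the multicellular
  cords this pipeline models).  Passing recovery tests shows the pipeline
  measures what was programmed; it cannot certify performance on real
  low-SNR recordings.
- Filopodia are rendered but not reconstructed or used for contact
  scoring; "filopodial contact" events are out of scope.
- Touching cells are tracked as aggregates; there is no watershed
  splitting or mitosis handling.
- The proprietary microscope (.lif) and legacy motion-analysis file
  formats are not read; input is TIFF/OME-TIFF, and all analysis is
  lossless end to end (no JPEG intermediates).
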