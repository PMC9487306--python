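# Methods

## Scope and model

The package models the geometric core of sub-arc collimator angle
optimization for single-isocenter coplanar VMAT SRS of multiple brain
metastases: BEV projection of target structures, conformal MLC aperture
fitting, the MCI heatmap over control points × collimator angles, exact
sub-arc segmentation, and DVH-derived plan indices. It deliberately stops
short of inverse optimization, dose calculation and monitor-unit
computation — those require a treatment planning system, and the indices
computed here on synthetic dose grids characterize the dose *model*, not a
deliverable plan.

Coordinates are DICOM LPS in millimetres, gantry angles follow IEC 61217,
and arcs are coplanar (the gantry rotates about the patient
superior–inferior axis; no couch kicks). The BEV frame per gantry angle g
uses u = leaf-travel direction at collimator 0 (= (cos g, sin g, 0)) and
v = leaf-stacking direction (= patient superior). A collimator rotation by
θ maps a silhouette feature at polar angle φ (from +u toward +v) to φ − θ.

## Machine and arc parameters

| parameter | default | notes |
|---|---|---|
| SAD | 1000 mm | C-arm linac source-axis distance |
| arc | dual 179°→181° (CCW) and 181°→179° (CW) | 358° span each |
| CP spacing | 2° | 180 CPs per arc, both endpoints kept |
| collimator grid | 0…179° step 1° | 180 values; θ+180° is equivalent for a symmetric bank |
| leaf bank | 60 pairs: 10×10 mm, 40×5 mm, 10×10 mm | Millennium-120-like widths at isocenter, bank centered on the isocenter projection |
| fitting margin | 0 mm | the PTV already carries its setup margin |
| min sub-arc span | 30° (15 CPs) | "more than 30°" read as ≥ 30° |
| max sub-arcs | 9 | "less than 10" read as ≤ 9 |
| score tolerance δ | 0.01 (relative) | fewest-sub-arcs-within-δ selection |
| prescription | 30 Gy (5 fractions) | used by metrics and the dose generator |
| voxel / BEV pixel | 1 mm / 0.5 mm | raster-path resolutions |

Since 358° = 2 × 179°, 2° is effectively the only usable CP spacing for
the full arc; partial arcs accept any spacing that divides their span.
With both arc endpoints as control points the printed gantry ranges of a
plan sum to 358°, matching Φ = 358° in the weighted field-size formula;
the minimum-span constraint is therefore enforced on CP count
(⌈min_span / spacing⌉ per sub-arc) and `weighted_field_size` accepts one
CP spacing of slack in the span sum.

## Silhouette computation — two paths

**Raster path** (`rasterize_structure` → `project_to_bev` →
`rotate_to_collimator_frame` → `fit_conformal_aperture`): contours are
filled per slice by the even-odd rule (degenerate zero-area polygons are
skipped with a warning; a grid finer than the contour spacing fills every
slice within half a slab so no gap slices appear), voxel centers are
projected point-wise with divergent magnification SAD/(SAD − d) (parallel
mode sets the factor to 1), rasterized with mirror-symmetric binning about
the isocenter and closed morphologically (3×3, one pixel radius).
Collimator rotation resamples the mask bilinearly and thresholds at 0.5.
This path is the general-purpose one: it works for any mask, and all
aperture/MCI operations are defined on it.

**Analytic path** (`project_contours_to_bev` → `mci_profile_polygon`),
used by `build_mci_heatmap`: for a coplanar beam the u-shadow of each
contour polygon is exact at its vertices (the divergent map is
fractional-linear, so extremes occur at vertices); consecutive slice
shadows are joined by linear interpolation — the standard
contour-to-surface reconstruction, whose chain vertices lie on the true
surface — and closed with half-slab apex caps. The resulting shapely
polygon is rotated exactly per collimator angle, and each leaf pair opens
to the extreme u-extent of the region inside its v-band, evaluated from
boundary vertices plus boundary/band-edge crossings.

The analytic path exists because raster artifacts are not small at this
task's tolerances: bilinear-threshold rotation lets a silhouette pole
wobble across a leaf-band edge, popping a whole 5 mm pair open and
injecting several percent of A_MLC jitter, and slab-box (staircase)
surface models place corners ~dz/2 outside the true surface with the same
effect. With the interpolated-shadow model a rotationally symmetric target
yields an MCI heatmap flat to a few 10⁻³ (the residual is the genuine
slice-staircase of 1 mm contour stacks, largest for small lesions), and
silhouette mirror symmetries (opposed parallel beams, θ ↔ θ+180°) hold to
machine precision. Both paths agree at θ = 0 by construction and within a
few 10⁻² elsewhere; the tests cross-check them.

## Aperture fitting and MCI conventions

* A leaf pair is a single interval: disjoint islands inside one v-band
  force one spanning opening. This is what makes island blocking visible
  to the MCI.
* Leaves snap outward (never clip target pixels), so coverage is
  guaranteed and MCI ≤ 1 is an invariant. A_MLC counts open-pair
  rectangles only; jaw-but-not-leaf area is excluded, since the index is
  defined against the MLC-fitted area.
* Band membership uses pixel centers (raster path) or the exact boundary
  (analytic path); silhouettes exceeding the bank height or the maximum
  leaf span raise errors rather than clipping.
* The jaw rectangle is the tight bounding box of the open pairs; its area
  in cm² is the per-CP field size, and a sub-arc's field size is the mean
  over its CPs at the sub-arc's collimator.

A consequence of the 5 mm leaf quantization worth knowing: for two lesions
*nearly touching* along the leaf-stacking direction, the best collimator
is not always the one that exactly separates them — tilting a few degrees
can align each lesion with whole leaf bands at the cost of a tiny shared
sliver, and win. The island-blocking law is therefore tested as "the
optimum avoids island blocking and strictly beats the fully blocked
orientation", not as proximity to a single predicted angle.

## Segmentation

"Avoiding the worst MCI" is operationalized as an exact optimization:
maximize the summed per-sub-arc best-collimator MCI subject to the span
and count constraints, by dynamic programming over segment boundaries
(prefix sums make each segment score an O(n_θ) lookup). Because the
objective never decreases under splitting, the unconstrained optimum
always uses the maximum sub-arc count; among segmentations scoring within
δ = 0.01 (relative) of the best, the fewest sub-arcs are kept, which
reproduces small sub-arc counts without a hand-tuned penalty. Collimator
ties break toward the lowest angle; a brute-force enumerator with the same
objective and tie-breaks (guarded to ≤ 40 CPs) serves as the test oracle,
and DP and oracle agree exactly (same floating-point accumulation order).
Boundary CPs belong to the later segment.

## Plan metrics

D_x% is the linearly interpolated percentile-from-top of voxel-center dose
samples inside the region; V_t is the absolute volume at or above t.
Region masks on the dose grid assign each grid slice the contours nearest
in z (within half the larger slice spacing) with even-odd filling. CI is
the simple ratio V_ref/V_T (not the Paddick index), with V_ref counted
inside the body contour when one is provided and over the whole grid
otherwise. GI requires V100 > 0 and is undefined (error) otherwise.
Reported cohort medians use midpoint-of-two-middle for even n and round
half-away-from-zero to one decimal, matching how such tables are printed.

## Synthetic data

`make_phantom` emulates the target cohort: 2–5 spherical (optionally
ellipsoidal) lesions with prescribed volumes, placed uniformly inside a
90 mm-radius head with ≥ 4 mm clearance between surfaces and to the shell,
seeded and retried a bounded number of times (volumes beyond ~30% of the
head volume are rejected up front). Lesions are written as 1 mm-slice
90-vertex contour stacks; rasterized volumes match the request within 2%
for radii ≥ 5 mm. The per-axis lesion spread R_max is defined as the
largest pairwise distance between outer bounding extents (center distance
plus both radii); the alternative gap-between-boundaries reading of the
cohort table's ambiguous definition is not used, and the bundled 20-case
table is a transcription, not recomputed (its case 1 total volume is
19.3 cc, consistent with its lesion volumes 10 + 9.3).

`make_synthetic_dose` paints Dp inside each lesion and
Dp·exp(−d²/2σ²) outside, where d is the distance to the nearest lesion
surface, computed by a Euclidean distance transform on a 2× refined
subgrid (no half-voxel correction: in the falloff region the outer
envelope over dense near-surface voxel centers already tracks the true
surface). For a single sphere this gives the closed form
GI = (1 + σ/R·√(2 ln 2))³, which the pipeline reproduces within ~1% at the
1 mm default grid; σ → 0 recovers GI → 1. What the generator does *not*
emulate: realistic dose from an optimizer (no modulation, no hot/cold
spots, HI ≡ 0 by construction), OAR anatomy, CT intensities, or
non-spherical lesion shapes beyond axis-aligned ellipsoids. Passing tests
therefore validate geometry and bookkeeping, not dosimetric claims about
real plans.

## Determinism, sizes, degenerate inputs

All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); repeated runs are byte-identical. Default
problem sizes — 180 × 180 heatmaps per arc, 1 mm dose grids over the
lesions plus a 25 mm margin — run in seconds to tens of seconds on one
CPU; tests use partial arcs and coarser collimator grids. Degenerate
inputs fail loudly: empty structures, empty silhouettes at a CP,
non-divisible CP spacing, infeasible segmentation constraints, silhouettes
taller than the bank, and all-sub-prescription dose grids each raise a
typed error.

## Known limitations

* No deliverability modeling: leaf speed, interdigitation,
  tongue-and-groove, transmission and leakage are out of scope.
* The two arcs of a dual-arc plan are optimized independently.
* The analytic silhouette's fallback for multi-island slices (per-polygon
  slab boxes) reintroduces staircase corners; single-polygon-per-slice
  stacks (all bundled generators) use the interpolated model.
* DICOM support covers reading RT-STRUCT contours and RT-DOSE grids;
  structures are exported in the package's JSON contour format, not as
  DICOM.
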