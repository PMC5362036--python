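# Methods

## The quantification

`memloc` quantifies where a fluorescent protein sits in a rod-shaped
bacterium by comparing the cell periphery with the cell interior. For each
cell, an outline polygon (from ground truth or a segmenter) is rasterized
to a pixel mask with a boundary-inclusive pixel-center rule, and the mask
is split into two compartments:

* **membrane ring** — the first `ring_width_px` intracellular pixels
  flanking the outline. "First k pixels" is formalized as Chebyshev
  distance ≤ k to the nearest exterior pixel, computed as k successive
  erosions with the 3×3 (8-connected) structuring element. The Chebyshev
  choice makes "k pixels flanking the outline" literal along both axes and
  diagonals (a Euclidean disc differs at corners) and admits an exact
  brute-force oracle, which the test suite checks against the erosion
  implementation on random masks. Default `ring_width_px = 4`.
* **cytosol** — the remaining interior pixels. Ring and interior partition
  the mask exactly.

The per-cell statistic is

    ratio_membrane_cytosol = mean(I[ring]) / mean(I[interior])

after optional background subtraction. A cell is classified
*membrane-associated* when the ratio is strictly greater than a threshold
(default 0.7) and *cytosolic* at or below it; the boundary value is
cytosolic. Cell length is reported as the Feret diameter (maximum pairwise
vertex distance) of the outline times the pixel size; for near-straight
rods this equals the pole-to-pole length, whereas a medial-axis length
would additionally follow cell curvature — a known, deliberate
simplification.

Why a threshold below 1 separates the two states: for a uniformly
cytosolic label the image is a projection through the cell body, so the
boundary ring — where the chord through the cell is short — is dimmer than
the interior and the ratio falls well below 1; for a membrane-confined
label the projected shell path length peaks at the silhouette edge and the
ratio exceeds 1.

## Synthetic microscopy generator

Because quantification needs ground truth, the package ships a forward
model rather than canned images. Cells are 3D spherocylinders (radius r,
pole-to-pole length L) and the camera image integrates fluorophore density
along the optical axis:

* cytosolic label: chord depth `2·sqrt(r² − d²)` at perpendicular distance
  d from the long axis, with d replaced by the distance to the cap center
  beyond the body/cap boundary at axial distance (L − W)/2; normalized so
  the mid-cell axis value equals `amplitude`;
* membrane label: shell path `2·(sqrt(r² − d²) − sqrt(max(0, (r−t)² − d²)))`
  for shell thickness t, scaled so the cell's total integrated signal
  equals the cytosolic render at the same amplitude. Equal totals make the
  mixing knob f (`membrane_fraction`) mean "fraction of label in the
  membrane": a mixed cell is `f·membrane + (1−f)·cytosolic`.

Optics and detection, in image-formation order: Gaussian PSF blur →
constant background offset → Poisson shot noise → additive Gaussian read
noise → clamp at zero. Everything is a pure function of the configuration
and its seed.

Populations are placed by rejection sampling against an occupancy grid:
silhouettes dilated by `spacing_px` must be disjoint and at least
`margin_px` from the border (so rings are never truncated and blur mass
stays on-canvas); placement fails loudly (`canvas_too_crowded`) after
`max_attempts` rejections per cell.

### Default study conditions

| parameter | default | meaning |
|---|---|---|
| `width_px` | 15 | cell diameter (~1 µm at 0.066 µm/px); must exceed 8 so a 4 px ring leaves a non-empty interior |
| `length_dist` | uniform(30, 60) px | pole-to-pole length, ~2–4 µm |
| `shell_thickness_px` | 1.5 | membrane shell (~100 nm) |
| `psf_sigma_px` | 2 | wide-field PSF (~130 nm sigma) |
| `amplitude` | 1000 | peak signal, arbitrary counts |
| `background` | 100 | constant offset |
| `read_sd` | 20 | detector read noise |
| `n_cells` | 250 | cells per cohort, a typical per-strain sample size |
| `pixel_size_um` | 0.066 | camera pixel size |

At these conditions the two pure label classes separate cleanly at ratio
0.7: noiseless single cells score ≈ 0.64 (cytosolic) and ≈ 1.14
(membrane), and with full noise a 250-cell cytosolic cohort spans roughly
0.61–0.67 while a membrane cohort spans roughly 1.10–1.17, so both
calibration controls classify 100% correctly. The per-cell means average
hundreds of pixels, which is why shot and read noise barely move the
ratio.

### What the generator does not emulate

No phase-contrast channel, no deconvolution, no cell curvature, division
or growth (time lapse is frame-indexed mode switching of fixed
geometries), no focal drift, no uneven illumination, no fluorophore
maturation or bleaching, and no segmentation error when ground-truth
outlines are used. Passing tests therefore demonstrate that the
quantification is correct *given* outlines and the stated image physics —
not that the threshold 0.7 is optimal for any particular real microscope,
whose PSF, background structure and pre-processing differ.

## Background handling

The ratio is background-dependent, so subtraction is explicit:
`background_mode="constant"` subtracts a known constant (used throughout
simulator-driven tests, where the background is exactly the configured
offset); `"none"` uses raw means (the conservative default for real
images, where the true background is unknown). A cell whose
background-subtracted cytosol mean is not positive gets an
`undefined_ratio` flag instead of an infinite ratio.

## Flags and exclusions

Cells touching the image border (`border`, ring would be truncated), cells
whose ring swallows the whole mask (`too_thin`), optionally saturated
cells, and cells with undefined ratios are flagged, kept in the output
table, and excluded from population fractions. Summaries report both the
excluded count and the analyzed count, so the all-cells convention is
recoverable.

## Calibration and summaries

`calibrate` scores both control cohorts at a given threshold
(misclassification = cytosolic controls above it, membrane controls at or
below it) and also reports the `optimal_threshold`: the candidate
minimizing total misclassification, candidates being exactly the observed
ratio values with ties resolved to the smallest — deterministic and
data-dependent, with no arbitrary grid. `summarize` reports the
membrane-associated fraction at the threshold; `ratio_vs_length` emits the
plotting-ready per-cell table.

## Time-lapse dispersal

For an id-tracked time lapse, each cell's per-frame ratio trace is scanned
for *dispersal episodes*: maximal runs of at least two consecutive
cytosolic-classified frames. The two-frame debounce suppresses
single-frame noise without hiding episodes of ~10 min at typical 3 min
framing; onset is the first frame of the run times the frame interval, and
duration is the run length times the interval. Missing or unmeasurable
frames break runs and flag the cell (`gap`).

## Numerical choices

* Coordinates: 0-based, x = column, y = row, pixel centers at integers;
  polygon vertices are continuous. Rasterization is boundary-inclusive on
  pixel centers, so an axis-aligned 12×12-pixel rectangle yields exactly
  144 pixels.
* Outline polygons of simulated cells sample the silhouette uniformly in
  arc length (64 vertices by default), keeping Feret length within a pixel
  of the true length and rasterized area within a few percent of the
  analytic silhouette area (L − W)·W + π(W/2)².
* Erosion uses `border_value=0`: out-of-image pixels count as exterior,
  consistent with the distance-transform definition.
* One run seed fans out to per-stage seeds by hashing the stage name
  (SHA-256, reduced below 2³¹), so a single integer reproduces a whole
  run; all tabular and JSON outputs are byte-reproducible.
* JSON outlines round vertices to 6 decimals; round-tripping preserves
  ids, order and coordinates at that precision.

## Stand-in segmenter

`segment_stand_in` (Gaussian smooth → Otsu → 8-connected components →
boundary tracing) exists so the pipeline can run end-to-end without
ground-truth outlines. It is deliberately minimal: no sub-pixel meshes, no
splitting of touching cells, not tuned for phase contrast. On noiseless
synthetic cohorts it recovers every cell with mask IoU ≥ 0.8 against
ground truth; it should not be expected to match dedicated bacterial
segmentation tools on real data.

## Problem sizes

Simulator-driven tests use cohorts of 8–40 cells on small canvases;
cohort-level validation (control calibration, parameter recovery across
seeds 1–10 and membrane probabilities {0, 0.3, 0.7, 1}) uses the full
default of 250 cells per cohort on a 1200×1200 canvas, a scale chosen to
match typical per-strain sample sizes while keeping a full validation run
in minutes on one CPU.

## Known limitations

* Feret length overestimates nothing for straight rods but ignores
  curvature; crescent-shaped cells would need a medial-axis measure.
* The optimal-threshold search is resubstitution (evaluated on the same
  control ratios); with well-separated controls this is harmless, but for
  overlapping populations a held-out evaluation would be needed.
* Significance testing on cohort comparisons is ordinary paired/unpaired
  t-testing and is left to standard statistics packages.
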