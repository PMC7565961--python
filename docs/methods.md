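# Methods notes

This note records the modelling assumptions, parameter choices and numerical
conventions of the pipeline, and what the synthetic-data experiments do and
do not demonstrate.

## Conventions fixed once

* **Coordinates.**  Row-major rasters, origin top-left, 0-based indices.
  Continuous coordinates place the centre of pixel `(row, col)` at
  `(col + 0.5, row + 0.5)`; a pixel spans a unit square.  Angles are
  measured from the +x (column) axis with y (rows) pointing down, reported
  in `(−90, 90]` for the long axis of a box.
* **Grayscale conversion.**  Mean of R, G, B with half-up rounding —
  deterministic and symmetric in the three planes.
* **Histogram equalization.**  Global (no tiling/CLAHE), using the transfer
  function `lut[v] = round(255·(cdf[v] − cdf_min)/(N − cdf_min))` with
  `cdf_min` the cumulative count at the lowest occupied level.  It is
  monotone, maps the lowest occupied level to 0 and the highest to 255.
  Degenerate (single-level) images are returned unchanged; consequently the
  CX43 mask of a constant channel is all-zero unless the channel sits at
  255.  This convention matters for the fixed 254 threshold of the CX43
  quantification mask: the top occupied intensity always remaps to 255, so
  the mask selects the upper tail (~1 %) of the equalized distribution.
* **Merged-image splitting.**  RGB merges are decomposed by plane, with the
  white (CX43) signal recovered as the pixelwise `min(R, G, B)` so that
  pure-colour regions do not leak into the CX43 channel.  How the original
  merged images were decomposed numerically is not documented anywhere we
  know of; the min-plane rule is this package's choice.
* **Bit depth.**  Inputs deeper than 8 bits are linearly rescaled to
  [0, 255] on load, because every threshold in the pipeline is defined on
  the 8-bit range.

## Morphology

Square structuring windows of rank `n` (side length `n` pixels), rank 1
being the identity.  Odd ranks are centred; for even ranks the anchor is
the top-left pixel of the central 2×2 block (a fixed, documented choice —
even ranks only occur in some single/two-channel parameter sets).
Out-of-image pixels are background.  Opening (erosion then dilation with
the same window) removes objects smaller than the window; growth is
`ng_it` successive dilations.  "Dilation of the foreground boundaries" and
whole-mask dilation coincide for binary masks, so standard dilation is
implemented.

## Mask combination

The automatic CM mask activates a `Mc1` pixel unless it is active in *both*
`Mc2` and `Mc3` — implemented literally as
`Mc1 AND (NOT Mc2 OR NOT Mc3)`; the algebraically equivalent
`Mc1 AND NOT (Mc2 AND Mc3)` serves as the test oracle.  Absent channels
enter as all-zero masks, so single-channel inputs degenerate to
`Ma = Mc1`.  For interstitium-free inputs an optional switch
(`invert_c3`) approximates the interstitium as the complement of `Mc1`
(default off).

## Contours and boxes

* Components are 8-connected (diagonal contacts do not fragment a cell);
  discovery order is row-major by first pixel, which fixes record ids.
* The external boundary is traced by marching squares at the 0.5 level on
  the hole-filled component.  This cuts corners at 45°, so a solid `n×n`
  square has traced area `n² − 0.5`.  Contour area (shoelace) and perimeter
  (Euclidean edge length) inherit that convention; plausibility thresholds
  (area > 100 µm², perimeter > 40 µm, both strict) are far from the
  sub-pixel convention error.
* Minimum-area rotated rectangles come from the convex-hull edge-alignment
  property (via shapely); a brute-force rotating-calipers oracle over hull
  edge orientations validates the area to 1e-6 relative in the tests.
  For exactly square boxes the "long" axis follows the hull edge that
  achieved the minimum — an arbitrary but deterministic tie-break.
* Box padding projects each vertex away from its diagonal partner by `h`
  pixels, producing a similar rectangle with diagonal `d + 2h`.  The
  default `h = 2·ng(c2)·ng_it(c2)` compensates the loss of cell-mask pixels
  where the grown CX43 mask intersects the grown interstitium mask near the
  cell poles; it is 0 when no CX43 channel is present, and can be
  overridden in the config (`h_px`).  Whether lengths are averaged before
  or after µm conversion is immaterial (the operations commute); conversion
  happens last here.
* Filtering order: contour filter before box fitting (cheap rejection),
  then the size filter on (L, W).  All four bounds are strict.

## CX43 quantification

* `Cex` and `r` are plain pixel-count percentages over `Mt` and its
  complement; both are undefined (raised) for empty denominators.
* Rasterization of rotated boxes uses the pixel-centre-inside-or-on-boundary
  rule (tolerance 1e-9).  The same rule is shared by compartment counting
  and by mask-agreement overlap, so the two stages can never disagree about
  which pixels a box owns.
* Compartment pools `N_i` count **all** box pixels clipped to the image,
  not only tissue pixels — the literal reading of "total pixels in the
  compartment".  Boundary pixels on a cut line go to the lower-index
  compartment; with pixel centres at half-integers ties are essentially
  non-occurring.
* Cells with no CX43 signal in their box (`Fl + Fp = 0`) are flagged
  `no_signal` and excluded from Clat distributions rather than coded as 0,
  to avoid inflating the lowest histogram bin.  Clat is reported with one
  decimal in output tables.
* The exponential model is fit by nonlinear least squares to the
  density-normalized histogram (default bin width 5 Clat-percent, exposed
  in config), seeded by a log-linear regression on the positive bins.
  Because bin-averaging an exponential only rescales its amplitude, the
  rate estimate is not biased by the binning.  The fit needs at least two
  non-empty bins and is statistically meaningful only for populations of
  tens of cells or more; the run report still records it for small runs,
  where it should be read as descriptive only.

## Agreement evaluation

Manual masks are pushed through the same contour → min-area-box stage, so
the overlap `I_ij` compares box rasters on the shared pixel grid,
normalized by the manual box area only (deliberately asymmetric).  The
percentile curve uses linear interpolation between closest ranks
(integer percentiles 1..100); the trapezoidal AUC closes the boundary with
`Pc(101) := Pc(100)`, which makes a constant curve at `c` integrate to
exactly `c/100` and self-evaluation to exactly 1.  With no automatic cells
every `I_i` is 0 and the AUC is 0.  "Matched" counts use strict
`I_i > 50`.

## Synthetic scenes

The generator emulates the features the pipeline actually consumes:
rectangular cell bodies (defaults 30–70 µm long, 10–30 µm wide in the
random-scene helper, within the plausible 20–200 × 5–50 µm envelope) at
arbitrary orientations on a 0.21 µm/px grid; CX43 as 4-px-thick bands at
both cell poles plus lateral specks hugging the long sides; a 1-px
interstitial halo around each cell; optional salt noise and a brightness
ramp (both default 0 — the recovery experiments characterise geometry, not
denoising).  CX43 is rendered at intensity 255 so the fixed 254 threshold
captures it after equalization; bodies are mid-range (200).

Lateral CX43 is planted only in the middle half of the cell length so that
under the four-quarter rule it falls entirely into the lateral
compartments, making `100·lateral/(lateral+polar)` the exact expected Clat.
When the requested lateral fraction exceeds the lateral strip capacity,
polar and lateral counts are scaled down jointly so the planted fraction is
preserved.  Ground truth records the boxes and the actually planted
fraction; the "manual" mask of a scene is the union of the ground-truth
boxes (synthetic, not expert-drawn).

**What passing the recovery experiments shows** — and does not.  On 20
seeded noise-free scenes (5 cells each) the pipeline under a
pure-thresholding configuration recovers every planted cell, lengths to a
mean error well under 2 pixels (0.42 µm), planted lateralization to well
under 5 points, and self-evaluation AUC ≈ 1.  That validates the geometry,
counting and agreement machinery end to end.  It does **not** exercise the
noise-removal/growth machinery against realistic confocal noise, brightness
heterogeneity, touching cells, or imperfect staining — real images need the
full morphology parameter set, and detection rates there are substantially
below 100 %.

The recovery experiments use the pure-thresholding configuration
(`threshold_only_config()`: all ranks 1, `h_px = 0`) because the scenes are
noise-free: the morphological cleanup exists to fight noise and its growth
step must then be compensated by box padding, neither of which has a role
when there is no noise to remove.

## Default parameters

The default config (`default_config()`) is the three-channel human
left-ventricle parameter set: thresholds 8/15/2 for c1/c2/c3, all opening
ranks 3, growth rank 3 with 3 iterations (5 for c2), no equalization,
`thr_c4 = 254`, scale 0.21 µm/px.  The 254 threshold on the equalized CX43
channel is the operating point at which expression stays below the
anatomically expected ~1.6 % of tissue while noise stays below 0.1 %.

## Known limitations

* Touching cells without an interstitium channel merge into one component
  (no watershed/nuclei-seeded splitting).
* Thresholds are global; strong brightness gradients degrade the masks
  (no local/adaptive thresholding).
* The exponential Clat model assumes a monotone decaying distribution; it
  is inappropriate for bimodal lateralization patterns.
* Proprietary microscope formats are not read; export to TIFF first.
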