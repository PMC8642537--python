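# Methods

octaquant quantifies 3 × 3 mm enface OCT angiography (OCTA) images of the
superficial and deep capillary plexus (SCP, DCP) and compares the resulting
indices between groups of eyes while respecting the correlation of fellow
eyes within a patient. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic validation does and
does not establish.

## Binarization referenced to the foveal avascular zone

The foveal avascular zone (FAZ) is physiologically vessel-free, so its
interior decorrelation signal is pure noise. The vessel threshold is

    t = mean(FAZ intensities) + k · SD(FAZ intensities),      k = 1.2

with the population SD (divide by n; a `faz_sd_population` switch selects
the sample SD). The FAZ mask comes from a user-supplied file when present;
otherwise a classical fallback takes the connected non-vessel component
containing the image center after closing 1-px gaps. The fallback requires
an avascular neighborhood at the center and fails loudly otherwise.

Three binarization modes exist (`binarize_source`):

* `gated` (default): a pixel is vessel when it exceeds the FAZ rule **both**
  on the raw intensity and on the multiscale Frangi vesselness response
  rescaled to [0, 1]. The vesselness factor suppresses speckle that is not
  tube-like; the intensity factor keeps the vessel footprint at its true
  caliber. On synthetic networks this keeps vessel density within ~1.4
  percentage points of truth across speckle levels 0–0.25 and yields a
  vessel diameter index near 2, the scale reported for real 304×304 scans.
* `enhanced`: threshold the rescaled vesselness only. The Frangi response
  of a 1–2 px capillary carries a ±2 px halo, so this mode widens vessels
  and inflates vessel density by ~10 points on capillary-scale networks;
  it is retained for sensitivity analyses.
* `raw`: threshold the raw intensity only (no vesselness gate).

Frangi scales default to {1, 1.5, 2} px — capillaries are 1–2 px at the
default 9.87 µm pitch (3 mm / 304 px).

## Vascular indices

* **VD** — vessel pixels as a percent of all pixels.
* **VLD** — skeleton (centerline) pixels as a percent of all pixels. The
  skeleton is a topology-preserving thinning (Euler number conserved,
  single-pixel width).
* **VDI = VD / VLD** — mean caliber in pixels. The inverse quotient is
  available (`vdi_inverted`) but gives values below 1 for any vessel wider
  than one pixel, inconsistent with reported magnitudes (≈ 2.2–2.3).
* **FD** — box-counting fractal dimension of the skeleton: the OLS slope of
  log N(s) against log(1/s) over box sizes {2, 4, 8, 16, 32, 64} px, grids
  anchored at the origin for determinism. A straight line measures ≈ 0.98,
  a filled field ≈ 1.97 at 304² (finite-size effects keep both slightly
  below the analytic 1 and 2).
* **VTI** — arc-to-chord ratio of skeleton segments, aggregated with
  arc-length weights (unweighted available). Segments are maximal chains
  between nodes of the reduced skeleton graph: 8-adjacency with diagonal
  edges dropped whenever the two pixels share a 4-adjacent skeleton pixel.
  In the reduced graph a clean curve pixel has degree exactly 2, so nodes
  (degree ≠ 2) and the chain partition are canonical — independent of
  traversal order and equivariant under 90° rotation. Isolated loops are
  split at their most distant pixel pair so each half has a nonzero chord.
  Segments shorter than 3 px (thinning spurs) are excluded.

  Arc length: the default estimator is the polygon through every 4th chain
  pixel (endpoints included, forward/backward averaged). The classic
  chain-code metric (1 per 4-step, √2 per diagonal) overestimates oblique
  digital arcs by up to 8% — a digital semicircle measures 1.055 · πr by
  construction — while the resampled polygon is exact on axis-aligned and
  diagonal straight runs, never falls below the chord, and measures a
  rasterized semicircle within ~0.5% of π/2. The chain-code length remains
  available on every `SegmentPath` and via `vti_arc_estimator="chain"`.
* **VCI** — isoperimetric quotient P² / (4π A), computed per 8-connected
  component and averaged with component-area weights (`vci_mode="pooled"`
  gives the single pooled quotient, which grows without bound for a
  connected capillary bed). P is the boundary length estimated as the
  polygon through every 4th vertex of the subpixel marching-squares
  contour: raw boundary-pixel counts measure a rasterized disk at 0.80 and
  Freeman-weighted counts at 1.08–1.10, while the resampled contour gives
  1.013 for the disk and 1.259 for a square (analytic 4/π ≈ 1.273). The
  literal pixel-count reading is available via `vci_pixel_counts`.

## Nonperfusion indices

Both measures threshold an exact Euclidean distance map (scaled to µm by
the pixel pitch) at the normal inter-capillary bound, default 30 µm for
both:

* **CNP** (capillary nonperfusion): distance to the nearest **vessel**
  pixel; the thresholded deficit is then attribute-filtered (connected
  regions below 500 px² removed) and eroded by a 1-px disk.
* **GPD** (geometric perfusion deficit): distance to the nearest
  **skeleton** pixel; no morphological post-filtering.

The FAZ is removed from the deficit last; the percent denominator is the
whole field (a flag excludes the FAZ from the denominator instead). Since
the skeleton is a subset of the vessel map, skeleton distances dominate
vessel distances pointwise and unfiltered GPD ≥ unfiltered CNP on every
image.

Both measures carry a deterministic negative bias for a well-demarcated
lesion: the band of lesion pixels within the distance threshold of the
surrounding vasculature is never counted, and the CNP erosion removes one
further boundary pixel. On noise-free synthetic fields with a 10% dropout
lesion this measures as ≈ −0.7 points for GPD and ≈ −1.3 points for CNP;
the tests assert this scale rather than pretending the estimators are
unbiased.

## Synthetic data

The generator produces three layers of ground truth, each a pure function
of (parameters, seed):

* **Shapes** (disk, square, bar, line, arc, annulus, grid) with exact truth
  masks, used as closed-form oracles.
* **Networks**: a sine-perturbed square lattice of 1-px capillaries (the
  spacing is solved from the target vessel fraction via two-family
  coverage), a few 3-px trunk vessels, a central avascular FAZ disk
  bounded by a 1-px parafoveal capillary ring, circular dropout lesions
  placed in the perifoveal annulus (border clipping allowed), and
  multiplicative Gaussian speckle. Defaults: 304² px over 3 mm, density
  target 33% (truth VD ≈ 29%), tortuosity amplitude 1.5 px over 40–80 px
  wavelengths, FAZ radius 380 µm (area ≈ 0.45 mm²), speckle SD 0.15.
  Capillary width must be 1 px at this resolution: 2-px vessels at 30%
  density imply 130 µm lattice spacing, which floods the 30 µm GPD
  threshold with "normal" deficit — real capillary beds at this density
  are single-pixel at 9.87 µm pitch.
* **Cohorts**: 92 patients, half bilateral (138 eyes), DME probability
  59/138 and PDR probability 44/138 per eye, drawn independently (the
  emulated cohort shows no DME–stage association). Every metric gets a
  shared Gaussian patient effect giving fellow-eye correlation ρ = 0.6.
  DME shifts GPD by +3 and CNP by +3 points and VD by −2.5 points (SCP;
  DCP effects scaled down), PDR carries smaller shifts of its own so the
  stage adjustment is meaningful. CST is drawn so each eye satisfies the
  classification rule (DME ⇔ CST > 350 µm or central cysts). With
  `with_images=True` the effects act on generator parameters instead and
  all metrics are measured by the full pipeline.

What the generator does **not** emulate: real capillary topology (it is a
perturbed lattice, not a vascular growth process), projection and motion
artifacts, segmentation error, intensity inhomogeneity, or eye-level
confounding between DME and image quality. Passing tests therefore
establish the correctness and calibration of the measurement chain, not
its accuracy on device images.

## Group comparison

The DME contrast for each metric is a Gaussian-identity marginal model
`metric ~ DME + stage` estimated by generalized estimating equations with
patients as clusters and an exchangeable working correlation. Inference
uses the Mancl–DeRouen bias-reduced sandwich covariance with a t reference
(df = clusters − parameters): at 92 clusters the plain robust sandwich is
measurably liberal (type-I ≈ 0.07–0.08 at nominal 0.05) while the
bias-reduced version is calibrated (≈ 0.05, verified on 1000 null
cohorts). p-values across the 15-metric family are Bonferroni-multiplied
(family size configurable). Within-subgroup CST associations use the same
machinery with CST as the continuous predictor.

Known limitation: in small subgroups where only a handful of bilateral
pairs inform the exchangeable correlation (e.g. ~8–10 both-DME pairs), the
efficient exchangeable estimator's robust CI undercovers (≈ 86–87%
observed at nominal 95% in simulation) because the variability of the
estimated working correlation is not captured. The larger subgroup
(≈ 15 informative pairs, ≈ 55 clusters) covers at ≈ 94%. Calibration
checks are therefore run where calibration is measurable; subgroup
analyses of the smaller group should be read with this in mind.

## Problem sizes and determinism

Default validation sizes: 100 seeded networks for structural invariants,
20 noise-free seeds for lesion recovery, 1000 null cohorts for type-I
calibration, 200 for power, 100 for CI coverage, 50 for effect directions.
Every stochastic component takes an explicit seed; fixed seed and
configuration reproduce CSV outputs byte-for-byte.
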