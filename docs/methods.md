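# Methods

This note records the model, the parameter choices, the numerical
decisions, and what the synthetic test bed does and does not establish.

## Pipeline model and assumptions

The segmenter assumes fundus photographs in which vessels are *dark,
locally line-like structures on a brighter, slowly varying background*,
imaged inside a roughly circular field of view (FOV) surrounded by black
frame. Two independent detection routes are fused:

1. an intensity route — vessels are pixels significantly darker than the
   local background estimate (49×49 box mean of the CLAHE image), found by
   adaptive thresholding of the difference image; and
2. a shape route — vessels are pixels where an oriented line model (the
   B-COSFIRE weighted geometric mean of blurred, shifted DoG responses)
   fires.

The AND of the two suppresses each route's characteristic false positives
(the intensity route hallucinates on noise and lesion edges; the shape
route responds to any elongated contrast, including the FOV rim). The
subsequent gate-and-rethreshold step re-anchors the consensus on the
enhanced image before the final OR. Because the gated image is zero
outside the consensus map and thresholding is strict, the OR's second
operand is a subset of the first; the OR is kept for interface fidelity
and as the hook for alternative gating rules.

All processing is floating point on [0, 1]; conversion to 8-/16-bit
happens only at file boundaries. Operations run on the full frame and are
masked afterwards; before B-COSFIRE filtering the region outside the FOV
is filled with the median interior intensity so the rim does not read as
a high-contrast line.

## Key parameters

| parameter | default | units | rationale |
|---|---|---|---|
| light-reflex opening disc | diameter 3 | px | smallest disc that removes a 1-px reflex without merging close vessels |
| mean / Gaussian kernels | 3×3, 9×9 (var 1.8) | px | standard denoising pair for ~565-px fundus frames |
| CLAHE grid, clip | 8×8 tiles, 0.01 | — | gentle contrast amplification bounded against noise |
| background kernel | 49×49 | px | wide enough to erase vessels and anatomy, narrow enough to track illumination drift |
| MISODATA tile | 64 | px | tiles large enough for stable class statistics |
| MISODATA tolerance | 0.25 | fraction of ROI range | a local threshold further than this from the global one is judged unreliable (vessel-free tile) and replaced |
| prune area | 25 | px² | minimum credible vessel fragment |
| eccentricity cutoff / round-area bound | 0.7 / 300 | — / px² | reject small round blobs; elongated or large structures always survive |
| B-COSFIRE symmetric | σ 2.4, ρ {0..8 step 2}, σ₀ 3, α 0.7 | px | published retinal configuration of the line detector |
| B-COSFIRE asymmetric | σ 1.8, ρ {0..22 step 2}, σ₀ 2, α 0.1 | px | likewise, for vessel endings |
| orientations | 12 | — | π/12 steps resolve retinal vessel curvature |
| response threshold t | 0.4 | fraction of max | suppresses the geometric mean's low-level noise floor |
| CAL tolerances ε, β | 2, 2 | px | dilation slack for the area and length scores |

Everything is overridable through `PipelineConfig` / YAML.

## Numerical choices

- **ISODATA convergence.** The Ridler–Calvard iteration stops when the
  update is below eps = 1/512 *and* the induced two-class partition is
  stable. The update-size test alone can stall several 8-bit levels short
  of the fixed point when the class means drift slowly; requiring a stable
  partition lands on the exact discrete fixed point. Degenerate
  (constant) regions raise an error rather than inventing a threshold.
- **MISODATA reconciliation.** A tile's local threshold is kept iff
  |T_local − T_global| ≤ tolerance × (ROI intensity range); tiles with
  < 25% ROI coverage or constant content inherit the global value. Chosen
  thresholds are bilinearly interpolated between tile centers (constant
  extrapolation at the border) to avoid blocking seams; a config switch
  restores hard tiles. Foreground uses strict `>`, so constant images
  yield empty output.
- **Difference image clamp.** `I_avg − I_clahe` is clamped at 0: bright
  structures (optic disc, exudates) would go negative, and only
  vessel-positive contrast is meaningful to the threshold stage.
- **DoG discretization.** Kernels are sampled on a ⌈3σ⌉ grid (5σ in the
  zero-sum tests). The integer-lattice sum of the inner 0.5σ Gaussian
  deviates from 1 noticeably below σ ≈ 1, so exact DC rejection holds
  only at the retinal scales used (σ ≥ 1.8); residual DC leakage is
  ~1e-4 of the input offset.
- **Weighted-maximum blur.** Computed as a grayscale dilation in the log
  domain with the Gaussian (density normalization, peak 1/(2πσ′²)) as the
  additive structuring element over a ±3σ′ window. The per-tuple
  normalization constant cancels in the geometric mean up to a uniform
  scale, which the final [0, 1] rescale removes.
- **Shifts.** Tuple displacements (−ρ cos φ, −ρ sin φ) are applied by
  bilinear interpolation (`order=1`, nearest edge fill); values are
  re-clamped at 0 afterwards so interpolation cannot create negative
  support. Blur results are cached per (σ, ρ), so a 12-orientation bank
  pays for the blurs once.
- **Geometric mean.** exp of the weighted mean of logs, with explicit
  zero propagation: any pixel where a tuple response is ≤ 0 is zeroed.
  Tuple weights are exp(−ρ²/2σ̂²) with σ̂ = max(ρ)/3 (all 1 when every
  ρ = 0).
- **Eccentricity.** Components are described by the ellipse with the same
  second central moments; eccentricity √(1 − λ₂/λ₁). 8-connectivity is
  the default so diagonal vessel pixels remain one component.
- **Ties and degenerate inputs.** Thresholding is strict everywhere;
  degenerate enhanced/gated images produce an empty segmentation with a
  warning rather than an error, since a vessel-free image is a valid
  input to the end-to-end pipeline.

## Synthetic test bed

The generator draws `n_vessels` quadratic Bézier curves from a virtual
optic-disc location to the FOV periphery, strokes them with widths
sampled from `width_range` (measured by distance transform), darkens the
green plane by `vessel_contrast` with a Gaussian cross-profile (smoothed
indicator, σ = 0.8 px), adds a 1-px bright reflex line to the widest
`reflex_fraction` of vessels, applies a linear illumination tilt, and
finishes with salt-and-pepper (density 0.002) and Gaussian (SD 0.01)
noise. The red plane renders the bright disc the automatic FOV mask
expects. Defaults — 256 px frames, 8 vessels, widths 1–8 px, contrast
0.3, gradient 0.15 — were chosen to mirror the difficulty of low-
resolution fundus benchmarks: thin vessels near the noise floor, a
reflex that splits wide profiles, and illumination drift comparable to
vessel contrast. One integer seed drives every random stream, and images
are bitwise reproducible.

What the fixtures do **not** model: vessel branching topology, central
vessel reflex curvature, pathology (hemorrhages, exudates, drusen),
optic-disc texture, JPEG artifacts, and inter-image color variation.
Passing the synthetic battery therefore demonstrates the pipeline's
mechanics (polarity, fusion algebra, rotation invariance, noise
robustness ordering) — not clinical-grade performance on real retinas.

Standard problem sizes: unit tests run on 16–72 px rasters; end-to-end
checks use the 256-px battery (a full segmentation takes a few seconds),
which keeps the default test run comfortably small while exercising every
stage at realistic vessel scales.

## Known limitations

- The AND fusion bounds sensitivity by the weaker branch; 1-px vessels
  at low contrast are the dominant miss class (the thin-only fixture
  scores Dice ≈ 0.67 vs ≈ 0.87 for mixed widths).
- The two-point AUC = (Sn + Sp)/2 is a summary of one operating point,
  not a ROC integral; no threshold sweep is provided by design.
- The eccentricity/area rejection rule uses fixed cutoffs; very short
  true vessel stubs (< 25 px after fusion) are discarded.
- The B-COSFIRE configuration is the fixed published retinal one; no
  per-image filter learning is implemented.
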