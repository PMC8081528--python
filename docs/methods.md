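# Methods

`conecensus` quantifies cone photoreceptor survival and metabolic state
from fluorescence images of retinal flat-mounts. This note documents the
models behind each stage, the parameters that matter, what the synthetic
data generator does and does not emulate, and the numerical choices made
where the design was genuinely open.

## Scientific setting

In retinitis pigmentosa models (e.g. *rd1* mice), rods die first and
cones follow, fastest in the central retina. Gene-therapy rescue
experiments therefore measure cone survival as the number of labeled
cone nuclei (a bright nuclear H2BGFP tracer, delivered at roughly 20 %
labeling efficiency) inside the central disk of half the retinal radius
of a flat-mounted retina. Metabolic consequences are read out ex vivo
with ratiometric sensors and dyes (PercevalHR for ATP:ADP, JC-1 for
mitochondrial membrane potential, pHRed for pH, iGlucoSnFR for glucose,
RH421 for Na+/K+-ATPase function, mitoRFP normalized to H2BGFP).
Magnitude anchors used throughout: ~50,000 cones in the half-radius
region of a wild-type retina (hence ~10,000 labeled at 20 % efficiency)
and ~11,000 labeled cones there in *rd1* at P20, just before central
degeneration.

## Synthetic flat-mounts (`synthetic`)

The generator produces a stated world with exact ground truth:

- **Geometry.** A roughly circular tissue region; the outline can be
  modulated by low-order (k = 2..5) Fourier roughness with peak relative
  amplitude `boundary_roughness`.
- **Nucleus placement.** Hard-core (minimum center distance
  `min_separation`, default 4 px — nuclei are solid objects) dart
  throwing, optionally thinned by a radial density profile
  d(r) ∝ 1 + g·r/R ("central_depleted", emulating faster central loss).
  Placement is batched: candidate points are drawn uniformly, thinned by
  boundary/density/crater rules, and conflict-resolved with a k-d tree;
  a run that cannot reach `n_cones_total` within a 100x candidate budget
  raises an error naming the achieved count. Fill fractions above ~80 %
  of the random-sequential-adsorption jamming density (~0.7·A/d²
  nuclei for area A) are infeasible by design.
- **Labeling and rendering.** Each nucleus is labeled independently with
  probability `labeling_efficiency` (default 0.2). Only labeled nuclei
  are rendered — the tracer is invisible in uninfected cells — as
  isotropic 2-D Gaussians of sd `psf_sigma` (default 1.3 px) with
  lognormal peak amplitudes (mean 2000, CV 0.2 on a 16-bit scale).
  `psf_sigma` is deliberately below `min_separation`/(2√2): with that
  margin no admissible pair of labeled nuclei merges into a single
  response peak, which is the property that makes automated counting of
  real flat-mounts feasible in the first place.
- **Craters.** Circular cone-free patches are carved by excluding
  nuclei from crater disks; the tissue background is unchanged.
- **Background and noise.** Constant offset (default 200) plus Gaussian
  read noise (sd 20) or Poisson shot noise, clipped at the 16-bit
  saturation value. Images are float64 in memory; quantization to
  uint16 happens only in TIFF output, so noiseless algebraic contracts
  (e.g. ratio exactness) hold exactly in memory.
- **Presets.** "wt" (200,000 nuclei) and "rd1_P20" (220,000 nuclei) on
  a 3328² reference frame reproduce the census anchors above; a preset
  can be rescaled to a smaller image, shrinking the census by the area
  factor so per-area density — and hence detectability — is preserved.
- **Ratio pairs.** Two registered channels share cell positions; the
  numerator equals `true_ratio` times the denominator (including the
  background) before per-channel noise, which is the unique rendering
  for which the whole-field ratio of means equals `true_ratio` exactly
  without background subtraction.

Not emulated: optics-accurate PSFs, 3-D structure, photobleaching,
motion, relaxing-cut petals, spatially varying background, or
autofluorescence. A green detection test on this world therefore
establishes algorithmic correctness at realistic density and SNR, not
robustness to every real-world artifact.

## Retinal geometry (`geometry`)

The outline circle is fitted as: Otsu threshold → largest connected
foreground component → center at its centroid, radius the
equivalent-area radius √(area/π). Equivalent-area is preferred over
maximum centroid-to-boundary distance because flat-mount outlines are
ragged. The counting region is the concentric disk of half that radius
with a strict `<` boundary convention (a point at exactly r/2 is
outside); the convention is arbitrary but fixed and used identically
for ground truth, detections, and masks. Manual (operator-drawn)
circles in the manifest always override the automatic fit.

## Cone detection (`detection`)

The "Gaussian model" of a labeled nucleus is realized as:

1. scale-normalized Laplacian-of-Gaussian matched filter at
   `sigma_expected` (response ≈ A/2 at the center of a matched spot);
2. local maxima of the response within the `min_separation`
   neighborhood, with a row-major plateau tie-break (strictly greater
   than earlier neighbors, ≥ later ones) so a perfectly symmetric
   merged pair yields exactly one candidate. Candidates below
   0.2 × `peak_threshold` in response are skipped: a spot whose fitted
   amplitude could pass the threshold maps at least ~0.3 of it into the
   response, so the floor cannot change the final spot set;
3. per-candidate least-squares fit of amplitude, sub-pixel center,
   isotropic variance, and local background offset in a ±3σ window
   (damped Gauss–Newton, fixed 15 iterations, vectorized over all
   candidates, hence deterministic). The fit is Gaussian-weighted
   toward the window center (weight sd 1.5σ) and the center update is
   clipped to ±0.75 px of the candidate pixel; both keep a weak spot's
   fit anchored against a brighter neighbor while remaining exact for
   noiseless Gaussian data;
4. filters: fitted amplitude ≥ `peak_threshold` (above local
   background) and fitted variance within `variance_bounds` (default
   0.25–4 × σ², i.e. spot sd between half and twice the expected);
5. greedy non-maximum suppression at radius `min_separation` (default
   2σ), strongest amplitude first, ties broken by lower (y, x).

This ordering makes the count monotone non-increasing in
`peak_threshold`: the threshold always removes the weaker member of any
suppressing pair first. The contract is pinned by an exhaustive
pixel-scan oracle (naive loops over every pixel and every pair) that
must agree spot-for-spot, not by any library blob detector.

"Variance of distribution" is read as the fitted spot-size variance;
the alternative reading (variance of the intensity histogram) is not
implemented. Absolute threshold values are study-specific and never
published, so only the calibration procedure is reproducible:
`calibrate_params` grid-searches (threshold, variance bounds) against
manually counted reference retinas, minimizing Σ|auto − manual| with
ties broken toward the higher (more conservative) threshold, and the
winning parameters are then frozen for every image of the study.

## Ratiometric quantification (`ratiometric`)

Each two-channel image reduces to the ratio of ROI means (default ROI:
whole field; a mean-of-pixel-ratios mode exists behind a flag but is
not default because it is unstable near zero-valued pixels). No
background subtraction. Ratios are normalized per condition (culture
medium) to the mean of the control group, making the control mean
exactly 1 within every condition; the sampling unit is the image
(typically 3–5 per retina).

## Group statistics (`stats`)

Classical pooled-variance two-tailed Student's t (Welch behind a flag),
paired t as one-sample t on differences, and one-way ANOVA with
Dunnett's two-sided many-to-one comparisons (multivariate-t
distribution via scipy, seeded; valid for unbalanced designs; reduces
to the t-test for a single comparison). Counting experiments use
retinas as n; imaging experiments use images as n. Star labels follow
strict inequalities (p = 0.05 → NS, p = 0.01 → "*"). Degenerate-input
conventions: two zero-variance groups with equal means give p = 1,
unequal means p = 0; constant nonzero paired differences raise.

## Pipeline (`pipeline`, `cli`)

Runs are configured in YAML, deterministic given the master seed (child
seeds are derived per image via crc32-keyed `SeedSequence`, all below
2³¹), and write relative paths so a run directory is byte-reproducible
and relocatable. Every run emits per-image spot CSVs, a group summary,
a comparisons CSV with stars, and a JSON report echoing all parameters.

## Known limitations

- The detector assumes isotropic spots; elongated or fused nuclei
  beyond the NMS radius are not split (no watershed).
- The physical pixel pitch of the original imaging is unstated, so the
  model is purely pixel-based; physical units enter only through the
  operator's choice of parameters.
- Packing constraints cap the density contrast a simulated rescue can
  use at a given `min_separation`; the provided experiments build the
  contrast downward from the preset density.
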