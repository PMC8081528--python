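# conecensus

Automated quantification for cone-survival and metabolic-imaging
experiments on retinal flat-mounts.

In mouse models of retinitis pigmentosa, rods die first and cones
follow — fastest in the central retina. Gene-therapy rescue studies
measure cone survival by counting fluorescently labeled cone nuclei
(nuclear H2BGFP tracer, ~20 % labeling efficiency) inside the central
**½-radius** disk of a flat-mounted retina, and probe cone metabolism
ex vivo with ratiometric sensors and dyes (PercevalHR, JC-1, pHRed,
iGlucoSnFR, RH421, mitoRFP). This package implements that whole
quantitative chain as a tested, reusable library and CLI:

- **`conecensus.synthetic`** — seeded synthetic flat-mounts and
  two-channel sensor pairs with exact ground truth (hard-core nucleus
  packing, radial density gradients, cone-free "craters", partial
  labeling, realistic noise), including census-anchored presets
  (`"wt"` ≈ 50,000 cones in the ½-radius; `"rd1_P20"` ≈ 11,000 labeled
  cones there).
- **`conecensus.geometry`** — retinal outline fitting (Otsu → largest
  component → equivalent-area radius) and the strict ½-radius ROI.
- **`conecensus.detection`** — Gaussian-model nuclear spot detection:
  scale-normalized LoG matched filter, sub-pixel Gaussian refinement
  with fitted local background, amplitude/spot-variance gating,
  non-maximum suppression, plus grid calibration of the fixed
  thresholds against manually counted reference retinas.
- **`conecensus.ratiometric`** — ROI ratios of sensor channel pairs and
  per-condition normalization to the control group's mean.
- **`conecensus.stats`** — pooled-variance Student's t (unpaired and
  paired), one-way ANOVA with Dunnett's many-to-one comparisons,
  mean ± SD/SEM summaries, and the standard significance-star labels.
- **`conecensus.pipeline` / `conecensus` CLI** — end-to-end seeded runs
  (`simulate`, `count`, `ratio`, `stats`, `full`) from YAML configs,
  with CSV/TIFF/JSON outputs that are byte-reproducible per seed.

## Worked example

Count cones on a synthetic degenerating retina and compare groups:

```python
import conecensus as cc
from conecensus.synthetic import preset, generate_flatmount
from conecensus.geometry import manual_geometry

spec = preset("rd1_P20", image_size=1024, seed=0)   # scaled rd1-like retina
image, truth = generate_flatmount(spec)
print("ground truth labeled in half-radius:", truth.n_labeled_half_radius)

census = cc.detect_cones(image, cc.DetectionParams())
geom = manual_geometry(spec.center, spec.retina_radius)
print("automated count in half-radius:   ", cc.count_in_half_radius(census, geom))

res = cc.unpaired_t_test([10234, 10977, 11123], [5130, 4779, 5442],
                         labels=("treated", "control"))
print("t =", round(res.statistic, 3), "p =", f"{res.p_values[0]:.2e}", res.stars[0])
```

```
ground truth labeled in half-radius: 1074
automated count in half-radius:    1073
t = 16.883 p = 7.22e-05 ****
```

The generator knows exactly where every nucleus is; the detector
recovers 1073 of the 1074 labeled nuclei inside the ½-radius ROI. The
t-test line shows the reporting convention: per-retina counts, pooled
two-tailed Student's t, and the star label ("****" for p ≪ 0.0001).

The same experiment from the shell:

```sh
conecensus full --config experiment.yaml
```

where `experiment.yaml` names the simulated arms (or, for real data, a
manifest CSV of TIFFs with optional operator-drawn geometry columns).
The run directory receives per-image spot tables, a counts summary, a
comparisons CSV with p-values and stars, and a JSON run report that
echoes every parameter and seed.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline end-to-end behavior from scratch: it
simulates a two-arm cone-rescue counting experiment (6 retinas/arm,
twofold density contrast) and a two-arm PercevalHR sensing experiment
(6 image pairs/arm, 1.5× ratio contrast), runs detection, counting,
normalization, and group statistics on them, prints the resulting
p-values, and writes the results JSON to `--out`.
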