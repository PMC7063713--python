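# macuquant

Quantification of macular structure and microvasculature from OCT and
OCT-angiography, aimed at studying early dysthyroid optic neuropathy (DON)
in thyroid-associated ophthalmopathy (TAO) — and, more generally, any
setting where inner-retinal thinning and parafoveal capillary loss are
candidate biomarkers.

The package implements, as a tested and reusable pipeline:

* **Intra-retinal layer segmentation** of radial B-scans: nine boundaries
  traced by a gradient-cost shortest-path search (column-wise dynamic
  programming with bounded vertical steps), lateral scale corrected for
  ocular magnification by Bennett's abbreviated formula
  q(AL) = 0.01306·(AL − 1.82), thickness maps over a 2.5 mm fovea-centered
  disk, and regional means for NFL, GCL+IPL, GCC (= NFL + GCL+IPL),
  INL+ORL, and total retina in the C / TAZ / S / T / I / N regions.
* **Retinal capillary density (RCD, %)** from 304×304 en face angiograms:
  SSI > 40 quality gate, bicubic upsampling to 1024², FAZ boundary
  detection (Canny-seeded morphological Chan–Vese level set), a noise
  floor from the fixed 0.60 mm foveal avascular disk, global thresholding
  plus a vessel-width filter for the large vessels, adaptive (local-mean)
  thresholding for all vessels, map subtraction for the capillaries, and
  regional densities over the TAZ (2.50 mm annulus minus the 0.60 mm FAZ
  disk), six concentric rings C1–C6 (diameters 0.92–2.50 mm), and four
  quadrant sectors.
* **Cohort statistics** with eye-cluster adjustment (two eyes of one
  patient are correlated): three-group comparisons, Pearson correlations,
  empirical (Mann–Whitney) and binormal ROC/AUC
  (Φ(|μ₁−μ₂|/√(σ₁²+σ₂²))), and a two-marker logistic composite index with
  Youden-optimal cutoffs.
* **Synthetic generators** — layered B-scan phantoms, angiogram phantoms,
  and three-group cohorts — every one seed-deterministic and emitting its
  ground truth, so the whole chain is validated end-to-end against known
  answers.

## Worked example

Simulate a cohort at the default study conditions (38 control / 36 non-DON
/ 38 DON eyes with the default group means and SDs, ~65% bilateral
patients, latent GCC–RCD correlation 0.312) and run the report:

```bash
macuquant simulate cohort --seed 1 --out demo/
macuquant cohort-report demo/cohort.csv --out demo/report/
```

`demo/report/` then contains the thickness and density comparison tables,
the correlation table, single and composite ROC tables, and a manifest.
With seed 1 the key rows read:

```
measure  control_mean  control_sd  nonDON_mean  DON_mean  p_control_vs_DON
GCC_TAZ        94.861      11.315       85.251    83.869             0.004

      x        y      r     p   n
GCC_TAZ SRCL_TAZ  0.319 0.006  74

indicators        auc  cutoff_a  cutoff_b  sensitivity  specificity
GCC_TAZ          0.703    84.061        —        55.3         81.6
SRCL_C6          0.709    60.794        —        50.0         97.4
GCC_TAZ+SRCL_C6  0.845    98.242    64.889       86.8         68.4
```

Reading this: GCC thickness in the total annular zone is ~9.6 μm thinner
in DON eyes than controls and the difference is flagged at the α = 0.01
family threshold; thickness and superficial capillary density correlate at
r ≈ 0.32 across the 74 TAO eyes; and the logistic composite of GCC
thickness with C6-ring capillary density separates DON from control eyes
(AUC 0.845) better than either marker alone, with one cutoff per component
(μm and %) at the Youden-optimal operating point.

Per-eye image quantification works the same way from the shell
(`macuquant simulate bscan|angio`, `segment-bscan`, `quantify-angio`,
`run-eye`) or from Python via `macuquant.pipeline.run_eye`.

## Layout

```
src/macuquant/
  geometry.py       fovea-centered grids and region masks (C, TAZ, rings, sectors)
  segmentation.py   gradient cost, shortest-path tracing, thickness maps
  angio.py          RCD chain: gate, upsample, FAZ, dual threshold, densities
  stats.py          group comparisons, Pearson, ROC/AUC, composite index
  synth.py          B-scan / angiogram / cohort generators with ground truth
  pipeline.py       per-eye records and cohort report bundles
  config.py, cli.py configuration (YAML round-trip) and the command line
docs/methods.md     model, parameter, and validation notes
```
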