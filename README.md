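# strokeatlas

Voxel-wise, population-based lesion–outcome atlases for ischemic stroke, and
outcome prediction from them.

Binary infarct masks (one per patient) are normalized into a common
stereotactic grid (512×512×64 voxels at 0.320119×0.320119×2 mm, or a reduced
grid for simulation) with a landmark-driven 12-block piecewise-affine
transform. For each clinical parameter (mRS at days 7–360, Barthel Index at
days 30–360, …) a stroke map accumulates a weighted sum, a weight sum and a
contributor count per voxel over all normalized lesions; the map value at a
voxel is the weighted mean of the parameter over the patients whose lesion
covers it. Eight weighting variants are provided (plain averaging, inverse
volume, and overlap/distance-driven weights that depend on the case under
prediction), plus case selection by infarct volume and NIHSS ranges, exact
merging of pre-computable maps over disjoint cohorts, and an infarct
frequency map for low-evidence masking.

A new case is predicted by normalizing its lesion and taking the unweighted
mean of the map values inside it. The evaluation machinery runs the full
leave-one-out grid (8 weights × 4 volume ranges × 4 NIHSSa ranges × 4 NIHSS7
ranges = 512 cells per case per parameter), summarizes errors per variant and
selection mode, computes error-reduction ratios, best selection variables,
pairwise variant t-tests and dichotomized ROC analyses (mRS 0–2|3–6, 0–1|2–6,
BI 0–45|46–100). A synthetic-cohort module generates cohorts from smooth
ground-truth outcome fields so the whole pipeline is testable without any
patient data.

## CLI

```sh
# generate a synthetic cohort (native masks, landmark JSONs, clinical CSV)
strokeatlas simulate --n 64 --seed 1 --sigma 0.5 --out cohort/

# build one map (weight 1 = plain averaging, pre-computable)
strokeatlas build --cohort cohort/ --param mRS90 --weight 1 \
    --vol 0:8.0 --out atlas/mRS90/

# merge maps computed at different sites over disjoint cohorts
strokeatlas merge atlasA/mRS90/ atlasB/mRS90/ -o merged/mRS90/

# predict a new case from a directory of map bundles
strokeatlas predict --atlas atlas/ --mask cohort/masks/case0000.nii \
    --landmarks cohort/landmarks/case0000.json --min-count 0 --out report.json

# full leave-one-out evaluation (512-cell grid, all nine parameters)
strokeatlas evaluate --cohort cohort/ --grid full --out results/
```

Formats: masks and maps are NIfTI-1 (`.nii`); the clinical table is a CSV
with columns `case_id, infarct_volume_cm3, nihss_admission, nihss_day7,
mrs7..mrs360, bi30..bi360` (empty cell = missing); landmarks are per-case
JSON (`AC, PC, L, R, A, P, S, I, msp_normal` in native mm). A map persists
as a directory with `sum.nii`, `weight.nii`, `count.nii` and `map.json`.

## Layout

- `src/strokeatlas/core.py` — atlas grid, contour/case/map/selection types,
  volume/overlap/centroid primitives
- `src/strokeatlas/normalization.py` — landmark sets, 12-block
  piecewise-affine transform, pull-back mask resampling
- `src/strokeatlas/weighting.py` — the eight weight variants (pluggable
  registry)
- `src/strokeatlas/build.py` — case selection, map aggregation, frequency
  maps, exact merging
- `src/strokeatlas/prediction.py` — distribution extraction and per-case
  prediction
- `src/strokeatlas/evaluation.py` — leave-one-out grid, planner, summaries,
  t-tests, ROC
- `src/strokeatlas/synthetic.py` — ground-truth fields and synthetic cohorts
- `src/strokeatlas/io.py`, `src/strokeatlas/cli.py` — file formats and the
  command line
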