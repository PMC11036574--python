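# immunorad

A tested, reusable pipeline for a two-stage chemoradiotherapy-response
analysis:

1. **Immunomarker classifier** — scores treatment-induced changes in
   tumor-infiltrating CD8+ T cells and CD68+ macrophages. A fixed reference
   linear model (`immune_score = 0.4569 + 0.0041·ΔCD8 − 0.0009·ΔCD68`,
   cutoff 0.307) ships as immutable constants, and the same construction
   recipe (z-score → 10-fold cross-validated LASSO logistic regression over
   13 marker changes) can be refit on new cohorts.
2. **CT radiomics signature** — 97 features (24 intensity, 20 geometric,
   53 textural: GLCM/GLRLM/GLSZM) extracted from NIfTI volume + VOI mask
   pairs on the native anisotropic grid, screened univariately at p < 0.2,
   then fed to the same cross-validated L1 logistic path to predict the
   immune class; evaluated with ROC/AUC (DeLong CI), Youden-index cutoffs,
   and uncorrected Pearson chi-square stratification tests.

A fully seeded **synthetic cohort generator** (latent hot/cold immune state
driving marker changes, response probability, and class-dependent tumor
texture) makes every stage testable without any external data.

## CLI

```bash
immunorad simulate --n-patients 30 --seed 7 --out cohort/
immunorad extract --cohort cohort/ --out features.csv
immunorad fit-immune --cohort cohort/ --out immune_model.json
immunorad fit-radiomics --features features.csv --cohort cohort/ \
    --label immune_group:high --out model.json
immunorad evaluate --cohort cohort/ --out evaluation.json
immunorad run-all --seed 7 --out run/          # end-to-end, all artifacts
immunorad fixtures --out fixtures/             # printed 2x2 reference tables
```

`run-all` writes `features.csv`, `screening.json`, `immune_model.json`,
`model.json`, `evaluation.json`, `scores.csv`, the resolved `config.json`
and a structured `run_log.json`; reruns with the same config are
byte-identical.

## Package layout

| module | purpose |
| --- | --- |
| `immunorad.synthetic` | seeded synthetic cohorts (volumes, masks, clinical CSV) |
| `immunorad.volumes` | NIfTI/CSV I/O, VOI cropping, typed patient records |
| `immunorad.features` | the 97-feature bank; `registry.json` is the source of truth |
| `immunorad.signature` | z-scoring, screening, L1 logistic path + CV, reference model |
| `immunorad.evaluation` | ROC/AUC, Youden cutoffs, 2×2 tests, rank tests, blood ratios |
| `immunorad.pipeline` / `immunorad.cli` | orchestration, config, CLI |

Notable conventions (documented in the module docstrings): the positive
class is CR and a positive call is `score ≥ cutoff`; chi-square tests are
uncorrected by default; quantization is equal-width with 64 bins over the
in-mask range; GLCM/GLRLM accumulate over the 13 unique 3D directions at
distance 1 voxel and are merged before feature computation; no resampling
is performed.
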