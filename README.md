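# frtnorm

Norming pipeline for a DRM-style false-recognition memory test: item-level
scoring, regression-based demographic adjustment, nonparametric
Equivalent-Score (ES) banding, clinical correction grids, and a calibrated
synthetic-cohort generator that stands in for the (unreleased) normative
sample.

## The test in brief

Three word lists (positive / neutral / negative valence) are encoded and
freely recalled; each recognition block then presents 12 items: 6 studied
words, 1 critical lure, 2 strong semantic associates and 3 unrelated words.
Six subscores result:

| subscore            | range | orientation    |
|---------------------|-------|----------------|
| free recall         | 0–36  | higher better  |
| recognition         | 0–36  | higher better  |
| failed recognition  | 0–18  | higher worse   |
| semantic false memory     | 0–9  | higher worse |
| non-semantic false memory | 0–9  | higher worse |
| total false memory  | 0–18  | higher worse   |

Two structural identities always hold: `total_fm = semantic_fm +
non_semantic_fm` and `recognition + failed_recognition + total_fm = 36`
(recognition counts hits **and** correct rejections).

## What the package does

- **`frtnorm.scoring`** — validates response sheets (3 lists, 6/1/2/3
  recognition composition) and computes the six subscores.
- **`frtnorm.normative`** — covariate transforms (`log10(100 − age)`,
  `√education`, sex coded female = −0.42 / male = 0.58), the published
  adjustment formulas (`PUBLISHED_MODEL`), OLS fitting with p < 0.05
  predictor retention, and raw → adjusted conversion.
- **`frtnorm.equivalent`** — one-sided nonparametric tolerance-limit ranks
  via the binomial construction (outer/inner = 6th/18th observation at
  n = 232, 95/95), five-level ES banding, and cut-offs.
- **`frtnorm.grid`** — age × education (× sex) correction grids at band
  midpoints, with extrapolation flags for demographically unoccupied cells
  and exact-formula fallback.
- **`frtnorm.cohort`** — synthetic normative cohorts: demographics drawn
  from the published frequency table, subscores from the published linear
  models plus calibrated noise and two latent person factors, structural
  identities enforced exactly.
- **`frtnorm.pipeline` / `frtnorm.cli`** — deterministic batch runs and
  versioned YAML/CSV artifacts.

## CLI

```sh
# 1. synthesize a normative cohort (or bring your own CSV with columns
#    subject_id,age,sex,education,free_recall,recognition,
#    failed_recognition,semantic_fm,non_semantic_fm,total_fm)
frtnorm simulate --n 232 --seed 7 --out cohort.csv

# 2. score item-level response sheets (one row per recognition item plus a
#    FREE_RECALL row per list; see frtnorm/scoring.py for the dialect)
frtnorm score sheets.csv --out raw_scores.csv

# 3. fit models, ES tables, grids and stratified cut-offs
frtnorm fit-norms cohort.csv --out-dir artifacts/

# 4. render a correction grid from the fitted model
frtnorm grid --model artifacts/model.yaml --subscale free_recall

# 5. evaluate newly tested subjects
frtnorm evaluate subjects.csv --artifacts artifacts/ --out report.csv
```

All randomness flows through `--seed`; identical inputs and seeds produce
byte-identical artifacts.

## Regenerating the generator calibration

Noise SDs, latent loadings and intercept offsets in `frtnorm.cohort` are
frozen from a one-off moment-matching run:

```sh
python -m frtnorm.calibration   # ~3 min; prints the constants
```
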