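# omt — analysis pipeline for the "What was where?" visuospatial memory task

`omt` is a tested, fully synthetic-data-driven implementation of the
analysis chain for a tablet-based delayed-reproduction short-term-memory
test used to stratify people across the Alzheimer's disease continuum
(elderly healthy controls, subjective cognitive decline, mild cognitive
impairment, Alzheimer's disease dementia — EHC / SCD / MCI / AD).

In the task a participant sees 1 or 3 fractal stimuli at random screen
locations, and after a 1 s or 4 s delay must identify the studied item
against a foil and drag it back to its remembered location. Each session is
8 practice trials plus 120 test trials (10 per condition per block, three
blocks), with stimuli drawn from a 196-fractal library (49 shapes × 4
colours).

Eight metrics are computed per participant-session, each cumulated as the
unweighted mean over the four set-size × delay conditions:

* **basic** — identification accuracy; absolute localization error
  (Euclidean, screen fractions); identification time; localization time;
* **mixture** — target detection, misbinding (swap errors), guessing and
  imprecision, obtained by a permutation attribution: per correct trial the
  response is classified to whichever is nearest of (1) the target's true
  location, (2) the nearest non-probed in-trial item, (3) an item location
  drawn from a random other trial, repeated 5000 times per trial; the class
  proportions estimate P(target), P(misbinding), P(guessing). Imprecision
  is the target-weighted SD of the radial error. Misbinding requires at
  least two objects and is never computed for 1-item trials.

Around these sit the study's statistics: group ANCOVAs with age, gender
and education as covariates and Holm-corrected contrasts; a 2×2
repeated-measures ANOVA with η² magnitude classes; Group × Session mixed
models; regressions of one-year ACE change on baseline metrics; h-tests
for dependent overlapping correlations; hippocampal-volume regressions;
and linear-SVM classification (task metrics vs the ACE screening score)
with paired DeLong ROC comparisons.

Because no public dataset exists for this task, the package includes a
first-class generative simulator: a mixture-model response generator with
per-group parameter presets, a latent severity score that couples task
parameters, ACE and hippocampal volume, and a two-session drift for the AD
group. Every estimator in the pipeline is validated against this known
ground truth (parameter recovery, type-I calibration, planted-effect
detection).

## Worked example

The numbered drivers under `analysis/` run the full study on a simulated
100-participant, two-session cohort and write their tables under
`results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_score_metrics.py
python analysis/03_cross_sectional_stats.py
python analysis/04_longitudinal_decline.py
python analysis/05_hv_regression.py
python analysis/06_classification.py
```

`02_score_metrics.py` prints the group means of the cumulative metrics —
the designed severity ordering is visible in every column:

```
       identification_accuracy  abs_localization_error  ...  guessing  imprecision
group
AD                       0.729                   0.223  ...     0.133        0.091
EHC                      0.942                   0.116  ...     0.061        0.062
MCI                      0.834                   0.188  ...     0.114        0.084
SCD                      0.918                   0.118  ...     0.059        0.056
```

`03_cross_sectional_stats.py` reports, per metric, the covariate-adjusted
group effect (e.g. `identification_accuracy F=38.88 p=2.2e-16 eta2=0.556`)
and the set-size/delay effect classes. `04_longitudinal_decline.py` shows
that the planted AD-only decline is picked up as a Group × Session
interaction (absolute localization error: interaction p=1.6e-09, AD
session contrast p=1.0e-05, other groups n.s.) and that every baseline
metric predicts the one-year ACE change (R² 0.24–0.45).
`06_classification.py` compares the two feature sets: on this cohort the
four-class accuracy is 0.57 for the eight task metrics vs 0.46 for ACE,
with pairwise AUCs of 0.63/0.80/0.99 (EHC–SCD / SCD–MCI / MCI–AD) for the
task metrics.

The same stages are scriptable through the `omt` CLI
(`omt simulate | mixture | stats | classify | run`) or in one call via
`omt.pipeline.run_pipeline(RunConfig(...))`.

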