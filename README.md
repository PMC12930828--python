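# bnorms

Baseline-conditioned normative models for longitudinal cortical
thickness.

Normative models ("brain charts") regress a biological measure on
reference covariates — age, sex, scan site — and use the predictive
distribution to place an individual on a centile, exactly like a
pediatric growth chart. Almost all published brain charts are
cross-sectional: they can say whether a child's cortex is thick or thin
*for their age*, but not whether it changed in an unusual way *given
where it started*. This package implements both kinds of norms for
region-wise cortical thickness in a multi-site adolescent cohort and the
statistics needed to compare them:

* **C-Norm** (cross-sectional): `CT ~ age + site`.
* **B-Norm** (baseline-conditioned): `CT_follow-up ~ CT_baseline +
  age_baseline + age_follow-up + site`, trained on (baseline, 2-year)
  pairs and applied at the 2-year and 4-year follow-ups.

Both are warped Bayesian linear regressions: a Gaussian BLR with prior
`w ~ N(0, α⁻¹I)` and noise precision `β` fitted to the sinh-arcsinh
warp `g(y; a, b) = sinh(b·asinh(y) − a)` of the standardized response,
with the four hyperparameters `(α, β, a, b)` set by type-II maximum
likelihood (Powell's method on the warped evidence). Deviation scores
`z = (g(y) − x·m)/s` and centiles follow from the warped predictive
Gaussian. Around the engine sit the stages a real analysis needs: a
synthetic multi-site cohort generator with known ground truth, the
participant exclusion cascade and 6-SD quality screens, per-region fit
metrics with a model×timepoint repeated-measures ANOVA, and three
validations linking deviation scores to pubertal development
(region-wise PDS associations with Benjamini–Hochberg correction,
Kruskal–Wallis tests of extreme-deviation counts across pubertal stages
with Dunn post-hocs, and percentile-shift grouping between follow-ups).

Intended users: researchers building or evaluating longitudinal
normative models on tabulated ROI data, and anyone needing a fully
synthetic, ground-truthed test bed for such pipelines.

## Worked example

```python
from bnorms import (Config, SimParams, simulate_cohort, split_train_test,
                    fit_norms, score_norms, metrics_table)

cfg = Config()
params = SimParams(n_subjects=600, n_rois=12, n_sites=3, y4_missing_frac=0.6)
table, truth = simulate_cohort(params, seed=1)
train, test = split_train_test(table)

norms_b = fit_norms(train, "bnorm", "F", cfg)
norms_c = fit_norms(train, "cnorm", "F", cfg)
dev_b = score_norms(norms_b, test, "y2", cfg)

print(metrics_table(dev_b, norms_b)[["roi_name", "ev", "smse"]].head(3))
print(norms_b.models[train.roi_names[0]].summary())
```

On this cohort (within-subject tracking ICC 0.8) the run prints B-Norm
explained variance around 0.65 per region versus roughly 0.03 for the
C-Norms — the baseline-conditioned model absorbs the stable
between-subject differences that a cross-sectional chart must treat as
unexplained spread. Each fitted region's `summary()` reports the
optimized hyperparameters (`alpha`, `beta`, warp skew `a`, warp shape
`b`) and the posterior mean and SD of every design coefficient.

The same pipeline is scriptable from the shell:

```sh
bnorms simulate --seed 1 --n-subjects 600 --n-rois 12 \
    --out cohort.csv --atlas atlas.csv
bnorms qc --in cohort.csv --out-train train.csv --out-test test.csv
bnorms fit --train train.csv --kind bnorm --sex F --out models/
bnorms score --models models/ --test test.csv --timepoint y2 --out dev_y2.csv
bnorms evaluate --dev dev_y2.csv --models models/ --out test_metrics.csv
bnorms validate --dev dev_y2.csv --cohort test.csv --atlas atlas.csv \
    --out-dir validation/
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full analysis from scratch at desk scale: it simulates a
600-subject, 12-region, 3-site cohort with a puberty-coupled region
subset, runs the exclusion cascade and both 6-SD screens, fits C-Norm
and B-Norm sets per sex, scores both follow-ups, computes fit metrics,
the model×timepoint repeated-measures ANOVA, the PDS associations with
FDR correction, the stage-wise Kruskal–Wallis omnibus tests and the
percentile-shift analysis, printing the headline quantities as it goes
and writing the JSON report to `--out`.

## Layout

```
src/bnorms/
  blr.py         warped Bayesian linear regression (model + results)
  shash.py       sinh-arcsinh warp, inverse, log-Jacobian
  norms.py       per-region C-/B-Norm sets: designs, fitting, scoring
  simulate.py    synthetic longitudinal cohorts with ground truth
  qc.py          exclusion cascade, 6-SD screens, train/test split
  evaluation.py  fit metrics, repeated-measures ANOVA
  puberty.py     PDS associations, stage subgroup tests, percentile shifts
  data.py        tabular data model and CSV I/O
  config.py      thresholds and switches (TOML-loadable)
  cli.py         `bnorms` command-line interface
```

See `docs/methods.md` for the model, its assumptions, and the design
choices behind the synthetic cohort.
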