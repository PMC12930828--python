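# Methods

## The warped BLR normative engine

Each region × sex × model kind is an independent Bayesian linear
regression fitted to a warped, standardized response. With training
response `y` (thickness, mm), standardization `ỹ = (y − m_y)/s_y` by
training mean/SD, and the two-parameter sinh-arcsinh warp

    g(ỹ; a, b) = sinh(b · asinh(ỹ) − a),    b > 0,

the model is `g(ỹ) = x·w + ε`, `ε ~ N(0, β⁻¹)`, `w ~ N(0, α⁻¹I)`.
`a` controls residual skew, `b` tail weight; (0, 1) is the identity, in
which case the engine reduces exactly to Bayesian ridge regression
(posterior `m = βA⁻¹Xᵀỹ`, `Σ = A⁻¹`, `A = αI + βXᵀX`) — a reduction the
test suite checks to 1e-8 against the ridge closed form.

Hyperparameters are set by type-II maximum likelihood. The objective is
the negative log marginal likelihood of the Gaussian BLR on the warped
response plus the warp's log-Jacobian `Σ log g′(ỹᵢ)`, minimized over
`(log α, log β, a, log b)` with Powell's method (start `α = 1`,
`β = 1/var(g(ỹ))`, `a = 0`, `log b = 0`; xtol = ftol = 1e-6, at most
500 iterations). Positivity of `α, β, b` is enforced by the log
parameterization; non-finite objective values and log-parameters beyond
±50 (or |a| > 10) return a 1e10 penalty so the direction-set search
stays in a numerically sane region. The evidence is validated against
brute-force numerical quadrature on one-weight toys to 1e-6.

Prediction at a new row `x*` is Gaussian in warped space:
`μ_w = x*·m`, `s_w² = x*ᵀΣx* + 1/β`. From it:

* deviation score `z = (g(ỹ*) − μ_w)/s_w`;
* centile of an observation `100·Φ(z)`;
* median prediction in mm `m_y + s_y · g⁻¹(μ_w)`;
* centile curves `m_y + s_y · g⁻¹(μ_w + s_w·Φ⁻¹(q))` for the
  configured quantile set (default 1, 5, 25, 50, 75, 95, 99%);
* predictive log-density in mm units, including both the warp and the
  standardization Jacobians (used by MSLL and BIC).

Design conventions: continuous covariates (ages, baseline thickness)
are standardized by training statistics; scan sites are one-hot columns
left untouched, acting jointly as per-site intercepts, so no separate
intercept column is added. A site unseen at training is an error by
default; `site_fallback = "reference"` maps it to the all-zero vector
with a warning. Ages enter linearly by default (`age_degree` exposes a
polynomial expansion). A degenerate no-signal region can legitimately
drive `α` to the bound (all-zero weights, constant predictions equal to
the training mean); metrics then report Pearson r as missing.

### Model kinds

* `cnorm` — response: thickness at a visit; design `[age, site]`;
  trained on baseline rows; at scoring the age covariate is the age at
  the scored follow-up.
* `cnorm_2year`, `cnorm_bl2year` — age-range controls trained on 2-year
  rows or on stacked baseline + 2-year rows.
* `bnorm` — response: follow-up thickness; design
  `[ct_baseline (same region), age_baseline, age_follow-up, site]`;
  trained on (baseline, 2-year) pairs; the 4-year follow-up is scored
  with the same weights and the 4-year age.

B-Norms condition only on the *same region's* baseline value, matching
the per-region model definition; cross-region multivariate norms are
out of scope. Because the baseline measurement is itself noisy, the
population slope on it is the tracking ICC `τ²/(τ² + σ²)` rather than
1, and the B-Norm residual variance is `σ²(1 + ICC)` — both facts are
used when calibrating simulated effect sizes and explain why a subject
with a constant offset is not *exactly* invisible to the B-Norm.

## Quality control and splitting

Participant-level exclusions run in a fixed order, each stage logged
with before/after counts: (1) subjects with a single visit; (2) any
BMI strictly below 10 or above 50 kg/m² (boundaries retained);
(3) missing PDS or any regional thickness at a retained visit. After
splitting by visit availability ({baseline, 2-year} → train; all three
visits → test; other patterns dropped with a warning), each split is
screened twice with a single-pass k = 6 sample-SD rule (ddof = 1,
candidate included, no re-screening): Euler numbers grouped by
scan-site, then thickness grouped by region and visit. A flagged visit
removes the participant wholesale. A single outlier can never trip the
screen in groups of 20 or fewer, since the studentized extreme is
bounded by `(n−1)/√n < 6`; the tests verify both this bound and exact
removal of planted outliers. `one_per_family` subsamples one subject
per family uniformly (seeded) where family structure is present.

## Fit metrics and model comparison

Per region × sex × kind × follow-up: Pearson r between observed and
median-predicted thickness; RMSE; SMSE (MSE over test variance, so the
mean predictor scores 1); EV `= 1 − var(resid)/var(obs)`; MSLL (mean
negative predictive log-density minus that of a Gaussian with the
*training* mean and variance — negative means the model beats the
trivial predictor); sample skewness and excess kurtosis of z; and BIC
with parameter count = design columns + 3 warp/noise hyperparameters (a
documented convention). Model comparison is a 2×2 repeated-measures
ANOVA (factors MODEL and TIMEPOINT, regions as the repeated-measures
identifier, via pingouin), reporting F with df (1, n_regions − 1) and
partial eta-squared `F·df₁/(F·df₁ + df₂)`; with two-level factors no
sphericity correction is needed, and each F equals the square of the
matching paired-t (checked to 1e-8). When a metric is identical in all
cells the 0/0 ratio is reported as F = 0, p = 1.

## Puberty validations

1. **Association**: per region, a Gaussian identity-link GLM (ordinary
   least squares, via statsmodels) of the caregiver mean PDS at a
   follow-up on the deviation score there; variants add a full
   factorial BMI × SES covariate block or replace the predictor with
   the raw thickness change from baseline. Wald z statistics;
   Benjamini–Hochberg across the regional tests within each
   (model kind, sex, timepoint) family — the family definition is
   config-exposed since other groupings are defensible. Cells with
   fewer than 10 subjects are flagged, not fitted.
2. **Stage subgroups**: pubertal stage (pre/early/mid/late/post) is
   assigned from the mean PDS by a documented threshold rule
   (< 1.5, < 2.25, < 3, < 3.75, else post) — a stand-in for
   questionnaire-item staging schemes, replaceable via
   `Config.stage_thresholds`. Extreme deviations (|z| strictly greater
   than 1.96) are counted per subject and lobe-hemisphere (six lobes ×
   two hemispheres), and Kruskal–Wallis (tie-corrected, scipy) compares
   counts across stages per (lobe-hemisphere, sign, model, timepoint)
   cell — 192 cells over both sexes in the full design. Empty stages
   shrink the df; BH runs across cells within a sex; Dunn's
   tie-corrected large-sample z tests with Bonferroni (over the pairs
   present in the cell) follow up significant cells.
3. **Percentile shifts**: per region, subjects split by
   `zDiff = z(4yr) − z(2yr)` into negative (< −1), positive (> 1) and
   stable (closed interval — boundary values are stable, since strict
   inequalities define the outer groups); Kruskal–Wallis on the change
   in PDS across the non-empty groups, BH across regions.

## The synthetic cohort

The generator emulates the structure the pipeline consumes, not raw
imaging: baseline age ~ truncated Normal(119, 7.4²) months on
(96, 144); follow-ups at ~24 ± 2 month gaps; a configurable fraction of
subjects lacking the 4-year visit (these become the training split);
sites uniform with Normal(0, 0.03 mm) constant offsets; per-region mean
thickness uniform on 2.0–3.5 mm with thinning −0.002 mm/month;
subject-by-region random intercepts (τ = 0.12 mm) over sinh-arcsinh
residuals (σ = 0.06 mm, identity warp by default). τ and σ are chosen
so the within-subject tracking ICC is 0.8, which puts B-Norm explained
variance near 0.64 and C-Norm near 0.03 on held-out data — the regime
reported for real adolescent cohorts. PDS follows sex-specific logistic
curves in age (midpoints 145 months for girls, 160 for boys, slope
0.06/month) plus a persistent per-subject "tempo" deviation
(SD 0.4), clipped to [1, 4]; item ratings are rounded perturbed copies
of the mean, with the menarche item binary. Puberty coupling, when
enabled, thins a designated region subset at follow-up visits by
κ × tempo-excess, so the signal lives in change between visits rather
than in baseline level; `kappa_for_f2` converts a target Cohen f² for
the PDS~z association into κ analytically, accounting for the B-Norm's
`σ²(1 + ICC)` effective residual variance and the age-driven PDS
spread. Scale defaults (800 subjects, 20 regions, 5 sites, 47% female)
are desk-scale stand-ins for a cohort two orders of magnitude larger;
the default 4-year-missing fraction of 0.5 keeps both splits usable at
these sizes.

What the generator does **not** emulate: raw MRI or surface
reconstruction failure modes beyond scalar Euler outliers, sibling/twin
correlations (family IDs default to singletons), site-by-age
interactions, spatially correlated region noise, and item-level PDS
psychometrics. A green test therefore establishes that the statistical
machinery is correct and calibrated on data with known truth — not that
any particular anatomical finding in a real cohort would replicate.

## Numerical choices and limitations

* Single seeded generator per simulation; identical seeds give
  byte-identical cohorts.
* Warp/inverse round-trip to 1e-10 over the tested parameter grids;
  log cosh is computed overflow-safely.
* Exact threshold equality is never "extreme" (|z| = 1.96 not counted;
  |zDiff| = 1 is stable; BMI exactly 10 or 50 retained).
* Kruskal–Wallis on identical values is reported as H = 0, p = 1
  rather than an error.
* The Powell search is local; with strongly mis-specified warps it can
  converge to a local optimum. Convergence flags are stored per model
  and failures per region are recorded, not fatal.
* The 4-year B-Norm scores reuse weights trained on 2-year pairs; any
  true change in the conditional relation between 2 and 4 years appears
  as miscalibration at the 4-year follow-up, which is visible in the
  skew/kurtosis metrics rather than silently absorbed.
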