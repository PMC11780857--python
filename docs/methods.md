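# Methods

## Task model and coordinate system

A session of the "What was where?" task is modelled as a schedule of
trials in a normalised screen space: locations are fractions of the screen
in [0, 1]², origin top-left. The physical stimulus size (≈2.3° of visual
angle on a tablet) is not modelled; all geometry is device-independent.
Items are placed by rejection sampling inside an edge margin of 0.10 with
a minimum pairwise separation of 0.15 screen fractions (10,000 attempts
per trial before an error). The original task placed items "pseudorandomly"
without published constants; these two values keep three items visibly
non-overlapping on any screen. The stimulus library is the full 49 × 4
(shape, colour) grid of 196 fractals; the foil is drawn uniformly from the
library minus the trial's items, and stimulus reuse across trials is
allowed (196 stimuli cannot cover 280 item slots without reuse). A default
session is 8 practice trials plus 3 blocks × 4 conditions × 10 trials =
120 test trials, each block a fresh random permutation of its 40 trials.

## Generative response model

Behaviour on a trial is simulated in two stages:

1. **Identification** — Bernoulli with a condition-specific probability
   `p_identify[(set size, delay)]`. Failed identifications place the foil
   uniformly in the placement region and carry no component label.
2. **Localization** (given correct identification) — a three-component
   mixture: with probability `p_target` the response is the target
   location plus isotropic Gaussian noise of SD σ (truncated to the screen
   by resampling); with `p_misbind` it is a uniformly chosen non-probed
   in-trial item plus the same noise; with `p_guess` it is uniform over
   the placement region. At set size 1 misbinding is impossible and its
   mass is reallocated proportionally to the other two components.

Response times are lognormal; no published distributional detail exists
for this task, and the lognormal is our choice (documented, not fitted).

Group presets (EHC, SCD, MCI, AD) order every parameter by designed
disease severity — target detection and identification fall, misbinding,
guessing and σ rise, response times lengthen. They are synthesis settings
chosen to give group separations of the size a clinical cohort shows (the
pairwise classifier AUCs they induce sit in the 0.6–0.99 range), not
estimates from any real dataset.

### Latent severity and covariates

Each participant draws a latent severity `z ~ N(μ_group, 1)` with group
means 0 / 0.6 / 1.6 / 3.2. The within-group deviation of `z` perturbs the
individual's task parameters (Gaussian shifts on the logit scale for the
mixture weights and identification, lognormal multiplier on σ), and the
full `z` generates ACE = 93 − 6·z (SD 3, clipped to [0, 100]) and
bilateral head-size-corrected hippocampal volume HV = 8000 − 450·z mm³
(SD 500, floored at 3000). Because the same severity drives behaviour, ACE
and HV, the designed metric–ACE and metric–HV correlations exist at both
the between- and within-group level, which is what the covariate-adjusted
regressions need to detect. Demographics differ by group (SCD youngest;
age means 64–73, SD 7) so that covariate adjustment is genuinely
exercised.

### Two-session drift

Session 2 re-runs the participant on a fresh schedule with parameters
shifted by the group's `SessionDrift`. Only the AD preset drifts by
default: σ +0.05, p_target −0.04 (mass reallocated), p_identify −0.03,
plus an ACE decline of 0.5 + 1.2·z points (SD 2). The drift magnitude is a
designed power target: it is sized so that a two-session study of 15
participants per group detects the AD-only decline through the full
estimator chain (mixed-model interaction plus Holm-corrected per-group
session contrast) with high probability — gentler drifts are swallowed by
the trial-sampling noise of a 120-trial session. One divergence from
observed cohorts is noted: empirically the relative mixture weights appear
stable over a year while precision degrades; the small p_target drift here
exists to make the planted effect unambiguous, not as a claim about
patients.

## Metrics

Identification accuracy uses all trials of a condition; localization error
and both response times use correctly identified trials only (the task
defines the times for the correct object; the same convention is applied
to localization error for coherence, and this is a documented assumption —
whether the original analysis included wrong-identification trials in the
error is unstated). Aggregation over trials uses means, and the cumulative
value of every metric is the unweighted mean of its four condition values
even when exclusions unbalance the condition counts.

## Permutation mixture decomposition

For each correctly identified trial the distances from the response to
(1) the target, (2) the nearest non-probed in-trial item (set size 3 has
two; the minimum implements "the remembered location of another item"),
and (3) one location drawn uniformly from the pool of all item locations
of all *other* trials of the session are compared; the smallest wins, with
the fixed tie-break priority target ≻ in-trial distractor ≻ pool draw
(ties have probability zero for continuous responses; the priority only
pins determinism). The draw is repeated 5000 times per trial with
replacement, and class counts / 5000 give the per-trial proportions. The
guess proportion is computed as the residual `1 − (target + misbind)` so
the three floats sum to exactly 1.

`exact_attribution` enumerates every pool element once and returns the
exact expectation of the sampler (the only randomness is the pool draw);
it is both the test oracle and a faster deterministic drop-in used by the
heavier simulation studies.

Cumulative mixture metrics follow the same condition-mean rule as the
basic metrics, with misbinding averaged over the two 3-item conditions
only (it does not exist at set size 1). Consequently the three cumulative
proportions need not sum exactly to one — normalization holds at the trial
and condition level, where it is enforced.

**Known estimator biases, tolerated by design.** Nearest-location
attribution misclassifies overlapping components: at realistic parameter
values misbinding and guessing are overestimated and target detection
underestimated, and the imprecision statistic (target-weighted SD of
radial error) saturates once guessing is common, because distant guesses
retain moderate target weight. The verification suite therefore asserts
monotonicity and ordering — estimated quantities increase with their
generative counterparts across the preset grid — never unbiasedness. This
is also why the longitudinal planted-effect analysis reads the σ drift out
through absolute localization error rather than through estimated
imprecision.

## Statistics

* **Cross-sectional ANCOVA**: `metric ~ group + age + gender + education`
  (gender as a binary indicator), omnibus type-II F for group, partial η²
  (SS_group / (SS_group + SS_resid)); pairwise contrasts are
  covariate-adjusted t tests from the full model with step-down Holm
  adjustment (via statsmodels `multipletests`), plus Cohen's d on the raw
  (covariate-unadjusted) group values with pooled SD — whether the
  original effect sizes were adjusted is unstated, so the simpler raw-scale
  d is used and documented.
* **2×2 factorial**: two-way repeated-measures ANOVA (pingouin) on the
  per-condition values, partial η² with the magnitude classes >0.01 small,
  >0.06 medium, >0.14 large. Misbinding enters a delay-only one-way RM
  ANOVA since it has no set-size-1 cells.
* **Longitudinal**: linear mixed model
  `metric ~ group × session + covariates` with a random intercept per
  participant (ML), Wald tests for the Group, Session and interaction
  terms; post hoc per-group paired t tests across sessions, Holm-adjusted
  across the four groups. Participants missing a session are dropped with
  a logged warning.
* **Decline**: OLS of ΔACE = ACE(t1) − ACE(t0) on each baseline metric
  separately (t, p, R²).
* **Dependent overlapping correlations**: Fisher-z statistic for
  H₀: ρ_jk = ρ_jh sharing variable j, with the covariance term
  c = [r_kh(1−2r̄²) − ½r̄²(1−2r̄²−r_kh²)] / (1−r̄²)² and
  z = (z_jk − z_jh)·√((n−3)/(2−2c)). The default "h-test" uses the
  backtransformed average of the two Fisher z's for r̄ (Hittner–May–Silver
  modification); Steiger's plain average is selectable for sensitivity.
* **HV regression**: OLS `HV ~ metric + covariates`; the metric's t and p
  are its contribution, R² is the overall model fit.

Degenerate inputs fail loudly: rank-deficient designs name the collinear
columns, single-session data cannot enter the longitudinal model, and
participants with no correct trials propagate missing metrics (dropped
listwise per analysis).

## Classification

Linear SVM (C = 1.0, class weights balanced — the strata are unbalanced by
design), features standardized *inside each training fold only*, stratified
5-fold cross-validation with a fixed seed. The two competing feature sets
are the eight task metrics + age/gender/education versus ACE +
age/gender/education. Per-class ROC AUCs come from one-vs-rest out-of-fold
decision scores; the same held-out scores feed DeLong's test (placement-
value variance and covariance; paired, since both models score identical
cases). The original study's cross-validation scheme is unpublished;
stratified 5-fold is this package's choice.

## Verification design and problem sizes

All verification runs on synthetic data with known truth; what passing
shows is that the estimators and tests behave correctly *under the
generative model* — Gaussian noise, lognormal times, linear severity
links. Real data bring contaminants the generator does not emulate
(attention lapses, response biases toward the screen centre, device
differences, practice effects beyond a linear drift), so the suite
validates the machinery, not clinical performance.

Problem sizes were chosen to put each check's Monte-Carlo error well below
its decision margin while keeping the suite fast: the attribution oracle
uses 200 random geometries at 5000 repetitions (3-SE binomial bound);
parameter recovery uses 20 replicate seeds × 3 preset grid points × 8
simulants of 120 trials (8 per point puts adjacent grid points ≈3 SEs
apart for the noisiest quantity); type-I calibrations use 1000–2000 null
replicates (rate band 0.035–0.065 at α = 0.05); planted-effect detection
uses 20 seeds at 15 participants/group × 2 sessions; classifier checks use
20 seeds at 50/group. The demonstration cohort in `analysis/` is 25
participants per group × 2 sessions.

## Limitations

* The permutation decomposition is a classifier, not a likelihood fit; its
  proportions are biased toward guessing/misbinding and its imprecision
  statistic saturates at high guess rates (see above). A von-Mises-style
  likelihood mixture is deliberately out of scope.
* Whether the comparison pool should exclude the current trial's foil, and
  whether pool draws were with or without replacement in the original
  procedure, is unpublished; this implementation pools all other-trial item
  locations and draws with replacement.
* Probe order/position at test is recorded nowhere and not modelled.
* The simulator draws no diagnostic conversions, plasma biomarkers, or
  nonlinear practice effects; hippocampal volume is generated directly
  from latent severity rather than from images.
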