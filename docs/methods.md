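# Methods

## Scope and design

The package implements a decision-support pipeline for clinical gait
analysis: per-surgery treatment-recommendation (propensity) models,
Shapley explanations, a concordance statistic, outcome-change models
with prediction intervals, and counterfactual policy simulation.  All
stages are exercised end-to-end on synthetic cohorts whose generative
truth is retained, because real clinical gait databases cannot be
redistributed.  The code is organised statsmodels-style: `PropensityModel`
and `OutcomeModel` are built from a cohort table and `fit()` returns a
results object carrying predictions, uncertainties and diagnostics.

## Synthetic cohort generator

One row is one limb-visit.  Patients contribute two limbs; a shared
patient-level latent severity (intra-patient correlation 0.5 by default)
induces bilateral correlation in severity-loaded features.  The default
cohort descriptors are those of a large single-center CGA service:
age 8.9 (sd 3.3) years, 42% female, 84% in one dominant diagnosis group
among 10 categories, and 12 surgery indicators with prevalence targets
from 3% to 25%.

Features are drawn as `mean + loading·severity + noise` on their
clinical scales (GDI ≈ 100 is typical gait; ordinal 0–4 spasticity;
degrees for torsions and ranges of motion).  Units and defaults live in
`cohort.FEATURE_DEFS`.

**Treatment assignment.** Each surgery has a latent policy: a logistic
model on centered features, optionally with quadratic or hinge terms
(e.g. the derotation-osteotomy policy is U-shaped in tibial torsion with
its minimum at the typical 15°; the rectus-transfer policy declines with
calendar era).  Clinician inconsistency is additive N(0, sd) noise on
the logit before the Bernoulli draw; the default sd of 1.0 logit unit
was chosen so that default-condition propensity fits reach balanced
accuracies in the mid-0.7s — the regime reported for real centers, where
historical decision consistency caps achievable model accuracy.  Policy
intercepts are calibrated by bisection so the mean *noisy* assignment
probability equals the prevalence target; the stored truth is the
noise-free probability, which doubles as the limb's indication strength.
A `threshold` assignment mode replaces the Bernoulli draw with its
degenerate limit (treat iff p > 0.5) for testing.

**Outcomes.** Ten change ("delta") outcomes span body structure (e.g.
ankle dorsiflexion ROM), kinematics (GDI) and activity (FAQt).  Each is
`regression-to-mean + Σ treated·effect + N(0, noise_sd)`, where the
per-limb effect interpolates between `effect_if_contraindicated` and
`effect_if_indicated` by indication strength — so well-indicated surgery
helps most, by construction, and concordance-versus-outcome trends
emerge without circular reference to any fitted model.  All deltas are
oriented so positive = improvement, which keeps the indicated effect
the larger one for measures surgery decreases.  Downstream outcomes
(FAQt) get attenuated effects and larger noise than structural ones.
Noise scales are set so well-specified models produce 90% interval
widths of roughly 16–45 units, the range reported for real gait
outcomes.  Both potential outcomes (natural history and each single
treatment's effect) are materialised per limb, making policy arms
counterfactually exact.

**Missingness.** Completely-at-random and severity-dependent masking
(severely involved limbs lose exam measurements preferentially, via a
logistic in latent severity calibrated to the marginal rate).  Treatment
and delta columns are never masked.

## Posterior backend

A single contract for models that emit posterior draws.  The default
engine is a resampling ensemble of gradient-boosted trees: 15 members,
each fit on an 85% subsample without replacement (m-out-of-n bootstrap),
with 1000 draws per limb produced by cycling members.  For regression,
draws add a fixed standardised N(0,1) sample scaled by sigma, where
sigma² = out-of-bag residual variance − mean member variance; member
spread then carries resampling (model) uncertainty while total
predictive spread matches out-of-bag error, which is what makes nominal
interval coverage land near its level.  Because the same noise sample is
reused across rows, paired differencing of counterfactual draws cancels
observation noise and effect intervals reflect model uncertainty only.
Probability draws are clipped to [1e−6, 1−1e−6].

Missing data use indicator augmentation: any feature with missing values
gains a binary `__missing` companion and is median/mode-filled; rows are
never dropped.  The indicator travels with its parent as one column
group, so explanations attribute it to the parent feature.

A faithful Bayesian additive regression trees sampler is out of scope;
the `bart-adapter` backend key is reserved for binding such a library
under the same contract and raises an informative error here.  All
calibration and acceptance checks are formula- or coverage-based, not
engine-based, so the contract — not the engine — is what downstream code
depends on.

## Propensity models

70/30 split is grouped by patient (both limbs land on one side) to
prevent within-patient leakage; the test side keeps its natural
imbalance.  Undersampling keeps every treated limb plus an equal-size
uniform subset of untreated limbs; one subsample per fit.  The
recommendation threshold is strictly greater than 0.5; quintile display
categories are left-open right-closed bins (0,0.2], …, (0.8,1.0] with
p = 0 in category 1.  AUC uses posterior-mean probabilities (midrank tie
handling).  Note that probabilities from balanced training are on the
balanced scale (base rate ≈ 0.5), as in the underlying practice.

## Shapley explanations

Interventional Shapley values on the probability scale against a fixed
background — by default the model's balanced training subsample, capped
at 200 seeded rows, whose mean prediction is the base value S̄.  The
coalition value v(S) replaces S-features of every background row with
the limb's values and averages the prediction.  Up to 12 features all
2^k coalitions are enumerated and efficiency (base + Σ contributions =
prediction) holds to machine precision; beyond that, a permutation
estimator reports Monte-Carlo standard errors (its telescoping sum keeps
efficiency exact as well).  Display buckets: |S_f| ≥ 0.05 strong,
0.01–0.05 weak, else neutral.  Features derived from instrumented gait
(vs physical exam) are flagged from a fixed registry.  A known
limitation: when two training columns are perfectly collinear, boosted
trees route all splits through one of them, so the fitted model — and
hence the attribution — is not symmetric between duplicates; the
symmetry axiom is guaranteed for symmetric value functions, not for
arbitrary fitted engines.

## Concordance

ρ\* = 2(p − 0.5); ρ\*\* = sign(ρ\*)·(ρ\*)² (the signed square, which
amplifies extremes and compresses moderate probabilities; the two
readings of the printed transformation are algebraically identical);
κ = ρ\*\* if treated else 0; K = Σκ over the configured surgeries.  p is
the posterior-mean probability.  Trends use statsmodels' lowess (tricube
weights, local degree 1), span 0.7, evaluated on an even grid, plus
quantile-binned means (5 bins) as a smoother-free summary.

## Outcome models and policy simulation

Outcome models fit the full unbalanced training split (undersampling is
a propensity-side device).  The untreated counterfactual zeroes all 12
indicators (natural history); `control="complement_zero"` leaves
non-index surgeries at recorded values and is what the policy simulator
uses, since its decision concerns one index surgery.  Multi-level
effects are approximated by summing single-level effect draws at
matched draw indices; the joint counterfactual and the discrepancy are
returned so the small-interactions assumption is checkable.  Intervals
are equal-tailed posterior quantiles throughout.

Policy arms use posterior means with strict thresholds (defaults:
probability 0.5, GDI change +7.5).  Realised outcomes per arm come from
the generator's potential outcomes; on data without counterfactual
truth the simulator refuses cross-policy outcome comparisons rather
than silently substituting model predictions.

## Problem sizes and numerical choices

Test and acceptance experiments use cohorts of 800–4,000 limbs
(3,000 for calibration and policy runs, 10 generator seeds for the
policy-direction experiment, 100 limbs for the efficiency-at-scale
check), sizes at which the checked quantities are stable under the
stated tolerances.  All randomness flows from explicit integer seeds
through `numpy.random.SeedSequence` child streams, so every stage is
independently bit-reproducible.  Intercept calibration bisects on
[−30, 30] for 100 iterations; probability clipping keeps logits finite;
lowess uses one robustifying iteration.

## Known limitations

- Counterfactual effect estimates are attenuated where treated and
  untreated limbs barely overlap (the extreme-probability region); the
  policy simulator therefore treats fewer limbs under effect-thresholded
  arms than an oracle would, though the qualitative ordering of arms is
  unaffected.  This mirrors the fundamental overlap problem of
  observational treatment-effect estimation, not an implementation
  defect.
- The generator emulates marginal structure and one latent severity
  axis; it does not simulate raw kinematic trajectories, multi-way
  feature interactions beyond the policy nonlinearities, era-varying
  case mix, or informative follow-up timing.  Passing recovery tests
  shows the pipeline recovers the structure the generator encodes — not
  that real-data performance would match.
- Effect intervals exclude observation noise by construction (paired
  draws); they are model-uncertainty intervals, narrower than
  prediction intervals for observed change.
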