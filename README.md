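# ebgait

Decision-support modelling for clinical gait analysis (CGA): propensity
models that estimate a center's historical standard of practice (SOP)
for twelve common orthopedic and neurosurgical procedures, Shapley-value
explanations of individual recommendations, a concordance statistic
linking administered surgery to the modeled SOP, outcome-change models
with calibrated prediction intervals, and counterfactual simulation of
treatment-policy rules.  The package is aimed at biostatisticians and
bioengineers studying how data-driven second opinions could change who
gets surgery and what outcomes result.

Because clinical gait databases are not publicly shareable, the package
ships a synthetic-cohort generator with known generative truth.  The
generator reproduces the statistical structure such an analysis assumes
(cohort demographics, imbalanced surgery prevalences from 3% to 25%, a
partly nonlinear latent treatment policy blurred by clinician-to-
clinician noise, and outcome changes whose treatment benefit scales with
how strongly the limb was indicated), so every modelling stage can be
tested against ground truth.

## The models

**Treatment recommendation (propensity).** For each surgery,
π<sub>treat</sub> = P<sub>treat</sub>(f₁, …, f_k) is the probability
that a limb receives the surgery under the historical SOP.  Training
uses a 70/30 patient-level split and undersampling of untreated limbs to
a balanced subsample; evaluation uses the naturally imbalanced test set
at a 0.5 mean-probability threshold, reporting sensitivity, specificity,
balanced accuracy = (sens + spec)/2, and AUC.  The fitted model is a
pseudo-posterior: a resampling ensemble of gradient-boosted trees whose
member spread provides equal-tailed probability intervals.

**Explanation.** Shapley values decompose an individual prediction
against the training base rate, π<sub>limb</sub> = S̄ + Σ_f S_f, with
exact coalition enumeration up to 12 features (a permutation estimator
with standard errors beyond that).  Positive S_f are indications,
negative are counter-indications.  Partial-dependence curves summarise
marginal feature effects model-wide.

**Concordance.** For probability p of an administered surgery,
ρ\* = 2(p − 0.5), ρ\*\* = sign(ρ\*)·(ρ\*)², and κ = ρ\*\* if the surgery
was performed, 0 otherwise; the overall K = Σκ over the twelve
surgeries.  A tricube-weighted local-linear trend (span 0.7) and binned
means relate κ or K to observed outcome changes.

**Outcomes.** ΔY = O(f₁, …, f_k, treat₁, …, treat₁₂) predicts the
follow-up change in a clinical measure from baseline features and the
twelve binary treatment indicators.  Counterfactual treatment effects
difference paired posterior draws between a treated prediction and the
all-treatments-off natural-history prediction, with 50% and 90%
equal-tailed intervals; calibration reports bias, MAE, interval width
and empirical coverage.

**Policy simulation.** Four implementation arms — current practice,
propensity-only (p > 0.5), outcome-only (predicted ΔGDI > +7.5), and the
combined conjunction — are scored on the generator's counterfactual
potential outcomes, so arms are compared on what would actually have
happened rather than on model predictions.

## Worked example

```python
import numpy as np
import ebgait
from ebgait import propensity as pm, outcomes as om
from ebgait.explain import shapley_values, indication_table

table, truth = ebgait.generate_cohort(ebgait.GeneratorConfig(n_limbs=3000, seed=7))
train, test = pm.split_train_test(table, train_frac=0.7, seed=7)

fdo = "femoral_derotation_osteotomy"
fit = pm.PropensityModel(train, fdo).fit(seed=7)
m = fit.evaluate(test)
print(f"balanced accuracy {m.balanced_accuracy:.2f}  AUC {m.auc:.2f}  "
      f"prevalence {m.prevalence:.2f}")

gdi = om.OutcomeModel(train, "delta_gdi").fit(seed=7)
rep = gdi.calibrate(test)
print(f"bias {rep.bias:+.1f}  MAE {rep.mae:.1f}  "
      f"90% PI width {rep.width_90:.1f}  90% PI coverage {rep.coverage_90:.0%}")

p = fit.predict_mean(test)
eff = gdi.estimate_treatment_effect(test, (fdo,), control="complement_zero")
best = int(np.argmax(np.where(p > 0.5, eff.effect_draws.mean(axis=1), -np.inf)))
limb = test.iloc[[best]]
profile = shapley_values(fit, limb, seed=7)
print(f"P(derotation) = {profile.prediction:.2f} (base rate {profile.base_value:.2f})")
print(indication_table(profile).head(4).to_string(index=False))
print(gdi.estimate_treatment_effect(limb, (fdo,)).summary_frame().round(1))
```

prints

```
balanced accuracy 0.74  AUC 0.82  prevalence 0.26
bias -0.1  MAE 6.3  90% PI width 26.5  90% PI coverage 89%
P(derotation) = 1.00 (base rate 0.56)
            feature     value  shapley  direction strength source
femoral_anteversion 44.847457 0.193370 indication   strong   exam
  hip_rotation_mean 28.324050 0.139767 indication   strong   gait
      baseline_faqt 35.927412 0.023127 indication     weak   exam
    popliteal_angle 48.632587 0.021508 indication     weak   exam
         mean  lo50  hi50  lo90  hi90
treated  15.0   9.3  20.6   2.1  28.5
control   5.1  -0.6  10.6  -7.6  18.4
effect    9.9   8.7  11.2   6.9  12.1
```

The derotation model discriminates well on a test set that keeps its
natural 26% prevalence; the Gait Deviation Index (GDI) change model is
essentially unbiased and its nominal 90% intervals cover 89% of held-out
observations.  The explained limb shows the canonical torsional-surgery
picture — excessive femoral anteversion (45°) and internal hip rotation
(28°) as strong indications — and a predicted GDI gain of about 10
points (90% interval 7 to 12) from surgery versus natural history, so
this limb would be treated under the combined policy rule.

A command-line interface mirrors the library
(`ebgait simulate | fit-propensity | explain | concordance | fit-outcome |
predict-outcome | simulate-policy | report`).

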