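"""Synthetic clinical-gait cohort generator with known generative truth.

Emulates the statistical structure of a single-center clinical gait
analysis (CGA) database: one row per limb-visit carrying demographic,
physical-exam and gait-kinematic features, twelve binary surgery
indicators, and follow-up change (delta) columns for ~10 outcome
measures.  Treatment assignment follows a latent, partly nonlinear
standard-of-practice policy perturbed by clinician-to-clinician noise;
outcome changes carry a treatment effect whose magnitude scales with how
strongly the limb was indicated for the surgery under the latent policy.

The generator materialises both potential outcomes for every limb and
treatment, so counterfactual policy arms can be evaluated against ground
truth rather than against model predictions.

All delta outcomes are oriented so that positive = clinical improvement
(e.g. the popliteal-angle outcome is the reduction toward typical), which
keeps "indicated effect >= contraindicated effect" true for every
outcome regardless of the raw measure's direction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit


class ConfigurationError(ValueError):
    """Raised for invalid generator or policy configuration."""


# --------------------------------------------------------------------------
# Feature registry: name -> (population mean, sd, severity loading, kind)
# Severity is a latent N(0,1) per limb; higher severity = more impaired.
# Loadings set the cross-feature correlation structure typical of CP gait
# data (low GDI, contracted ankle, high popliteal angle co-occur).
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureDef:
    name: str
    mean: float
    sd: float            # residual (independent) sd
    severity_loading: float
    kind: str = "numeric"  # numeric | ordinal | binary | categorical


FEATURE_DEFS: tuple[FeatureDef, ...] = (
    FeatureDef("age", 8.9, 3.3, 0.0),
    FeatureDef("female", 0.42, 0.0, 0.0, kind="binary"),
    FeatureDef("dx_category", 0.0, 0.0, 0.0, kind="categorical"),
    FeatureDef("era", 2009.0, 8.0, 0.0),
    FeatureDef("baseline_gdi", 72.0, 8.0, -8.0),
    FeatureDef("baseline_faqt", 60.0, 10.0, -9.0),
    FeatureDef("tibial_torsion", 15.0, 9.0, 4.0),
    FeatureDef("femoral_anteversion", 30.0, 9.0, 7.0),
    FeatureDef("hip_rotation_mean", 5.0, 9.0, 6.0),
    FeatureDef("ankle_dorsiflexion_rom", 10.0, 7.0, -5.0),
    FeatureDef("knee_flexion_rom", 45.0, 9.0, -7.0),
    FeatureDef("popliteal_angle", 40.0, 11.0, 8.0),
    FeatureDef("max_knee_flexion", 55.0, 8.0, -6.0),
    FeatureDef("foot_deformity_score", 3.0, 1.5, 0.8),
    FeatureDef("rectus_spasticity", 1.5, 1.0, 0.6, kind="ordinal"),
    FeatureDef("prior_rectus_transfer", 0.08, 0.0, 0.0, kind="binary"),
)

FEATURE_MEANS: dict[str, float] = {f.name: f.mean for f in FEATURE_DEFS}
FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in FEATURE_DEFS)

# The twelve modeled surgeries with their approximate historical
# prevalences at a large CGA center.
TREATMENT_PREVALENCES: dict[str, float] = {
    "neural_rhizotomy": 0.18,
    "rectus_transfer": 0.07,
    "psoas_release": 0.06,
    "hams_lengthening": 0.07,
    "adductor_release": 0.04,
    "calf_lengthening": 0.18,
    "femoral_derotation_osteotomy": 0.25,
    "tibial_derotation_osteotomy": 0.16,
    "dfeo_patellar_advance": 0.03,
    "patellar_advance": 0.03,
    "foot_ankle_bone": 0.19,
    "foot_ankle_soft_tissue": 0.12,
}

TREATMENT_NAMES: tuple[str, ...] = tuple(TREATMENT_PREVALENCES)


@dataclass(frozen=True)
class NonlinearTerm:
    """Nonlinear policy term on the logit scale.

    kind="quadratic": weight * ((x - center) / scale)**2  (U-shape with
    minimum at `center`); kind="hinge": weight * max(0, (x - center) / scale).
    """

    feature: str
    kind: str  # "quadratic" | "hinge"
    center: float
    scale: float = 1.0
    weight: float = 1.0

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        z = (x - self.center) / self.scale
        if self.kind == "quadratic":
            return self.weight * z**2
        if self.kind == "hinge":
            return self.weight * np.maximum(z, 0.0)
        raise ConfigurationError(f"unknown nonlinear term kind {self.kind!r}")


@dataclass(frozen=True)
class TreatmentSpec:
    """Latent standard-of-practice policy for one surgery.

    `policy_coefficients` are logit-scale weights applied to the feature's
    deviation from its population center, so a missing value contributes
    the prior mean (zero deviation).  `intercept=None` means "calibrate at
    generation time so the realized prevalence matches the target".
    """

    name: str
    prevalence_target: float
    policy_coefficients: Mapping[str, float] = field(default_factory=dict)
    nonlinear_terms: tuple[NonlinearTerm, ...] = ()
    intercept: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence_target <= 0.5):
            raise ConfigurationError(
                f"prevalence target for {self.name!r} must be in (0, 0.5], "
                f"got {self.prevalence_target}"
            )


@dataclass(frozen=True)
class OutcomeSpec:
    """Generative law for one follow-up change column.

    The realised treatment effect for a limb is
    ``contra + (ind - contra) * s`` where ``s`` is the limb's latent
    indication strength (its true policy probability), so well-indicated
    surgery helps a lot and contraindicated surgery helps little or harms.
    """

    name: str
    baseline_feature: str
    direct_treatments: tuple[str, ...]
    effect_if_indicated: float
    effect_if_contraindicated: float
    noise_sd: float
    regression_to_mean_coef: float = 0.25

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0 for {self.name!r}")
        if self.effect_if_indicated < self.effect_if_contraindicated:
            raise ConfigurationError(
                f"effect_if_indicated < effect_if_contraindicated for {self.name!r}"
            )


@dataclass(frozen=True)
class MissingnessSpec:
    """Masking rates per feature with MCAR or severity-dependent mechanism.

    severity-dependent masking removes values preferentially on severe
    limbs (the 'cannot measure a severely contracted limb' mechanism).
    """

    rates: Mapping[str, float] = field(default_factory=dict)
    mechanisms: Mapping[str, str] = field(default_factory=dict)  # mcar | severity
    severity_slope: float = 1.0

    def __post_init__(self) -> None:
        for name, rate in self.rates.items():
            if not (0.0 <= rate <= 1.0):
                raise ConfigurationError(f"missingness rate for {name!r} not in [0,1]")
            mech = self.mechanisms.get(name, "mcar")
            if mech not in ("mcar", "severity"):
                raise ConfigurationError(f"unknown missingness mechanism {mech!r}")


def default_treatments() -> tuple[TreatmentSpec, ...]:
    """The twelve default surgery policies.

    Coefficients encode the field's canonical indications: torsional
    deformity for derotation osteotomies (U-shaped in tibial torsion),
    contracture measures for lengthenings, spasticity for rhizotomy, a
    declining era trend for rectus transfer, etc.
    """
    return (
        TreatmentSpec("neural_rhizotomy", 0.18, {
            "rectus_spasticity": 1.0, "age": -0.30, "baseline_gdi": -0.08}),
        TreatmentSpec("rectus_transfer", 0.07, {
            "knee_flexion_rom": -0.10, "age": 0.18, "era": -0.10,
            "rectus_spasticity": 0.6, "prior_rectus_transfer": -2.0,
            "max_knee_flexion": -0.07}),
        TreatmentSpec("psoas_release", 0.06, {
            "popliteal_angle": 0.03, "baseline_gdi": -0.04}),
        TreatmentSpec("hams_lengthening", 0.07, {
            "popliteal_angle": 0.12, "knee_flexion_rom": -0.04}),
        TreatmentSpec("adductor_release", 0.04, {
            "rectus_spasticity": 0.5, "baseline_gdi": -0.06}),
        TreatmentSpec("calf_lengthening", 0.18, {
            "ankle_dorsiflexion_rom": -0.16, "age": 0.10, "era": -0.05}),
        TreatmentSpec("femoral_derotation_osteotomy", 0.25, {
            "femoral_anteversion": 0.14, "hip_rotation_mean": 0.10}),
        TreatmentSpec("tibial_derotation_osteotomy", 0.16, {},
                      nonlinear_terms=(NonlinearTerm(
                          "tibial_torsion", "quadratic", center=15.0,
                          scale=10.0, weight=1.4),)),
        TreatmentSpec("dfeo_patellar_advance", 0.03, {
            "popliteal_angle": 0.10, "age": 0.35, "max_knee_flexion": -0.05}),
        TreatmentSpec("patellar_advance", 0.03, {
            "popliteal_angle": 0.07, "age": 0.20}),
        TreatmentSpec("foot_ankle_bone", 0.19, {
            "foot_deformity_score": 0.9, "age": 0.08}),
        TreatmentSpec("foot_ankle_soft_tissue", 0.12, {
            "foot_deformity_score": 0.5, "age": -0.12}),
    )


def default_outcomes() -> tuple[OutcomeSpec, ...]:
    """Ten default change outcomes spanning body-structure measures
    (direct, tightly coupled to one surgery) through kinematics (GDI) to
    activity (FAQt, causally downstream: attenuated effects, more noise).
    Noise scales are set so that well-specified models yield 90% interval
    widths comparable to the 16-45 unit range seen for real gait outcomes.
    """
    gdi_direct = ("femoral_derotation_osteotomy", "calf_lengthening",
                  "tibial_derotation_osteotomy", "foot_ankle_bone",
                  "neural_rhizotomy", "hams_lengthening")
    return (
        OutcomeSpec("delta_gdi", "baseline_gdi", gdi_direct, 12.0, -3.0, 7.5, 0.25),
        OutcomeSpec("delta_faqt", "baseline_faqt", gdi_direct, 6.0, -1.5, 12.0, 0.20),
        OutcomeSpec("delta_ankle_dorsiflexion_rom", "ankle_dorsiflexion_rom",
                    ("calf_lengthening",), 15.0, -2.0, 7.0, 0.30),
        OutcomeSpec("delta_max_ankle_dorsiflexion", "ankle_dorsiflexion_rom",
                    ("calf_lengthening",), 12.0, -2.0, 6.0, 0.30),
        OutcomeSpec("delta_popliteal_angle", "popliteal_angle",
                    ("hams_lengthening", "dfeo_patellar_advance"), 18.0, -2.0, 9.0, 0.30),
        OutcomeSpec("delta_femoral_anteversion", "femoral_anteversion",
                    ("femoral_derotation_osteotomy",), 25.0, 0.0, 9.0, 0.10),
        OutcomeSpec("delta_tibial_torsion", "tibial_torsion",
                    ("tibial_derotation_osteotomy",), 20.0, 0.0, 8.0, 0.10),
        OutcomeSpec("delta_hip_rotation", "hip_rotation_mean",
                    ("femoral_derotation_osteotomy",), 15.0, -2.0, 9.0, 0.30),
        OutcomeSpec("delta_knee_flexion_ic", "knee_flexion_rom",
                    ("hams_lengthening",), 10.0, -1.0, 8.0, 0.30),
        OutcomeSpec("delta_foot_deformity", "foot_deformity_score",
                    ("foot_ankle_bone", "foot_ankle_soft_tissue"), 3.0, 0.0, 1.5, 0.30),
    )


def strong_signal_config(n_limbs: int = 4000, seed: int = 0,
                         clinician_noise_sd: float = 0.25) -> "GeneratorConfig":
    """Recovery-experiment conditions: a strong two-feature derotation
    policy near 50% prevalence with adjustable clinician noise, used to
    probe how well propensity fits recover a consistent standard of
    practice and how accuracy degrades as decisions get noisier."""
    specs = list(default_treatments())
    specs[6] = TreatmentSpec("femoral_derotation_osteotomy", 0.45, {
        "femoral_anteversion": 0.6, "hip_rotation_mean": 0.42})
    return GeneratorConfig(n_limbs=n_limbs, seed=seed,
                           treatments=tuple(specs),
                           clinician_noise_sd=clinician_noise_sd)


def default_missingness() -> MissingnessSpec:
    # severity-dependent ROM missingness mirrors real clinics: severely
    # contracted limbs are the ones that cannot be measured.
    return MissingnessSpec(
        rates={"ankle_dorsiflexion_rom": 0.06, "popliteal_angle": 0.05,
               "femoral_anteversion": 0.08, "tibial_torsion": 0.08,
               "rectus_spasticity": 0.04},
        mechanisms={"ankle_dorsiflexion_rom": "severity",
                    "popliteal_angle": "severity"},
    )


@dataclass(frozen=True)
class GeneratorConfig:
    n_limbs: int = 7546
    seed: int = 0
    age_mean: float = 8.9
    age_sd: float = 3.3
    female_frac: float = 0.42
    dominant_dx_frac: float = 0.84
    n_dx_categories: int = 10
    treatments: tuple[TreatmentSpec, ...] = field(default_factory=default_treatments)
    outcomes: tuple[OutcomeSpec, ...] = field(default_factory=default_outcomes)
    missingness: MissingnessSpec = field(default_factory=default_missingness)
    clinician_noise_sd: float = 1.0   # logit units; bounds achievable accuracy
    bilateral_correlation: float = 0.5
    assignment: str = "bernoulli"     # bernoulli | threshold (degenerate limit)

    def __post_init__(self) -> None:
        if self.n_limbs < 2:
            raise ConfigurationError("n_limbs must be >= 2")
        for frac, label in ((self.female_frac, "female_frac"),
                            (self.dominant_dx_frac, "dominant_dx_frac"),
                            (self.bilateral_correlation, "bilateral_correlation")):
            if not (0.0 <= frac <= 1.0):
                raise ConfigurationError(f"{label} must be in [0,1]")
        if self.clinician_noise_sd < 0:
            raise ConfigurationError("clinician_noise_sd must be >= 0")
        if self.assignment not in ("bernoulli", "threshold"):
            raise ConfigurationError(f"unknown assignment mode {self.assignment!r}")


@dataclass
class SyntheticTruth:
    """Ground truth retained at generation time.

    policy_probability : DataFrame (limb_id x treatment), the noise-free
        latent policy probability — also the limb's indication strength.
    effects : outcome name -> DataFrame (limb_id x direct treatments),
        the per-limb true treatment effect in outcome units.
    natural_delta : DataFrame (limb_id x outcome), the potential outcome
        change with every treatment switched off (natural history).
    resolved_treatments : specs with calibrated intercepts filled in.
    """

    policy_probability: pd.DataFrame
    effects: dict[str, pd.DataFrame]
    natural_delta: pd.DataFrame
    resolved_treatments: tuple[TreatmentSpec, ...]
    seed: int

    def potential_delta(self, outcome: str,
                        decisions: pd.DataFrame) -> pd.Series:
        """Potential outcome change under an arbitrary decision matrix.

        `decisions` is (limb_id x treatment) of {0,1}; missing treatment
        columns count as untreated.
        """
        if outcome not in self.natural_delta.columns:
            raise KeyError(f"no counterfactual truth for outcome {outcome!r}")
        delta = self.natural_delta.loc[decisions.index, outcome].astype(float).copy()
        eff = self.effects[outcome]
        for treat in eff.columns:
            if treat in decisions.columns:
                delta = delta + decisions[treat].to_numpy(dtype=float) * eff.loc[
                    decisions.index, treat].to_numpy()
        return delta

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "policy_probability": self.policy_probability.to_dict(orient="index"),
            "effects": {k: v.to_dict(orient="index") for k, v in self.effects.items()},
            "natural_delta": self.natural_delta.to_dict(orient="index"),
            "intercepts": {t.name: t.intercept for t in self.resolved_treatments},
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        pp = pd.DataFrame.from_dict(payload["policy_probability"], orient="index")
        pp.index.name = "limb_id"
        effects = {}
        for k, v in payload["effects"].items():
            df = pd.DataFrame.from_dict(v, orient="index")
            df.index.name = "limb_id"
            effects[k] = df
        nd = pd.DataFrame.from_dict(payload["natural_delta"], orient="index")
        nd.index.name = "limb_id"
        specs = tuple(
            replace(t, intercept=payload["intercepts"].get(t.name))
            for t in default_treatments()
        )
        return cls(pp, effects, nd, specs, payload["seed"])


# --------------------------------------------------------------------------
# Policy evaluation
# --------------------------------------------------------------------------

def policy_score(features: pd.DataFrame, spec: TreatmentSpec) -> np.ndarray:
    """Centered logit-scale policy score, excluding the intercept.

    Missing values contribute zero after centering, i.e. the prior mean.
    """
    score = np.zeros(len(features), dtype=float)
    for name, weight in spec.policy_coefficients.items():
        if name not in features.columns:
            raise ConfigurationError(
                f"policy for {spec.name!r} references unknown feature {name!r}")
        center = FEATURE_MEANS.get(name, 0.0)
        x = pd.to_numeric(features[name], errors="coerce").to_numpy(dtype=float)
        score += weight * np.nan_to_num(x - center, nan=0.0)
    for term in spec.nonlinear_terms:
        if term.feature not in features.columns:
            raise ConfigurationError(
                f"policy for {spec.name!r} references unknown feature {term.feature!r}")
        x = pd.to_numeric(features[term.feature], errors="coerce").to_numpy(dtype=float)
        vals = term.evaluate(np.nan_to_num(x, nan=term.center))
        # center the nonlinear term at its value for a typical limb
        vals -= term.evaluate(np.array([FEATURE_MEANS.get(term.feature, term.center)]))[0]
        score += vals
    return score


def true_policy_probability(features: pd.DataFrame, spec: TreatmentSpec) -> np.ndarray:
    """Latent probability that the historical standard of practice
    prescribes `spec.name` for each row of `features`.

    With no calibrated intercept the intercept implied by the prevalence
    target (logit of the target) is used, so an all-zero-coefficient
    policy returns the target exactly.
    """
    intercept = spec.intercept if spec.intercept is not None else float(
        logit(spec.prevalence_target))
    return expit(intercept + policy_score(features, spec))


def _calibrate_intercept(score_plus_noise: np.ndarray, target: float) -> float:
    """Intercept c with mean(expit(score + c)) == target, by bisection."""
    lo, hi = -30.0, 30.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if float(np.mean(expit(score_plus_noise + mid))) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

def _draw_features(config: GeneratorConfig, rng: np.random.Generator
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw limb-visit feature rows; returns (features, severity)."""
    n = config.n_limbs
    n_patients = (n + 1) // 2
    patient_of_limb = np.repeat(np.arange(n_patients), 2)[:n]
    side = np.tile(["L", "R"], n_patients)[:n]

    # shared patient-level latent severity induces bilateral correlation
    r = config.bilateral_correlation
    u_patient = rng.normal(size=n_patients)
    severity = (np.sqrt(r) * u_patient[patient_of_limb]
                + np.sqrt(1.0 - r) * rng.normal(size=n))

    age_p = np.clip(rng.normal(config.age_mean, config.age_sd, n_patients), 1.5, 21.0)
    female_p = (rng.random(n_patients) < config.female_frac).astype(int)
    dx_p = np.where(
        rng.random(n_patients) < config.dominant_dx_frac, 0,
        rng.integers(1, max(config.n_dx_categories, 2), n_patients))
    era_p = np.clip(np.round(rng.normal(2009.0, 8.0, n_patients)), 1994, 2024)

    cols: dict[str, np.ndarray] = {
        "age": age_p[patient_of_limb],
        "female": female_p[patient_of_limb],
        "dx_category": dx_p[patient_of_limb],
        "era": era_p[patient_of_limb],
    }
    for fd in FEATURE_DEFS:
        if fd.name in cols:
            continue
        if fd.kind == "binary":
            p = np.clip(fd.mean + 0.05 * fd.severity_loading * severity, 0.0, 1.0)
            cols[fd.name] = (rng.random(n) < p).astype(int)
        elif fd.kind == "ordinal":
            raw = fd.mean + fd.severity_loading * severity + rng.normal(0, fd.sd, n)
            cols[fd.name] = np.clip(np.round(raw), 0, 4).astype(int)
        else:
            cols[fd.name] = (fd.mean + fd.severity_loading * severity
                             + rng.normal(0, fd.sd, n))
    feats = pd.DataFrame(cols, index=pd.Index(
        [f"limb_{i:05d}" for i in range(n)], name="limb_id"))
    feats.insert(0, "patient_id", [f"pat_{p:05d}" for p in patient_of_limb])
    feats.insert(1, "side", side)
    # keep foot deformity on its 0-10 scale
    feats["foot_deformity_score"] = np.clip(feats["foot_deformity_score"], 0.0, 10.0)
    return feats, severity


def generate_cohort(config: GeneratorConfig
                    ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate a limb-visit cohort table and its generative truth.

    Deterministic given ``config.seed``; every stage draws from an
    independent child stream of one seeded generator.
    """
    root = np.random.SeedSequence(config.seed)
    s_feat, s_assign, s_outcome, s_miss = root.spawn(4)
    feats, severity = _draw_features(config, np.random.default_rng(s_feat))
    feature_cols = [c for c in feats.columns if c not in ("patient_id", "side")]

    rng_a = np.random.default_rng(s_assign)
    policy_prob = {}
    resolved = []
    treat_cols = {}
    for spec in config.treatments:
        score = policy_score(feats[feature_cols], spec)
        noise = (config.clinician_noise_sd * rng_a.normal(size=len(feats))
                 if config.clinician_noise_sd > 0 else np.zeros(len(feats)))
        if spec.intercept is not None:
            intercept = spec.intercept
        else:
            intercept = _calibrate_intercept(score + noise, spec.prevalence_target)
        rspec = replace(spec, intercept=intercept)
        resolved.append(rspec)
        pi_clean = expit(intercept + score)
        policy_prob[spec.name] = pi_clean
        p_noisy = expit(intercept + score + noise)
        if config.assignment == "threshold":
            treat_cols[spec.name] = (p_noisy > 0.5).astype(int)
        else:
            treat_cols[spec.name] = (rng_a.random(len(feats)) < p_noisy).astype(int)

    policy_df = pd.DataFrame(policy_prob, index=feats.index)
    treat_df = pd.DataFrame(treat_cols, index=feats.index)

    rng_o = np.random.default_rng(s_outcome)
    effects: dict[str, pd.DataFrame] = {}
    natural = {}
    delta_cols = {}
    for ospec in config.outcomes:
        base = pd.to_numeric(feats[ospec.baseline_feature]).to_numpy(dtype=float)
        pop_mean = FEATURE_MEANS[ospec.baseline_feature]
        nat = (ospec.regression_to_mean_coef * (pop_mean - base)
               + rng_o.normal(0.0, ospec.noise_sd, len(feats)))
        span = ospec.effect_if_indicated - ospec.effect_if_contraindicated
        eff = pd.DataFrame(
            {t: ospec.effect_if_contraindicated + span * policy_df[t].to_numpy()
             for t in ospec.direct_treatments}, index=feats.index)
        observed = nat.copy()
        for t in ospec.direct_treatments:
            observed = observed + treat_df[t].to_numpy() * eff[t].to_numpy()
        effects[ospec.name] = eff
        natural[ospec.name] = nat
        delta_cols[ospec.name] = observed

    table = pd.concat(
        [feats, treat_df, pd.DataFrame(delta_cols, index=feats.index)], axis=1)
    table = apply_missingness(table, config.missingness,
                              severity=severity,
                              rng=np.random.default_rng(s_miss))
    truth = SyntheticTruth(
        policy_probability=policy_df,
        effects=effects,
        natural_delta=pd.DataFrame(natural, index=feats.index),
        resolved_treatments=tuple(resolved),
        seed=config.seed,
    )
    return table, truth


def apply_missingness(table: pd.DataFrame, spec: MissingnessSpec, *,
                      severity: np.ndarray | None = None,
                      rng: np.random.Generator | None = None,
                      seed: int | None = None) -> pd.DataFrame:
    """Mask feature cells per the missingness spec.

    Treatment indicator and delta-outcome columns must never be masked.
    severity-dependent masking needs the latent severity vector; without
    one the feature's own standardized value is used as the severity
    proxy (value-dependent missingness).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out = table.copy()
    protected = set(TREATMENT_NAMES) | {c for c in table.columns
                                        if c.startswith("delta_")}
    for name, rate in spec.rates.items():
        if name in protected:
            raise ConfigurationError(
                f"refusing to mask treatment/outcome column {name!r}")
        if name not in out.columns or rate == 0.0:
            continue
        n = len(out)
        mech = spec.mechanisms.get(name, "mcar")
        if mech == "mcar":
            mask = rng.random(n) < rate
        else:
            if severity is not None:
                sev = severity
            else:
                x = pd.to_numeric(out[name], errors="coerce")
                sev = ((x - x.mean()) / (x.std() or 1.0)).to_numpy()
                sev = sev * np.sign(
                    next(f.severity_loading for f in FEATURE_DEFS
                         if f.name == name) or 1.0)
            # logistic in severity, calibrated so the marginal rate ~ rate
            shift = _calibrate_intercept(spec.severity_slope * sev, rate)
            mask = rng.random(n) < expit(spec.severity_slope * sev + shift)
        col = out[name].astype(float)
        col[mask] = np.nan
        out[name] = col
    return out


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Model-feature columns of a cohort table (excludes identifiers,
    treatment indicators and delta outcomes)."""
    skip = {"patient_id", "side"} | set(TREATMENT_NAMES)
    return [c for c in table.columns
            if c not in skip and not c.startswith("delta_")]
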