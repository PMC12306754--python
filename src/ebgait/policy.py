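"""Counterfactual simulation of treatment-policy implementation
strategies for one index surgery.

Four arms: (1) current practice — keep the administered treatment
vector; (2) recommendation-only — treat when the propensity mean
exceeds a probability threshold; (3) outcome-only — treat when the mean
predicted treatment effect exceeds an outcome threshold; (4) combined —
the conjunction of both rules.  On synthetic cohorts each limb's two
potential outcomes are known, so policy arms are scored against ground
truth rather than against the models making the decisions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import SyntheticTruth

POLICIES = ("current", "propensity_only", "outcome_only", "combined")


@dataclass(frozen=True)
class PolicyConfig:
    policy: str
    probability_threshold: float = 0.5
    outcome_threshold: float = 7.5      # default: GDI change of at least +7.5

    def __post_init__(self) -> None:
        if self.policy not in POLICIES:
            raise ValueError(f"unknown policy {self.policy!r}")
        if not (0.0 < self.probability_threshold < 1.0):
            raise ValueError("probability_threshold must be in (0,1)")
        if not np.isfinite(self.outcome_threshold) and self.policy in (
                "outcome_only", "combined"):
            # infinite thresholds are allowed as degenerate limits
            pass


@dataclass(frozen=True)
class PolicyResult:
    policy: str
    n_treated: int
    n_untreated: int
    fraction_treated: float
    mean_delta_treated: float
    mean_delta_untreated: float

    def to_row(self) -> dict:
        return {"policy": self.policy,
                "frac_treated": self.fraction_treated,
                "mean_change_treated": self.mean_delta_treated,
                "mean_change_untreated": self.mean_delta_untreated,
                "n_treated": self.n_treated,
                "n_untreated": self.n_untreated}


def decide(config: PolicyConfig, p_mean, effect_mean, actual_treated):
    """Per-limb treatment decision under a policy arm.

    Comparisons are strict: probability must exceed the threshold and
    the mean predicted effect must exceed the outcome threshold.
    """
    p_mean = np.asarray(p_mean, dtype=float)
    effect_mean = np.asarray(effect_mean, dtype=float)
    actual = np.asarray(actual_treated, dtype=int)
    if config.policy == "current":
        out = actual
    elif config.policy == "propensity_only":
        out = (p_mean > config.probability_threshold).astype(int)
    elif config.policy == "outcome_only":
        out = (effect_mean > config.outcome_threshold).astype(int)
    else:  # combined
        out = ((p_mean > config.probability_threshold)
               & (effect_mean > config.outcome_threshold)).astype(int)
    return out


def simulate_policies(cohort: pd.DataFrame, propensity_fit, outcome_fit,
                      truth: SyntheticTruth, *,
                      treatment: str | None = None,
                      outcome: str | None = None,
                      configs: list[PolicyConfig] | None = None
                      ) -> list[PolicyResult]:
    """Evaluate the four policy arms on a cohort disjoint from the
    models' training data.

    For each limb the index-surgery decision is made per arm; the other
    eleven surgeries stay at their recorded values.  The realised
    outcome change comes from the generative truth's counterfactual
    pair, so arms are compared on what would actually have happened.
    """
    treatment = treatment or propensity_fit.treatment
    outcome = outcome or outcome_fit.outcome
    if truth is None:
        raise ValueError(
            "counterfactual truth is required to compare policy arms; "
            "without it only observed-arm summaries are defined")
    if configs is None:
        configs = [PolicyConfig(p) for p in POLICIES]

    p_mean = propensity_fit.predict_mean(cohort)
    effect = outcome_fit.estimate_treatment_effect(
        cohort, (treatment,), control="complement_zero")
    effect_mean = effect.effect_draws.mean(axis=1)
    actual = cohort[treatment].to_numpy(dtype=int)

    other_decisions = cohort[[t for t in truth.policy_probability.columns
                              if t != treatment]].astype(int)
    results = []
    for config in configs:
        dec = decide(config, p_mean, effect_mean, actual)
        decisions = other_decisions.copy()
        decisions[treatment] = dec
        realized = truth.potential_delta(outcome, decisions).to_numpy()
        treated = dec == 1
        results.append(PolicyResult(
            policy=config.policy,
            n_treated=int(treated.sum()),
            n_untreated=int((~treated).sum()),
            fraction_treated=float(treated.mean()),
            mean_delta_treated=float(realized[treated].mean())
            if treated.any() else float("nan"),
            mean_delta_untreated=float(realized[~treated].mean())
            if (~treated).any() else float("nan"),
        ))
    return results


def results_table(results: list[PolicyResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
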