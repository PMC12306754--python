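"""Outcome-change models and counterfactual treatment-effect estimates.

An outcome model predicts the follow-up change in a clinical measure
from the baseline value of that measure, relevant structural and
biomechanical features, and the twelve binary treatment indicators:

    dY = O(f_1, ..., f_k, treat_1, ..., treat_12)

Treatment effects are counterfactual: the same limb is predicted with a
chosen treatment set switched on and with every treatment switched off
(the natural-history control), and posterior draws are differenced
pairwise.  Calibration on held-out data reports bias, mean absolute
error, mean 90% interval width and empirical 90% coverage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import backend
from .cohort import TREATMENT_NAMES, feature_columns


class OutcomeConfigurationError(ValueError):
    pass


@dataclass
class EffectEstimate:
    """Counterfactual prediction pair and their paired difference."""

    treated: backend.PosteriorDraws
    control: backend.PosteriorDraws
    treat_set: tuple[str, ...]

    @property
    def effect_draws(self) -> np.ndarray:
        return self.treated.values - self.control.values

    def summary_frame(self) -> pd.DataFrame:
        rows = {}
        for label, vals in (("treated", self.treated.values),
                            ("control", self.control.values),
                            ("effect", self.effect_draws)):
            lo50, hi50 = np.quantile(vals, [0.25, 0.75], axis=1)
            lo90, hi90 = np.quantile(vals, [0.05, 0.95], axis=1)
            rows[label] = {"mean": float(vals.mean()),
                           "lo50": float(lo50.mean()), "hi50": float(hi50.mean()),
                           "lo90": float(lo90.mean()), "hi90": float(hi90.mean())}
        return pd.DataFrame(rows).T

    @property
    def mean_effect(self) -> float:
        return float(self.effect_draws.mean())


@dataclass(frozen=True)
class CalibrationReport:
    outcome: str
    bias: float
    mae: float
    width_90: float
    coverage_90: float
    n_test: int


class OutcomeModel:
    """Model for one follow-up change column.

    Parameters
    ----------
    train : cohort rows (full, unbalanced training split).
    outcome : name of the delta column to model.
    features : clinical features; must include the baseline value of the
        outcome variable.  Defaults to all feature columns.
    treatments : treatment indicator columns (default: the 12 surgeries).
    baseline_feature : name of the baseline-of-outcome feature, used only
        to validate that it is present among ``features``.
    """

    def __init__(self, train: pd.DataFrame, outcome: str,
                 features: list[str] | None = None,
                 treatments: tuple[str, ...] = TREATMENT_NAMES,
                 baseline_feature: str | None = None):
        if outcome not in train.columns:
            raise KeyError(f"outcome column {outcome!r} not in table")
        self.features = features or feature_columns(train)
        if baseline_feature is not None and baseline_feature not in self.features:
            raise OutcomeConfigurationError(
                f"baseline feature {baseline_feature!r} missing from features")
        for t in treatments:
            vals = pd.unique(train[t].dropna())
            if not np.isin(vals, [0, 1]).all():
                raise OutcomeConfigurationError(
                    f"treatment column {t!r} is not binary")
        self.train = train
        self.outcome = outcome
        self.treatments = tuple(treatments)

    def fit(self, seed: int = 0, **fit_kwargs) -> "OutcomeResults":
        cols = self.features + list(self.treatments)
        rows = self.train[self.train[self.outcome].notna()]
        posterior = backend.fit(rows[cols], rows[self.outcome], "regression",
                                seed=seed, **fit_kwargs)
        return OutcomeResults(self, posterior, seed)


class OutcomeResults:
    """Fitted outcome model with counterfactual-prediction helpers."""

    def __init__(self, model: OutcomeModel, posterior: backend.PosteriorModel,
                 seed: int):
        self.model = model
        self.posterior = posterior
        self.seed = seed

    @property
    def outcome(self) -> str:
        return self.model.outcome

    def _design(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.model.features + list(self.model.treatments)]

    def predict_draws(self, X: pd.DataFrame) -> backend.PosteriorDraws:
        return self.posterior.predict_draws(self._design(X))

    def predict_mean(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_draws(X).mean()

    def _counterfactual(self, X: pd.DataFrame, on: tuple[str, ...],
                        off: tuple[str, ...]) -> backend.PosteriorDraws:
        cf = X.copy()
        for t in on:
            cf[t] = 1
        for t in off:
            cf[t] = 0
        return self.predict_draws(cf)

    def estimate_treatment_effect(self, limb: pd.DataFrame,
                                  treat_set, *,
                                  control: str = "all_zero") -> EffectEstimate:
        """Counterfactual effect of switching ``treat_set`` on.

        The control arm sets every treatment indicator to 0 (natural
        history) by default; ``control="complement_zero"`` zeroes only
        the treat_set, leaving other indicators at their recorded values.
        Draws are differenced at matched draw indices.
        """
        treat_set = tuple([treat_set] if isinstance(treat_set, str)
                          else treat_set)
        if not treat_set:
            raise ValueError("treat_set must be non-empty")
        unknown = [t for t in treat_set if t not in self.model.treatments]
        if unknown:
            raise KeyError(f"unknown treatment(s) {unknown}")
        treated = self._counterfactual(
            limb, on=treat_set,
            off=tuple(t for t in self.model.treatments if t not in treat_set)
            if control == "all_zero" else ())
        off = (self.model.treatments if control == "all_zero"
               else treat_set)
        ctrl = self._counterfactual(limb, on=(), off=tuple(off))
        return EffectEstimate(treated, ctrl, treat_set)

    def multilevel_effect(self, limb: pd.DataFrame, treat_set
                          ) -> tuple[EffectEstimate, EffectEstimate, float]:
        """Joint multi-level counterfactual versus the sum of
        single-level effects; returns (joint, summed, mean discrepancy).

        The summed estimate adds single-treatment effect draws at
        matched draw indices — the small-interactions approximation.
        """
        treat_set = tuple(treat_set)
        if len(treat_set) < 2:
            raise ValueError("multilevel effect needs at least 2 treatments")
        joint = self.estimate_treatment_effect(limb, treat_set)
        singles = [self.estimate_treatment_effect(limb, (t,))
                   for t in treat_set]
        summed_vals = np.sum([s.effect_draws for s in singles], axis=0)
        control = singles[0].control
        summed = EffectEstimate(
            backend.PosteriorDraws(control.values + summed_vals, "outcome"),
            control, treat_set)
        discrepancy = float(joint.mean_effect - summed.mean_effect)
        return joint, summed, discrepancy

    def calibrate(self, test: pd.DataFrame,
                  level: float = 0.9) -> CalibrationReport:
        """Bias, MAE, interval width and empirical coverage on held-out
        rows with observed outcome changes."""
        rows = test[test[self.outcome].notna()]
        if len(rows) == 0:
            raise ValueError("empty test set")
        draws = self.predict_draws(rows)
        pred = draws.mean()
        obs = rows[self.outcome].to_numpy(dtype=float)
        lo, hi = draws.interval(level)
        err = pred - obs
        return CalibrationReport(
            outcome=self.outcome,
            bias=float(err.mean()),
            mae=float(np.abs(err).mean()),
            width_90=float((hi - lo).mean()),
            coverage_90=float(np.mean((obs >= lo) & (obs <= hi))),
            n_test=len(rows),
        )

    def summary(self) -> str:
        return (f"OutcomeResults({self.outcome!r}, "
                f"members={len(self.posterior.members)}, "
                f"sigma={self.posterior.sigma:.2f}, seed={self.seed})")
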