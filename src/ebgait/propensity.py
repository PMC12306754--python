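"""Treatment-recommendation (propensity) models.

For each of the 12 surgeries: split the cohort 70/30 at the patient
level, undersample the training side to a balanced treated/untreated
subsample, fit a posterior tree model of treatment probability, and
evaluate sensitivity, specificity, balanced accuracy and AUC on the
naturally imbalanced test set at the 0.5 mean-probability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupShuffleSplit

from . import backend
from .cohort import TREATMENT_NAMES, feature_columns


class SplitError(ValueError):
    pass


class UndersampleError(ValueError):
    pass


class EvaluationError(ValueError):
    pass


def split_train_test(table: pd.DataFrame, train_frac: float = 0.7,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient-level train/test split: both limbs of a patient land on
    the same side, and the test side keeps its natural class imbalance."""
    if not (0.0 < train_frac < 1.0):
        raise SplitError("train_frac must be in (0,1)")
    groups = (table["patient_id"] if "patient_id" in table.columns
              else table.index.to_series())
    if groups.nunique() < 2:
        raise SplitError("need at least 2 patients to split")
    splitter = GroupShuffleSplit(n_splits=1, train_size=train_frac,
                                 random_state=seed)
    (tr_idx, te_idx), = splitter.split(table, groups=groups)
    return table.iloc[np.sort(tr_idx)], table.iloc[np.sort(te_idx)]


def undersample_balanced(train: pd.DataFrame, treatment: str,
                         seed: int = 0) -> pd.DataFrame:
    """Keep every treated limb plus an equal-size uniform random subset
    of untreated limbs."""
    y = train[treatment].to_numpy()
    treated = train[y == 1]
    untreated = train[y == 0]
    if len(treated) < 10:
        raise UndersampleError(
            f"only {len(treated)} treated limbs for {treatment!r}; "
            "need at least 10 to build a balanced subsample")
    if len(untreated) <= len(treated):
        return train
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(untreated), size=len(treated), replace=False)
    out = pd.concat([treated, untreated.iloc[np.sort(keep)]])
    return out.sort_index()


@dataclass(frozen=True)
class ClassifierMetrics:
    """Test-set metrics at the 0.5 mean-probability threshold."""

    treatment: str
    prevalence: float
    sensitivity: float
    specificity: float
    auc: float

    @property
    def balanced_accuracy(self) -> float:
        return (self.sensitivity + self.specificity) / 2.0

    def to_row(self) -> dict:
        return {"surgery": self.treatment, "prevalence": self.prevalence,
                "balanced_accuracy": self.balanced_accuracy, "auc": self.auc,
                "specificity": self.specificity, "sensitivity": self.sensitivity}


def quintile_category(p: float) -> int:
    """Probability quintile 1-5 with left-open right-closed bins
    (0,0.2], (0.2,0.4], ...; p=0 maps to 1."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("probability outside [0,1]")
    return min(5, max(1, ceil(5.0 * p)))


class PropensityModel:
    """Treatment-recommendation model for one surgery.

    Parameters
    ----------
    train : cohort table rows used for fitting (typically the 70% side of
        a patient-level split).
    treatment : name of the binary treatment column to model.
    features : feature columns; defaults to every non-identifier,
        non-treatment, non-delta column of the table.
    """

    def __init__(self, train: pd.DataFrame, treatment: str,
                 features: list[str] | None = None):
        if treatment not in train.columns:
            raise KeyError(f"treatment column {treatment!r} not in table")
        self.train = train
        self.treatment = treatment
        self.features = features or feature_columns(train)

    def fit(self, seed: int = 0, **fit_kwargs) -> "PropensityResults":
        balanced = undersample_balanced(self.train, self.treatment, seed=seed)
        posterior = backend.fit(balanced[self.features],
                                balanced[self.treatment], "binary",
                                seed=seed, **fit_kwargs)
        return PropensityResults(self, posterior, balanced, seed)


class PropensityResults:
    """Fitted propensity model: posterior probabilities, metrics and the
    quintile recommendation category."""

    def __init__(self, model: PropensityModel,
                 posterior: backend.PosteriorModel,
                 balanced_train: pd.DataFrame, seed: int):
        self.model = model
        self.posterior = posterior
        self.balanced_train = balanced_train
        self.seed = seed

    @property
    def treatment(self) -> str:
        return self.model.treatment

    def predict_draws(self, X: pd.DataFrame) -> backend.PosteriorDraws:
        return self.posterior.predict_draws(X[self.model.features])

    def predict_mean(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_draws(X).mean()

    def evaluate(self, test: pd.DataFrame,
                 threshold: float = 0.5) -> ClassifierMetrics:
        return evaluate_metrics(self, test, threshold)

    def summary(self) -> str:
        n = len(self.balanced_train)
        return (f"PropensityResults({self.treatment!r}, balanced n={n}, "
                f"members={len(self.posterior.members)}, seed={self.seed})")


def evaluate_metrics(fit: PropensityResults, test: pd.DataFrame,
                     threshold: float = 0.5) -> ClassifierMetrics:
    """Confusion-matrix metrics on an (unbalanced) test set.

    Recommendation = posterior mean probability strictly greater than the
    threshold.  AUC is the rank statistic over posterior means.
    """
    y = test[fit.treatment].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise EvaluationError(
            f"test set contains a single class for {fit.treatment!r}")
    p = fit.predict_mean(test)
    pred = (p > threshold).astype(int)
    sens = float(np.mean(pred[y == 1] == 1))
    spec = float(np.mean(pred[y == 0] == 0))
    return ClassifierMetrics(
        treatment=fit.treatment,
        prevalence=float(np.mean(y)),
        sensitivity=sens,
        specificity=spec,
        auc=float(roc_auc_score(y, p)),
    )


@dataclass(frozen=True)
class RecommendationRow:
    treatment: str
    probability: float
    interval_90: tuple[float, float]
    category: int

    @property
    def label(self) -> str:
        return (f"{self.treatment}: {self.probability:.0%} "
                f"({self.interval_90[0]:.0%}-{self.interval_90[1]:.0%}) "
                f"[quintile {self.category}]")


def recommendation_profile(fits: dict[str, PropensityResults],
                           limb: pd.DataFrame) -> list[RecommendationRow]:
    """Per-surgery mean probability, 90% interval and quintile category
    for a single limb row (a one-row DataFrame)."""
    if len(limb) != 1:
        raise ValueError("limb must be a single-row DataFrame")
    rows = []
    for name, fit in fits.items():
        draws = fit.predict_draws(limb)
        p = float(draws.mean()[0])
        lo, hi = draws.interval(0.90)
        rows.append(RecommendationRow(name, p, (float(lo[0]), float(hi[0])),
                                      quintile_category(p)))
    return rows


def metrics_table(metrics: list[ClassifierMetrics]) -> pd.DataFrame:
    """Stack per-surgery metrics into a table with the conventional
    column order (surgery, prevalence, balanced accuracy, AUC,
    specificity, sensitivity)."""
    return pd.DataFrame([m.to_row() for m in metrics])


def fit_all(train: pd.DataFrame, seed: int = 0,
            treatments: tuple[str, ...] = TREATMENT_NAMES,
            features: list[str] | None = None,
            **fit_kwargs) -> dict[str, PropensityResults]:
    """Fit all propensity models; each treatment gets an independent
    child seed so single-model refits reproduce the ensemble run."""
    out = {}
    for i, t in enumerate(treatments):
        out[t] = PropensityModel(train, t, features).fit(
            seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)),
            **fit_kwargs)
    return out
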