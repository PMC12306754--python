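"""Shapley-value explanation of individual propensity predictions, and
partial-dependence curves for model-level understanding.

Shapley values are computed on the probability scale against a fixed
background sample (by default the model's balanced training subsample,
capped at 200 rows): the value of a coalition S is the model's mean
prediction over background rows whose S-features are replaced by the
explained limb's values.  With at most 12 features all 2^k coalitions
are enumerated, which makes the additivity (efficiency) identity

    pi_limb = S_bar + sum_f S_f

exact to machine precision; above 12 features a permutation-sampling
estimator with a reported Monte-Carlo standard error is used.  A
feature's missingness indicator is treated as part of the feature (one
player), so the indicator's attribution is folded into its parent's row.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd

from .backend import PosteriorModel
from .propensity import PropensityResults

#: features extracted from instrumented gait analysis (vs physical exam)
GAIT_FEATURES = frozenset({
    "baseline_gdi", "hip_rotation_mean", "max_knee_flexion",
    "knee_flexion_rom",
})

EXACT_LIMIT = 12


class ExplanationError(ValueError):
    pass


@dataclass
class ShapleyProfile:
    """Additive decomposition of one limb's treatment probability."""

    treatment: str
    base_value: float                  # mean prediction over the background
    contributions: pd.Series           # signed, probability scale, per feature
    feature_values: pd.Series          # as displayed
    prediction: float                  # model probability for the limb
    std_errors: pd.Series | None = None  # Monte-Carlo s.e. (sampled method)
    method: str = "exact"

    @property
    def reconstruction(self) -> float:
        return float(self.base_value + self.contributions.sum())

    @property
    def residual(self) -> float:
        return self.reconstruction - self.prediction


@dataclass
class PartialDependenceCurve:
    feature: str
    grid: np.ndarray
    values: np.ndarray                 # mean marginal probability per grid value


def _posterior_mean_matrix(model: PosteriorModel, M: np.ndarray) -> np.ndarray:
    """Mean prediction on a raw design matrix without materialising the
    full draw matrix (memory: coalitions x background rows can be large)."""
    acc = np.zeros(len(M))
    for member in model.members:
        acc += model._member_predict(member, M)
    mean = acc / len(model.members)
    if model.task == "binary":
        mean = np.clip(mean, 1e-6, 1 - 1e-6)
    return mean


def _default_background(fit: PropensityResults, cap: int = 200) -> pd.DataFrame:
    bg = fit.balanced_train[fit.model.features]
    if len(bg) > cap:
        rng = np.random.default_rng(fit.seed)
        bg = bg.iloc[np.sort(rng.choice(len(bg), size=cap, replace=False))]
    return bg


def _coalition_values(predict_fn, x: np.ndarray, B: np.ndarray,
                      groups: list[list[int]],
                      subsets: np.ndarray) -> np.ndarray:
    """v(S) for each subset bitmask: mean prediction over background rows
    with the S-players' design columns replaced by the limb's values."""
    b = len(B)
    out = np.empty(len(subsets))
    chunk = max(1, 200_000 // max(b, 1))
    for start in range(0, len(subsets), chunk):
        batch = subsets[start:start + chunk]
        rows = np.tile(B, (len(batch), 1))
        for j, s in enumerate(batch):
            block = rows[j * b:(j + 1) * b]
            for i, cols in enumerate(groups):
                if s >> i & 1:
                    block[:, cols] = x[cols]
        preds = predict_fn(rows)
        out[start:start + chunk] = preds.reshape(len(batch), b).mean(axis=1)
    return out


def _exact_shapley(predict_fn, x: np.ndarray, B: np.ndarray,
                   groups: list[list[int]]) -> tuple[np.ndarray, float, float]:
    k = len(groups)
    subsets = np.arange(2**k, dtype=np.int64)
    v = _coalition_values(predict_fn, x, B, groups, subsets)
    # Shapley kernel weights by coalition size
    w = np.array([1.0 / (k * comb(k - 1, m)) for m in range(k)])
    phi = np.zeros(k)
    sizes = np.array([int(s).bit_count() for s in subsets])
    for i in range(k):
        without = subsets[(subsets >> i & 1) == 0]
        m = sizes[without]
        phi[i] = np.sum(w[m] * (v[without | (1 << i)] - v[without]))
    return phi, float(v[0]), float(v[-1])


def _sampled_shapley(predict_fn, x: np.ndarray, B: np.ndarray,
                     groups: list[list[int]], n_permutations: int,
                     seed: int) -> tuple[np.ndarray, np.ndarray, float, float]:
    k = len(groups)
    rng = np.random.default_rng(seed)
    contrib = np.zeros((n_permutations, k))
    base = float(_coalition_values(predict_fn, x, B, groups,
                                   np.array([0], dtype=np.int64))[0])
    full = float(_coalition_values(predict_fn, x, B, groups,
                                   np.array([2**k - 1], dtype=np.int64))[0])
    for p in range(n_permutations):
        order = rng.permutation(k)
        masks = np.empty(k, dtype=np.int64)
        s = 0
        for j, i in enumerate(order):
            s |= 1 << int(i)
            masks[j] = s
        vals = _coalition_values(predict_fn, x, B, groups, masks)
        prev = base
        for j, i in enumerate(order):
            contrib[p, i] = vals[j] - prev
            prev = vals[j]
    phi = contrib.mean(axis=0)
    se = contrib.std(axis=0, ddof=1) / np.sqrt(n_permutations)
    return phi, se, base, full


def shapley_values(fit: PropensityResults, limb: pd.DataFrame, *,
                   background: pd.DataFrame | None = None,
                   method: str = "auto", n_permutations: int = 100,
                   seed: int = 0) -> ShapleyProfile:
    """Explain one limb's treatment probability.

    ``limb`` is a one-row DataFrame carrying the model's features.
    ``method`` is "exact" (coalition enumeration), "sampled"
    (permutation estimator with standard errors), or "auto" (exact up to
    12 features).
    """
    if len(limb) != 1:
        raise ValueError("limb must be a single-row DataFrame")
    features = fit.model.features
    if background is None:
        background = _default_background(fit)
    if len(background) == 0:
        raise ExplanationError("background sample is empty")

    model = fit.posterior
    group_map = model.registry.column_groups()
    players = list(model.registry.columns)
    groups = [group_map[c] for c in players]
    x = model.registry.transform(limb[features])[0]
    B = model.registry.transform(background[features])

    def predict_fn(M):
        return _posterior_mean_matrix(model, M)

    if method == "auto":
        method = "exact" if len(players) <= EXACT_LIMIT else "sampled"
    if method == "exact":
        phi, base, full = _exact_shapley(predict_fn, x, B, groups)
        se = None
    elif method == "sampled":
        phi, se_arr, base, full = _sampled_shapley(
            predict_fn, x, B, groups, n_permutations, seed)
        se = pd.Series(se_arr, index=players)
    else:
        raise ValueError(f"unknown method {method!r}")

    return ShapleyProfile(
        treatment=fit.treatment,
        base_value=base,
        contributions=pd.Series(phi, index=players),
        feature_values=limb.iloc[0][features],
        prediction=full,
        std_errors=se,
        method=method,
    )


def _strength(s: float) -> str:
    a = abs(s)
    if a >= 0.05:
        return "strong"
    if a >= 0.01:
        return "weak"
    return "neutral"


def indication_table(profile: ShapleyProfile) -> pd.DataFrame:
    """Sorted display table: strongest indication first, with direction,
    magnitude bucket and data-source flag per feature."""
    df = pd.DataFrame({
        "feature": profile.contributions.index,
        "value": [profile.feature_values.get(f) for f in profile.contributions.index],
        "shapley": profile.contributions.to_numpy(),
    })
    df["direction"] = np.where(df["shapley"] > 0, "indication",
                               np.where(df["shapley"] < 0,
                                        "counter-indication", "neutral"))
    df["strength"] = df["shapley"].map(_strength)
    df["source"] = ["gait" if f in GAIT_FEATURES else "exam"
                    for f in df["feature"]]
    return df.sort_values("shapley", ascending=False,
                          kind="stable").reset_index(drop=True)


def partial_dependence(fit: PropensityResults, feature: str,
                       grid: np.ndarray | None = None, *,
                       background: pd.DataFrame | None = None,
                       n_grid: int = 20) -> PartialDependenceCurve:
    """Marginal effect of one feature: for each grid value, set the
    feature to that value for every background row and average the
    predicted probability."""
    if feature not in fit.model.features:
        raise KeyError(f"{feature!r} is not a model feature")
    if background is None:
        background = _default_background(fit)
    if grid is None:
        obs = pd.to_numeric(background[feature], errors="coerce").dropna()
        grid = np.linspace(obs.min(), obs.max(), n_grid)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    values = np.empty(len(grid))
    for i, g in enumerate(grid):
        bg = background.copy()
        bg[feature] = g
        values[i] = float(np.mean(fit.predict_mean(bg)))
    return PartialDependenceCurve(feature, grid, values)
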