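"""Pluggable posterior-model backend.

A single contract for probabilistic tabular models that return posterior
draws: fit a binary-probability or continuous-regression model, then ask
for ``n_draws`` samples per row.  The default engine is a bootstrap
ensemble of CART trees — a pseudo-posterior in which each bootstrap
member contributes draws, and (for regression) an out-of-bag residual
scale supplies the observation-noise component of predictive intervals.
A Bayesian additive regression trees adapter can be registered under the
same contract when such a library is installed.

Missing data are handled by missingness-indicator augmentation: every
feature column with any missing value gains a binary ``<name>__missing``
companion, and the original column is median-filled (mode-filled for
categoricals).  Rows are never deleted.  The indicator travels with its
parent feature as one "column group", which downstream explanation code
uses to fold indicator attributions into the parent feature's row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (HistGradientBoostingClassifier,
                              HistGradientBoostingRegressor)

PROB_CLIP = 1e-6


class FittingError(ValueError):
    pass


class PredictionError(ValueError):
    pass


@dataclass
class FeatureRegistry:
    """Fit-time feature schema: column order, categorical codings, fill
    values and missingness-indicator augmentation."""

    columns: list[str] = field(default_factory=list)
    fill_values: dict[str, float] = field(default_factory=dict)
    categorical_codes: dict[str, dict] = field(default_factory=dict)
    augmented: list[str] = field(default_factory=list)  # parents with indicator

    def fit(self, X: pd.DataFrame) -> "FeatureRegistry":
        self.columns = list(X.columns)
        for col in self.columns:
            s = X[col]
            if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
                cats = sorted(s.dropna().astype(str).unique())
                self.categorical_codes[col] = {c: i for i, c in enumerate(cats)}
                s = s.astype(str).map(self.categorical_codes[col])
                fill = s.mode().iloc[0] if s.notna().any() else 0.0
            else:
                s = pd.to_numeric(s, errors="coerce")
                fill = float(s.median()) if s.notna().any() else 0.0
            self.fill_values[col] = float(fill)
            if s.isna().any():
                self.augmented.append(col)
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        missing_cols = [c for c in self.columns if c not in X.columns]
        if missing_cols:
            raise PredictionError(
                f"registered feature column(s) absent from input: {missing_cols}")
        blocks = []
        for col in self.columns:
            s = X[col]
            if col in self.categorical_codes:
                s = s.astype(str).map(self.categorical_codes[col])
            s = pd.to_numeric(s, errors="coerce")
            isna = s.isna().to_numpy()
            blocks.append(np.where(isna, self.fill_values[col],
                                   s.to_numpy(dtype=float)))
            if col in self.augmented:
                blocks.append(isna.astype(float))
        return np.column_stack(blocks)

    def column_groups(self) -> dict[str, list[int]]:
        """Design-matrix column indices grouped by parent feature."""
        groups: dict[str, list[int]] = {}
        j = 0
        for col in self.columns:
            groups[col] = [j]
            j += 1
            if col in self.augmented:
                groups[col].append(j)
                j += 1
        return groups


@dataclass
class PosteriorDraws:
    """Matrix of posterior samples, one row per input limb."""

    values: np.ndarray           # (n_rows, n_draws)
    scale: str                   # "probability" | "outcome"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("draws must be 2-D (rows x draws)")
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite posterior draws")

    @property
    def n_draws(self) -> int:
        return self.values.shape[1]

    def mean(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def interval(self, level: float = 0.9) -> tuple[np.ndarray, np.ndarray]:
        """Equal-tailed interval at the given nominal level."""
        if not (0.0 < level < 1.0):
            raise ValueError("level must be in (0,1)")
        alpha = (1.0 - level) / 2.0
        lo = np.quantile(self.values, alpha, axis=1)
        hi = np.quantile(self.values, 1.0 - alpha, axis=1)
        return lo, hi


@dataclass
class PosteriorModel:
    """Fitted ensemble honouring the posterior-draw contract."""

    task: str                       # "binary" | "regression"
    registry: FeatureRegistry
    members: list
    sigma: float                    # obs-noise scale (regression; 0 for binary)
    n_draws: int
    seed: int
    eps: np.ndarray                 # fixed N(0,1) draw offsets, len n_draws
    backend: str = "bootstrap-trees"

    def predict_draws(self, X: pd.DataFrame) -> PosteriorDraws:
        extra = [c for c in X.columns if c not in self.registry.columns
                 and c not in ("patient_id", "side")]
        del extra  # extra columns are simply ignored
        M = self.registry.transform(X)
        return self._predict_matrix(M)

    def _predict_matrix(self, M: np.ndarray) -> PosteriorDraws:
        preds = np.column_stack([self._member_predict(m, M) for m in self.members])
        idx = np.arange(self.n_draws) % len(self.members)
        draws = preds[:, idx]
        if self.task == "regression":
            # member spread carries the bootstrap uncertainty of the fit;
            # sigma adds the residual observation-noise component (sized
            # so total predictive spread matches out-of-bag error)
            draws = draws + self.sigma * self.eps[None, :]
            return PosteriorDraws(draws, "outcome")
        draws = np.clip(draws, PROB_CLIP, 1.0 - PROB_CLIP)
        return PosteriorDraws(draws, "probability")

    def _member_predict(self, member, M: np.ndarray) -> np.ndarray:
        if self.task == "binary":
            proba = member.predict_proba(M)
            if proba.shape[1] == 1:
                return np.full(len(M), float(member.classes_[0]))
            return proba[:, list(member.classes_).index(1)]
        return member.predict(M)

    def predict_mean(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict_draws(X).mean()


def fit(X: pd.DataFrame, y, task: str, *, seed: int = 0,
        n_members: int = 15, n_draws: int = 1000,
        subsample_frac: float = 0.85,
        max_depth: int | None = None, min_samples_leaf: int | None = None,
        max_iter: int | None = None, learning_rate: float | None = None,
        backend: str = "bootstrap-trees") -> PosteriorModel:
    """Fit a posterior model.

    The pseudo-posterior is a resampling ensemble: ``n_members`` boosted
    tree models, each trained on an m-out-of-n subsample of the training
    rows (``subsample_frac`` without replacement), whose spread at a
    point carries the resampling uncertainty of the fit.  ``n_draws``
    posterior samples are produced per row at prediction time (default
    1000, matching the convention of reporting 1000 post-burn-in
    posterior iterations).
    """
    if backend == "bart-adapter":
        raise ImportError(
            "no Bayesian additive regression trees library is installed in "
            "this environment; use the default 'bootstrap-trees' backend")
    if backend != "bootstrap-trees":
        raise FittingError(f"unknown backend {backend!r}")
    if task not in ("binary", "regression"):
        raise FittingError(f"unknown task {task!r}")
    y = np.asarray(pd.to_numeric(pd.Series(y), errors="coerce"), dtype=float)
    if len(X) < 20:
        raise FittingError("need at least 20 rows to fit")
    if len(X) != len(y) or np.isnan(y).any():
        raise FittingError("target length mismatch or missing target values")
    if task == "binary":
        classes = np.unique(y)
        if not np.isin(classes, [0.0, 1.0]).all():
            raise FittingError("binary task requires a {0,1} target")
        if len(classes) < 2:
            raise FittingError("binary target contains a single class")

    if min_samples_leaf is None:
        min_samples_leaf = 10
    if max_iter is None:
        max_iter = 150 if task == "regression" else 100
    if learning_rate is None:
        learning_rate = 0.1 if task == "regression" else 0.12
    if not (0.0 < subsample_frac <= 1.0):
        raise FittingError("subsample_frac must be in (0,1]")

    registry = FeatureRegistry().fit(X)
    M = registry.transform(X)
    rng = np.random.default_rng(seed)
    n = len(M)
    m = max(min(n, 20), int(round(subsample_frac * n)))

    members = []
    boot_idx = []
    for _ in range(n_members):
        idx = rng.choice(n, m, replace=False)
        if task == "binary":
            while len(np.unique(y[idx])) < 2:   # degenerate subsample
                idx = rng.choice(n, m, replace=False)
            member = HistGradientBoostingClassifier(
                max_iter=max_iter, learning_rate=learning_rate,
                max_depth=max_depth, min_samples_leaf=min_samples_leaf,
                random_state=int(rng.integers(2**31)))
            member.fit(M[idx], y[idx].astype(int))
        else:
            member = HistGradientBoostingRegressor(
                max_iter=max_iter, learning_rate=learning_rate,
                max_depth=max_depth, min_samples_leaf=min_samples_leaf,
                random_state=int(rng.integers(2**31)))
            member.fit(M[idx], y[idx])
        boot_idx.append(idx)
        members.append(member)

    sigma = 0.0
    if task == "regression":
        # observation-noise scale: out-of-bag residual variance (the
        # total predictive error of the ensemble mean) minus the share
        # already expressed by the bootstrap member spread
        oob_sum = np.zeros(n)
        oob_cnt = np.zeros(n)
        all_preds = np.column_stack([m.predict(M) for m in members])
        for j, idx in enumerate(boot_idx):
            mask = np.ones(n, dtype=bool)
            mask[idx] = False
            if mask.any():
                oob_sum[mask] += all_preds[mask, j]
                oob_cnt[mask] += 1
        seen = oob_cnt > 0
        if seen.sum() >= 20:
            resid = y[seen] - oob_sum[seen] / oob_cnt[seen]
        else:
            resid = y - all_preds.mean(axis=1)
        oob_var = float(np.var(resid, ddof=1))
        member_var = float(np.mean(np.var(all_preds, axis=1, ddof=1)))
        sigma = float(np.sqrt(max(oob_var - member_var, 0.0)))

    eps = np.random.default_rng(np.random.SeedSequence([seed, 0xE95])).normal(
        size=n_draws)
    # standardise the fixed noise sample so posterior means carry no
    # Monte-Carlo offset and sigma is reproduced exactly
    eps = (eps - eps.mean()) / eps.std()
    return PosteriorModel(task=task, registry=registry, members=members,
                          sigma=sigma, n_draws=n_draws, seed=seed, eps=eps)
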