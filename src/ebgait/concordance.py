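"""Concordance between administered treatments and the modeled standard
of practice, and the concordance-versus-outcome trend analysis.

For a treated limb the surgery probability p is rescaled to
rho* = 2(p - 0.5) in [-1, 1] and then signed-squared,
rho** = sign(rho*) * (rho*)^2, which amplifies differences at the
extremes while compressing moderate probabilities.  The per-treatment
concordance kappa equals rho** if the surgery was administered and 0
otherwise; the overall concordance K is the sum of the 12 kappas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .cohort import TREATMENT_NAMES


class TrendError(ValueError):
    pass


def rho_star(p):
    """Rescale a probability to [-1, 1]."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probability outside [0,1]")
    return 2.0 * (p - 0.5)


def rho_star_star(p):
    """Signed square of the rescaled probability."""
    r = rho_star(p)
    return np.sign(r) * r**2


def treatment_concordance(p, treated):
    """kappa = sign(2p-1) * (2p-1)^2 if treated else 0."""
    r2 = rho_star_star(p)
    treated = np.asarray(treated, dtype=float)
    if np.any((treated != 0) & (treated != 1)):
        raise ValueError("treated must be 0 or 1")
    out = r2 * treated
    return float(out) if np.ndim(out) == 0 else out


def overall_concordance(kappas) -> float:
    """K = sum of the per-treatment concordances (expects exactly the
    configured treatment set when given a mapping)."""
    if isinstance(kappas, dict):
        missing = [t for t in TREATMENT_NAMES if t not in kappas]
        if missing:
            raise KeyError(f"missing treatment entries: {missing}")
        kappas = [kappas[t] for t in TREATMENT_NAMES]
    return float(np.sum(kappas))


@dataclass
class ConcordanceScore:
    """Per-limb concordance decomposition."""

    p_treat: pd.Series
    kappa: pd.Series

    @property
    def rho_star(self) -> pd.Series:
        return 2.0 * (self.p_treat - 0.5)

    @property
    def rho_star_star(self) -> pd.Series:
        r = self.rho_star
        return np.sign(r) * r**2

    @property
    def overall(self) -> float:
        return float(self.kappa.sum())


def cohort_concordance(table: pd.DataFrame,
                       fits: dict) -> pd.DataFrame:
    """Per-limb kappa for each fitted surgery plus the overall K.

    ``fits`` maps treatment name -> PropensityResults; the posterior
    mean probability enters the concordance formula.
    """
    out = {}
    for name, fit in fits.items():
        p = fit.predict_mean(table)
        out[f"kappa_{name}"] = treatment_concordance(
            p, table[name].to_numpy())
    df = pd.DataFrame(out, index=table.index)
    df["K"] = df.sum(axis=1)
    return df


@dataclass
class TrendCurve:
    grid: np.ndarray
    fitted: np.ndarray
    bin_centers: np.ndarray
    bin_means: np.ndarray
    span: float


def concordance_trend(x, y, span: float = 0.7, *, n_grid: int = 50,
                      n_bins: int = 5) -> TrendCurve:
    """Locally weighted (tricube, degree-1) trend of outcome change
    against concordance, evaluated on an even grid, plus binned means as
    a smoother-free summary."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 20:
        raise TrendError("need equal-length x and y with at least 20 points")
    if np.ptp(x) == 0:
        raise TrendError("trend undefined: all x values identical")
    grid = np.linspace(x.min(), x.max(), n_grid)
    fitted = lowess(y, x, frac=span, it=1, xvals=grid)
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    edges[0] -= 1e-9
    which = np.clip(np.searchsorted(edges, x, side="left") - 1, 0, n_bins - 1)
    centers = np.array([x[which == b].mean() if np.any(which == b) else np.nan
                        for b in range(n_bins)])
    means = np.array([y[which == b].mean() if np.any(which == b) else np.nan
                      for b in range(n_bins)])
    return TrendCurve(grid, fitted, centers, means, span)


def roughness(curve: TrendCurve) -> float:
    """Sum of squared second differences of the fitted curve."""
    return float(np.sum(np.diff(curve.fitted, 2) ** 2))
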