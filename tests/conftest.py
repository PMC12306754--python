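"""Shared fixtures: a small cohort for fast unit tests and a
mid-sized cohort with fitted models reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import ebgait
from ebgait import outcomes as om
from ebgait import propensity as pm


@pytest.fixture(scope="session")
def small_cohort():
    table, truth = ebgait.generate_cohort(
        ebgait.GeneratorConfig(n_limbs=800, seed=42))
    return table, truth


@pytest.fixture(scope="session")
def cohort3k():
    table, truth = ebgait.generate_cohort(
        ebgait.GeneratorConfig(n_limbs=3000, seed=7))
    train, test = pm.split_train_test(table, 0.7, seed=7)
    return {"table": table, "truth": truth, "train": train, "test": test}


@pytest.fixture(scope="session")
def gdi_fit(cohort3k):
    return om.OutcomeModel(cohort3k["train"], "delta_gdi").fit(seed=7)


@pytest.fixture(scope="session")
def fdo_fit(cohort3k):
    return pm.PropensityModel(
        cohort3k["train"], "femoral_derotation_osteotomy").fit(seed=7)


@pytest.fixture(scope="session")
def calf_fit(cohort3k):
    return pm.PropensityModel(cohort3k["train"], "calf_lengthening").fit(seed=7)


class StubPropensityFit:
    """Duck-typed propensity fit returning fixed probabilities; used to
    test metric and report plumbing independently of any model engine."""

    def __init__(self, treatment, probs, width=0.0, n_draws=200, seed=0):
        self.treatment = treatment
        self.probs = np.asarray(probs, dtype=float)
        self.width = width
        self.n_draws = n_draws
        self.seed = seed

    def predict_draws(self, X):
        from ebgait.backend import PosteriorDraws
        base = np.tile(self.probs[: len(X), None], (1, self.n_draws))
        if self.width:
            spread = np.linspace(-self.width / 2, self.width / 2, self.n_draws)
            base = np.clip(base + spread[None, :], 1e-6, 1 - 1e-6)
        return PosteriorDraws(base, "probability")

    def predict_mean(self, X):
        return self.predict_draws(X).mean()


@pytest.fixture
def stub_fit_factory():
    return StubPropensityFit
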