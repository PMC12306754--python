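"""Shapley explanations: exactness against a brute-force coalition
oracle, the efficiency/null-player/symmetry axioms, the indication table
and partial-dependence recovery of generative shapes."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ebgait import explain as ex
from ebgait import propensity as pm
from ebgait.explain import (ExplanationError, ShapleyProfile,
                            indication_table, partial_dependence,
                            shapley_values)

FEATS3 = ["femoral_anteversion", "hip_rotation_mean", "age"]


@pytest.fixture(scope="module")
def fit3(cohort3k):
    return pm.PropensityModel(
        cohort3k["train"], "femoral_derotation_osteotomy", FEATS3).fit(
        seed=5, n_members=8, max_iter=50)


def brute_force_shapley(model, x, B, groups):
    """Independent oracle: direct per-feature coalition enumeration with
    factorial weights."""
    def v(S):
        rows = B.copy()
        for i in S:
            rows[:, groups[i]] = x[groups[i]]
        return float(ex._posterior_mean_matrix(model, rows).mean())

    k = len(groups)
    phi = np.zeros(k)
    for i in range(k):
        others = [j for j in range(k) if j != i]
        for r in range(k):
            for S in itertools.combinations(others, r):
                w = (math.factorial(len(S)) * math.factorial(k - len(S) - 1)
                     / math.factorial(k))
                phi[i] += w * (v(set(S) | {i}) - v(set(S)))
    return phi


class TestExactShapley:
    def test_matches_brute_force_on_three_features(self, fit3, cohort3k):
        limb = cohort3k["test"].iloc[[3]]
        bg = ex._default_background(fit3, cap=30)
        prof = shapley_values(fit3, limb, background=bg, method="exact")
        model = fit3.posterior
        x = model.registry.transform(limb[FEATS3])[0]
        B = model.registry.transform(bg[FEATS3])
        groups = list(model.registry.column_groups().values())
        oracle = brute_force_shapley(model, x, B, groups)
        assert np.abs(prof.contributions.to_numpy() - oracle).max() < 1e-9

    def test_efficiency_axiom_exact(self, fit3, cohort3k):
        for i in (0, 11, 47):
            prof = shapley_values(fit3, cohort3k["test"].iloc[[i]])
            assert abs(prof.residual) < 1e-6
            assert prof.prediction == pytest.approx(
                float(fit3.predict_mean(cohort3k["test"].iloc[[i]])[0]), abs=1e-9)

    def test_null_player_gets_zero(self, cohort3k):
        # constant column carries no signal; its contribution must vanish
        train = cohort3k["train"].copy()
        train["inert"] = 1.0
        fit = pm.PropensityModel(
            train, "femoral_derotation_osteotomy",
            FEATS3 + ["inert"]).fit(seed=6, n_members=6, max_iter=40)
        limb = cohort3k["test"].iloc[[0]].assign(inert=1.0)
        prof = shapley_values(fit, limb)
        assert abs(prof.contributions["inert"]) < 1e-12

    def test_symmetry_axiom_for_exchangeable_features(self):
        # a value function symmetric in two columns must yield equal
        # contributions; probed directly at the engine level because
        # fitted trees break ties between duplicated columns arbitrarily
        rng = np.random.default_rng(7)
        B = rng.normal(size=(40, 3))
        B[:, 1] = B[:, 0]               # duplicated background column
        x = np.array([1.3, 1.3, -0.4])
        groups = [[0], [1], [2]]

        def predict_fn(M):
            return np.tanh(M[:, 0] + M[:, 1]) + 0.5 * M[:, 2]

        phi, base, full = ex._exact_shapley(predict_fn, x, B, groups)
        assert phi[0] == pytest.approx(phi[1], abs=1e-12)
        assert base + phi.sum() == pytest.approx(full, abs=1e-12)

    def test_empty_background_errors(self, fit3, cohort3k):
        with pytest.raises(ExplanationError):
            shapley_values(fit3, cohort3k["test"].iloc[[0]],
                           background=cohort3k["train"][FEATS3].iloc[:0])


class TestSampledShapley:
    def test_agrees_with_exact_within_three_se(self, fit3, cohort3k):
        limb = cohort3k["test"].iloc[[9]]
        bg = ex._default_background(fit3, cap=30)
        exact = shapley_values(fit3, limb, background=bg, method="exact")
        sampled = shapley_values(fit3, limb, background=bg, method="sampled",
                                 n_permutations=60, seed=1)
        diff = (sampled.contributions - exact.contributions).abs()
        tol = 3 * sampled.std_errors + 1e-9
        assert (diff <= tol).all()

    def test_permutation_estimator_additivity(self, fit3, cohort3k):
        # the permutation chain telescopes, so efficiency holds exactly
        prof = shapley_values(fit3, cohort3k["test"].iloc[[2]],
                              method="sampled", n_permutations=10, seed=2)
        assert abs(prof.residual) < 1e-9


class TestIndicationTable:
    def _profile(self, contribs):
        s = pd.Series(contribs)
        return ShapleyProfile(
            treatment="calf_lengthening", base_value=0.5, contributions=s,
            feature_values=pd.Series({k: 0.0 for k in s.index}),
            prediction=0.5 + s.sum())

    def test_sorted_strongest_indication_first(self):
        table = indication_table(self._profile(
            {"a": 0.11, "b": -0.02, "c": 0.03}))
        assert list(table["shapley"]) == [0.11, 0.03, -0.02]
        assert list(table["direction"]) == [
            "indication", "indication", "counter-indication"]
        assert list(table["strength"]) == ["strong", "weak", "weak"]

    def test_all_zero_contributions_stable_and_neutral(self):
        table = indication_table(self._profile({"a": 0.0, "b": 0.0, "c": 0.0}))
        assert list(table["feature"]) == ["a", "b", "c"]
        assert (table["direction"] == "neutral").all()
        assert (table["strength"] == "neutral").all()

    def test_gait_source_flagged(self):
        table = indication_table(self._profile(
            {"baseline_gdi": 0.02, "age": 0.01}))
        src = dict(zip(table["feature"], table["source"]))
        assert src == {"baseline_gdi": "gait", "age": "exam"}


class TestPartialDependence:
    def test_flat_for_intercept_only_model(self, cohort3k):
        train = cohort3k["train"].copy()
        train["const"] = 0.0
        fit = pm.PropensityModel(train, "calf_lengthening", ["const"]).fit(
            seed=8, n_members=5, max_iter=20)
        curve = partial_dependence(fit, "const", np.array([-1.0, 0.0, 1.0]))
        assert np.ptp(curve.values) < 1e-9

    def test_recovers_u_shaped_torsion_policy(self, cohort3k):
        fit = pm.PropensityModel(
            cohort3k["train"], "tibial_derotation_osteotomy").fit(seed=9)
        grid = np.linspace(-15.0, 45.0, 13)          # 5-degree steps
        curve = partial_dependence(fit, "tibial_torsion", grid)
        g_min = grid[int(np.argmin(curve.values))]
        assert abs(g_min - 15.0) <= 5.0
        assert curve.values[0] > curve.values.min()
        assert curve.values[-1] > curve.values.min()

    def test_monotone_era_trend_recovered(self, cohort3k):
        fit = pm.PropensityModel(cohort3k["train"], "rectus_transfer").fit(
            seed=10)
        curve = partial_dependence(fit, "era", np.linspace(1994, 2024, 11))
        inversions = int((np.diff(curve.values) > 0).sum())
        assert inversions <= 1
        assert curve.values[-1] < curve.values[0]

    def test_grid_validation(self, cohort3k, fit3):
        with pytest.raises(ValueError):
            partial_dependence(fit3, "age", np.array([]))
        with pytest.raises(ValueError):
            partial_dependence(fit3, "age", np.array([2.0, 1.0]))
        with pytest.raises(KeyError):
            partial_dependence(fit3, "not_a_feature")
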