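"""Generator: demographics, prevalences, policies, missingness, truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

import ebgait
from ebgait.cohort import (FEATURE_MEANS, TREATMENT_NAMES, ConfigurationError,
                           GeneratorConfig, MissingnessSpec, NonlinearTerm,
                           OutcomeSpec, TreatmentSpec, apply_missingness,
                           default_treatments, generate_cohort,
                           true_policy_probability)


class TestConfigValidation:
    def test_prevalence_target_bounds(self):
        with pytest.raises(ConfigurationError):
            TreatmentSpec("calf_lengthening", 0.0)
        with pytest.raises(ConfigurationError):
            TreatmentSpec("calf_lengthening", 0.6)

    def test_invalid_fractions_and_sizes(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(n_limbs=1)
        with pytest.raises(ConfigurationError):
            GeneratorConfig(n_limbs=100, female_frac=1.2)

    def test_outcome_effect_ordering(self):
        with pytest.raises(ConfigurationError):
            OutcomeSpec("delta_gdi", "baseline_gdi", (), 1.0, 2.0, 1.0)


class TestGenerateCohort:
    def test_bit_reproducible_given_seed(self):
        cfg = GeneratorConfig(n_limbs=300, seed=13)
        t1, tr1 = generate_cohort(cfg)
        t2, tr2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(tr1.policy_probability,
                                      tr2.policy_probability)
        pd.testing.assert_frame_equal(tr1.natural_delta, tr2.natural_delta)

    def test_demographics_match_cohort_descriptors(self):
        table, _ = generate_cohort(GeneratorConfig(n_limbs=5000, seed=1))
        assert abs(table["age"].mean() - 8.9) < 0.2
        assert abs(table["age"].std() - 3.3) < 0.2
        assert abs(table["female"].mean() - 0.42) < 0.03
        assert abs((table["dx_category"] == 0).mean() - 0.84) < 0.03

    def test_adductor_release_prevalence_near_target(self):
        # binomial bound around the 4% target at n=5000
        table, _ = generate_cohort(GeneratorConfig(n_limbs=5000, seed=2))
        assert 0.028 <= table["adductor_release"].mean() <= 0.052

    def test_all_prevalences_converge_to_targets(self):
        table, _ = generate_cohort(GeneratorConfig(n_limbs=20000, seed=3))
        for spec in default_treatments():
            realized = table[spec.name].mean()
            assert abs(realized / spec.prevalence_target - 1.0) < 0.10, spec.name

    def test_schema_invariants(self, small_cohort):
        table, _ = small_cohort
        assert table.index.is_unique
        for t in TREATMENT_NAMES:
            assert set(table[t].unique()) <= {0, 1}
        for c in table.columns:
            if c.startswith("delta_"):
                assert table[c].notna().any()

    def test_threshold_assignment_is_degenerate_policy_limit(self):
        cfg = GeneratorConfig(n_limbs=1000, seed=4, clinician_noise_sd=0.0,
                              assignment="threshold")
        table, truth = generate_cohort(cfg)
        for t in TREATMENT_NAMES:
            expected = (truth.policy_probability[t] > 0.5).astype(int)
            assert (table[t] == expected).all(), t

    def test_indication_strength_orders_true_effects(self, small_cohort):
        # limbs most indicated for derotation benefit most, by construction
        _, truth = small_cohort
        pi = truth.policy_probability["femoral_derotation_osteotomy"]
        eff = truth.effects["delta_gdi"]["femoral_derotation_osteotomy"]
        top = eff[pi >= pi.quantile(0.75)].mean()
        bottom = eff[pi <= pi.quantile(0.25)].mean()
        assert top > bottom

    def test_bilateral_limbs_share_patient(self, small_cohort):
        table, _ = small_cohort
        sizes = table.groupby("patient_id").size()
        assert sizes.max() <= 2
        # limb severity correlates within patient via shared latent
        both = table[table.groupby("patient_id")["side"].transform("size") == 2]
        wide = both.pivot_table(index="patient_id", columns="side",
                                values="baseline_gdi")
        # severity explains half the GDI variance and siblings share half
        # their severity, so the feature-level correlation is ~0.25
        r = wide["L"].corr(wide["R"])
        assert r > 0.1


class TestPolicyProbability:
    def test_zero_coefficients_return_intercept_implied_target(self):
        spec = TreatmentSpec("calf_lengthening", 0.18)
        feats = pd.DataFrame({"age": [5.0, 10.0, 15.0]})
        p = true_policy_probability(feats, spec)
        assert np.allclose(p, 0.18)

    def test_u_shaped_torsion_minimum_at_typical_value(self):
        spec = TreatmentSpec(
            "tibial_derotation_osteotomy", 0.16,
            nonlinear_terms=(NonlinearTerm("tibial_torsion", "quadratic",
                                           center=15.0, scale=10.0, weight=1.4),))
        grid = pd.DataFrame({"tibial_torsion": np.linspace(-25.0, 55.0, 17)})
        p = true_policy_probability(grid, spec)
        i_min = int(np.argmin(p))
        assert grid["tibial_torsion"].iloc[i_min] == 15.0
        assert p[0] > p[i_min] and p[-1] > p[i_min]

    def test_hand_evaluated_logit(self):
        # independent spreadsheet-style evaluation of the logistic form
        spec = TreatmentSpec("calf_lengthening", 0.2,
                             {"age": 0.1, "ankle_dorsiflexion_rom": -0.15},
                             intercept=-1.0)
        feats = pd.DataFrame({"age": [12.0], "ankle_dorsiflexion_rom": [4.0]})
        expected = expit(-1.0 + 0.1 * (12.0 - FEATURE_MEANS["age"])
                         - 0.15 * (4.0 - FEATURE_MEANS["ankle_dorsiflexion_rom"]))
        assert np.allclose(true_policy_probability(feats, spec), expected)

    def test_missing_value_contributes_prior_mean(self):
        spec = TreatmentSpec("calf_lengthening", 0.2,
                             {"ankle_dorsiflexion_rom": -0.15}, intercept=0.0)
        feats = pd.DataFrame({"ankle_dorsiflexion_rom": [np.nan]})
        assert np.allclose(true_policy_probability(feats, spec), 0.5)

    def test_unknown_feature_errors(self):
        spec = TreatmentSpec("calf_lengthening", 0.2, {"nope": 1.0})
        with pytest.raises(ConfigurationError):
            true_policy_probability(pd.DataFrame({"age": [5.0]}), spec)


class TestMissingness:
    def test_rate_zero_leaves_table_unchanged(self, small_cohort):
        table, _ = small_cohort
        out = apply_missingness(table, MissingnessSpec(rates={"age": 0.0}),
                                seed=0)
        pd.testing.assert_frame_equal(out, table)

    def test_mcar_rate_recovered(self):
        cfg = GeneratorConfig(n_limbs=5000, seed=5,
                              missingness=MissingnessSpec())
        table, _ = generate_cohort(cfg)
        out = apply_missingness(
            table, MissingnessSpec(rates={"knee_flexion_rom": 0.1}), seed=5)
        assert 0.08 <= out["knee_flexion_rom"].isna().mean() <= 0.12

    def test_severity_dependent_masking_biases_observed_mean(self):
        # contracted (low-ROM) limbs go missing, so observed mean is high
        cfg = GeneratorConfig(n_limbs=5000, seed=6,
                              missingness=MissingnessSpec())
        table, _ = generate_cohort(cfg)
        spec = MissingnessSpec(rates={"ankle_dorsiflexion_rom": 0.3},
                               mechanisms={"ankle_dorsiflexion_rom": "severity"})
        out = apply_missingness(table, spec, seed=6)
        masked = out["ankle_dorsiflexion_rom"]
        assert masked.isna().mean() > 0.15
        assert masked.mean() > table["ankle_dorsiflexion_rom"].mean()

    def test_masking_treatment_column_refused(self, small_cohort):
        table, _ = small_cohort
        with pytest.raises(ConfigurationError):
            apply_missingness(table,
                              MissingnessSpec(rates={"calf_lengthening": 0.1}),
                              seed=0)


def test_truth_json_roundtrip(tmp_path, small_cohort):
    _, truth = small_cohort
    path = tmp_path / "truth.json"
    truth.to_json(path)
    back = ebgait.SyntheticTruth.from_json(path)
    pd.testing.assert_frame_equal(
        back.policy_probability, truth.policy_probability, check_exact=False)
    decisions = truth.policy_probability.iloc[:50].round().astype(int)
    a = truth.potential_delta("delta_gdi", decisions)
    b = back.potential_delta("delta_gdi", decisions)
    assert np.allclose(a, b)
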