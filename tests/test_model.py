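import copy

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uc_mbma.data import ArmDescriptor, CovariateProfile
from uc_mbma.model import (CovariateEffectSpec, DrugEffectSpec, ModelSpec,
                           PlaceboSpec, apply_covariate, drug_effect,
                           inverse_logit, load_model, logit, placebo_effect,
                           rcs_basis, response_probability, save_model)

REMISSION_PLACEBO = PlaceboSpec(form="exponential", B=-39.26, A=37.04,
                                k_pbo=0.66)


class TestLink:
    def test_symmetry_point(self):
        assert inverse_logit(0.0) == pytest.approx(0.5)

    def test_asymptotic_remission_placebo(self):
        # B + A = -2.22 on the logit scale ~ 9.8% responders
        assert inverse_logit(-2.22) == pytest.approx(0.0980, abs=5e-4)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_inverse_pair(self, p):
        assert float(inverse_logit(logit(p))) == pytest.approx(p, rel=1e-9)

    def test_monotone(self):
        x = np.linspace(-30, 30, 201)
        assert np.all(np.diff(inverse_logit(x)) > 0)


class TestPlaceboEffect:
    def test_intercept_at_time_zero(self):
        assert placebo_effect(0.0, REMISSION_PLACEBO) == pytest.approx(-39.26)

    def test_week8_worked_example(self):
        e0 = float(placebo_effect(8.0, REMISSION_PLACEBO))
        assert e0 == pytest.approx(-2.41, abs=0.01)
        assert float(inverse_logit(e0)) == pytest.approx(0.082, abs=0.001)

    def test_converges_to_asymptote(self):
        assert placebo_effect(1e4, REMISSION_PLACEBO) == pytest.approx(-2.22)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            placebo_effect(-1.0, REMISSION_PLACEBO)

    def test_strictly_increasing_when_A_positive(self):
        t = np.linspace(0, 60, 500)
        p = inverse_logit(placebo_effect(t, REMISSION_PLACEBO))
        assert np.all(np.diff(p) >= 0)
        early = np.linspace(0, 20, 100)
        assert np.all(
            np.diff(inverse_logit(placebo_effect(early, REMISSION_PLACEBO))) > 0
        )

    def test_rcs_placebo_continuous(self):
        spec = PlaceboSpec(form="rcs", knots=[2, 8, 24],
                           spline_coeffs=[-1.6, 0.09, -0.13])
        t = np.linspace(0, 60, 2000)
        e0 = placebo_effect(t, spec)
        assert np.all(np.abs(np.diff(e0)) < 0.05)


class TestRcsBasis:
    def test_too_few_knots(self):
        with pytest.raises(ValueError):
            rcs_basis(5.0, [2, 8])

    def test_dimension(self):
        assert rcs_basis(5.0, [2, 8, 24]).shape == (2,)
        assert rcs_basis(np.arange(4.0), [1, 2, 3, 4]).shape == (4, 3)

    @pytest.mark.parametrize("t0,expect_zero", [(1.0, True), (20.0, True),
                                                (6.0, False)])
    def test_linear_tails_by_second_derivative(self, t0, expect_zero):
        knots = [2.0, 6.0, 14.0]
        h = 1e-3
        vals = np.stack([rcs_basis(t0 + d, knots) for d in (-h, 0.0, h)])
        second = (vals[0] - 2 * vals[1] + vals[2]) / h**2
        if expect_zero:
            assert np.all(np.abs(second) < 1e-4)
        else:
            assert np.any(np.abs(second) > 1e-2)


class TestDrugEffect:
    def test_flat_emax_dose_independent(self):
        spec = DrugEffectSpec("infliximab", Emax=1.48)
        for dose in (100.0, 350.0, 700.0):
            for t in (2.0, 8.0, 52.0):
                assert drug_effect("infliximab", dose, t, spec) == \
                    pytest.approx(1.48)

    def test_linear_slope_times_dose(self):
        spec = DrugEffectSpec("filgotinib", dose_model="linear",
                              slope=6.87e-3)
        assert drug_effect("filgotinib", 200.0, 8.0, spec) == \
            pytest.approx(1.374)
        # exact proportionality on the logit scale
        e100 = float(drug_effect("filgotinib", 100.0, 8.0, spec))
        e200 = float(drug_effect("filgotinib", 200.0, 8.0, spec))
        assert e200 == pytest.approx(2 * e100)

    def test_onset_factor_ninety_percent_point(self):
        k = 0.103
        spec = DrugEffectSpec("tofacitinib", Emax=1.0, k_onset=k)
        t90 = np.log(10.0) / k
        assert t90 == pytest.approx(22.36, abs=0.01)
        assert drug_effect("tofacitinib", 10.0, t90, spec) == \
            pytest.approx(0.9, abs=1e-9)

    def test_placebo_and_zero_dose_give_zero(self):
        spec = DrugEffectSpec("etrasimod", dose_model="linear", slope=0.544)
        assert drug_effect("placebo", 0.0, 8.0, spec) == 0.0
        assert drug_effect("etrasimod", 0.0, 8.0, spec) == 0.0

    def test_regimen_override_consulted_first(self):
        spec = DrugEffectSpec("upadacitinib", Emax=0.234,
                              regimen_overrides={"45mg": 2.90})
        assert drug_effect("upadacitinib", 45.0, 8.0, spec,
                           regimen_tag="45mg") == pytest.approx(2.90)
        assert drug_effect("upadacitinib", 30.0, 8.0, spec) == \
            pytest.approx(0.234)

    def test_sigmoid_emax_with_hill_one(self):
        spec = DrugEffectSpec("golimumab", dose_model="emax", Emax=2.0,
                              ED50=100.0)
        assert drug_effect("golimumab", 100.0, 8.0, spec) == pytest.approx(1.0)


class TestApplyCovariate:
    def test_reference_point_identity(self):
        for form in ("additive", "power"):
            eff = CovariateEffectSpec("duration", "drug_emax", form, 0.7, 7.53)
            assert apply_covariate(1.48, 7.53, eff) == pytest.approx(1.48)

    def test_additive_duration_on_asymptote(self):
        eff = CovariateEffectSpec("duration", "placebo_asymptote", "additive",
                                  0.695, 7.53)
        assert apply_covariate(37.04, 8.53, eff) == pytest.approx(37.735)

    def test_power_zero_theta_identity(self):
        eff = CovariateEffectSpec("duration", "drug_emax", "power", 0.0, 7.53)
        assert apply_covariate(1.48, 3.0, eff) == pytest.approx(1.48)

    def test_power_rejects_nonpositive_value(self):
        eff = CovariateEffectSpec("duration", "drug_emax", "power", 0.5, 7.53)
        with pytest.raises(ValueError):
            apply_covariate(1.48, 0.0, eff)


class TestResponseProbability:
    def _arm(self, drug="placebo", dose=0.0, duration=7.53):
        covs = CovariateProfile(age=41.2, weight=70, male_pct=60,
                                duration=duration, prior_tnf_pct=22.4,
                                steroid_pct=46.0)
        return ArmDescriptor("T1", "a1", drug, dose, covariates=covs)

    def _model(self):
        return ModelSpec(
            endpoint="remission",
            placebo=copy.deepcopy(REMISSION_PLACEBO),
            drugs=[DrugEffectSpec("infliximab", Emax=1.48)],
        )

    def test_placebo_arm_is_link_of_e0(self):
        m = self._model()
        p = response_probability(self._arm(), 8.0, m, eta=0.3)
        e0 = placebo_effect(8.0, m.placebo)
        assert float(p) == pytest.approx(float(inverse_logit(e0 + 0.3)))

    def test_infliximab_week8_composition(self):
        m = self._model()
        p = response_probability(self._arm("infliximab", 350.0), 8.0, m)
        assert float(p) == pytest.approx(0.283, abs=0.002)

    def test_eta_monotonicity(self):
        m = self._model()
        p0 = response_probability(self._arm(), 8.0, m, eta=0.0)
        p1 = response_probability(self._arm(), 8.0, m, eta=1.0)
        assert p1 > p0

    def test_probability_in_unit_interval_over_time(self):
        m = self._model()
        t = np.linspace(0, 60, 300)
        p = response_probability(self._arm("infliximab", 350.0), t, m)
        assert np.all((p > 0) & (p < 1))


class TestCovariateReferenceIdentity:
    @pytest.mark.parametrize("endpoint", ["remission", "response",
                                          "endoscopic"])
    def test_reference_covariates_reproduce_unadjusted_model(
        self, endpoint, request
    ):
        model = request.getfixturevalue(f"{endpoint}_model")
        ref = {e.covariate: e.cov_mean for e in model.covariate_effects}
        covs = CovariateProfile(
            age=ref.get("age", 41.2), weight=70.0, male_pct=60.0,
            duration=ref.get("duration", 7.53),
            prior_tnf_pct=ref.get("prior_tnf_pct", 22.4),
            steroid_pct=ref.get("steroid_pct", 46.0),
        )
        bare = copy.deepcopy(model)
        bare.covariate_effects = []
        t = np.linspace(0.0, 60.0, 61)
        for drug in ("placebo", "infliximab", "upadacitinib"):
            arm_adj = ArmDescriptor("T", "a", drug,
                                    0.0 if drug == "placebo" else 30.0,
                                    covariates=covs)
            p_adj = response_probability(arm_adj, t, model)
            p_bare = response_probability(arm_adj, t, bare)
            np.testing.assert_allclose(p_adj, p_bare, rtol=0, atol=1e-15)


class TestSerialization:
    def test_yaml_round_trip(self, tmp_path, response_model):
        path = tmp_path / "m.yaml"
        save_model(response_model, path)
        loaded = load_model(path)
        assert loaded == response_model

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PlaceboSpec(form="exponential", B=0.0, A=1.0, k_pbo=-1).validate()
        with pytest.raises(ValueError):
            PlaceboSpec(form="rcs", knots=[1, 2], spline_coeffs=[0, 0]).validate()
        with pytest.raises(ValueError):
            ModelSpec("remission", REMISSION_PLACEBO, omega2=-1).validate()
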