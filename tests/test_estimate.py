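import copy
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.special import expit
from scipy.stats import norm

from uc_mbma.data import ArmDescriptor, CovariateProfile, ObservationRecord
from uc_mbma.estimate import (FitResult, ObjectiveConfig, binomial_loglik,
                              compare_models, fit_model, marginal_loglik,
                              stepwise_covariates,
                              weighted_normal_objective)
from uc_mbma.model import (CovariateEffectSpec, DrugEffectSpec, ModelSpec,
                           PlaceboSpec)
from uc_mbma.synthetic import generate_dataset

from conftest import make_small_design, make_small_truth


def _flat_model(p=0.5, omega2=0.0, sigma=1.0, autocorr="none", rho=0.0):
    """Model with constant response probability p at every time."""
    b = float(np.log(p) - np.log1p(-p))
    return ModelSpec(
        endpoint="remission",
        placebo=PlaceboSpec(form="polynomial", poly_coeffs=[b]),
        omega2=omega2, sigma=sigma, autocorr=autocorr, rho=rho,
    )


def _arm(arm_id="a1", drug="placebo", dose=0.0):
    return ArmDescriptor("T1", arm_id, drug, dose,
                         covariates=CovariateProfile())


def _rec(arm_id="a1", t=8.0, N=10, n=5):
    return ObservationRecord("T1", arm_id, "remission", t, N, n)


class TestBinomialLoglik:
    def test_closed_form_half(self):
        # N=10, n=5, P=0.5: log C(10,5) - 10 log 2
        ll = binomial_loglik([_rec()], [_arm()], _flat_model(0.5),
                             {("T1", "a1"): 0.0})
        assert ll == pytest.approx(math.log(252) - 10 * math.log(2), abs=1e-9)
        assert ll == pytest.approx(-1.4020, abs=1e-4)

    def test_zero_responders_vanishing_probability(self):
        ll = binomial_loglik([_rec(N=10, n=0)], [_arm()], _flat_model(1e-7),
                             {("T1", "a1"): 0.0})
        assert ll == pytest.approx(0.0, abs=1e-5)

    def test_matches_exhaustive_enumeration(self):
        # brute force: enumerate all Bernoulli outcome vectors for N <= 5
        model = _flat_model(0.3)
        records = [_rec("a1", 4.0, 4, 1), _rec("a1", 8.0, 5, 3),
                   _rec("a2", 8.0, 3, 0)]
        arms = [_arm("a1"), _arm("a2")]
        p = 0.3
        total = 0.0
        for r in records:
            mass = sum(
                math.prod(p if x else 1 - p for x in outcome)
                for outcome in itertools.product([0, 1], repeat=r.n_total)
                if sum(outcome) == r.n_response
            )
            total += math.log(mass)
        ll = binomial_loglik(records, arms, model,
                             {("T1", "a1"): 0.0, ("T1", "a2"): 0.0})
        assert ll == pytest.approx(total, abs=1e-10)

    def test_missing_eta_rejected(self):
        with pytest.raises(KeyError):
            binomial_loglik([_rec()], [_arm()], _flat_model(0.5), {})


class TestWeightedNormal:
    @pytest.mark.parametrize("p,N", [(0.5, 100), (0.2, 64)])
    def test_binomial_standard_error_weight(self, p, N):
        # residual SD is sigma * sqrt(P(1-P)/N) = sigma * 0.05 for both cases
        n_obs = int(round(0.4 * N))
        rec = [_rec(N=N, n=n_obs)]
        model = _flat_model(p, sigma=2.0)
        ll = weighted_normal_objective(rec, [_arm()], model)
        sd = 2.0 * math.sqrt(p * (1 - p) / N)
        assert sd == pytest.approx(2.0 * 0.05)
        expected = norm.logpdf(n_obs / N, loc=p, scale=sd)
        assert ll == pytest.approx(float(expected), abs=1e-9)

    def test_rho_zero_matches_independent(self):
        recs = [_rec("a1", t, 50, n) for t, n in [(2, 10), (4, 15), (8, 20)]]
        base = _flat_model(0.4)
        ar1 = _flat_model(0.4, autocorr="ar1", rho=0.0)
        ll0 = weighted_normal_objective(recs, [_arm()], base)
        ll1 = weighted_normal_objective(recs, [_arm()], ar1)
        assert ll1 == pytest.approx(ll0, abs=1e-10)

    def test_autocorrelation_changes_likelihood(self):
        recs = [_rec("a1", t, 50, n) for t, n in [(2, 10), (4, 15), (8, 20)]]
        ll_ind = weighted_normal_objective(recs, [_arm()], _flat_model(0.4))
        ll_ar1 = weighted_normal_objective(
            recs, [_arm()], _flat_model(0.4, autocorr="ar1", rho=0.5))
        ll_cs = weighted_normal_objective(
            recs, [_arm()], _flat_model(0.4, autocorr="cs", rho=0.5))
        assert ll_ar1 != pytest.approx(ll_ind)
        assert ll_cs != pytest.approx(ll_ind)
        assert ll_ar1 != pytest.approx(ll_cs)


class TestMarginalLoglik:
    def test_zero_omega_reduces_to_conditional(self, small_dataset):
        records, arms = small_dataset
        model = make_small_truth(omega2=0.0)
        ml = marginal_loglik(records, arms, model)
        cl = binomial_loglik(records, arms, model,
                             {a.key: 0.0 for a in arms})
        assert ml == pytest.approx(cl, abs=1e-10)

    def test_single_patient_matches_numeric_integration(self):
        model = _flat_model(0.3, omega2=0.2)
        rec = [_rec(N=1, n=1)]
        arm = [_arm()]
        ml = marginal_loglik(rec, arm, model, ObjectiveConfig(quad_points=15))
        b = float(np.log(0.3) - np.log1p(-0.3))

        def integrand(e):
            return expit(b + e) * norm.pdf(e, 0, math.sqrt(0.2))

        oracle, err = integrate.quad(integrand, -8, 8, epsabs=1e-12)
        assert ml == pytest.approx(math.log(oracle), abs=1e-6)

    def test_quadrature_convergence(self, small_dataset, small_truth):
        records, arms = small_dataset
        ml7 = marginal_loglik(records, arms, small_truth,
                              ObjectiveConfig(quad_points=7))
        ml15 = marginal_loglik(records, arms, small_truth,
                               ObjectiveConfig(quad_points=15))
        assert abs(ml7 - ml15) < 1e-4

    def test_laplace_close_to_quadrature(self, small_dataset, small_truth):
        records, arms = small_dataset
        aghq = marginal_loglik(records, arms, small_truth, ObjectiveConfig())
        lap = marginal_loglik(records, arms, small_truth,
                              ObjectiveConfig(integration="laplace"))
        assert lap == pytest.approx(aghq, abs=0.5)

    def test_reparameterization_invariance(self, small_dataset):
        # shifting a covariate and its reference mean together leaves the
        # additive-form likelihood unchanged
        records, arms = small_dataset
        m1 = make_small_truth()
        m1.covariate_effects = [
            CovariateEffectSpec("duration", "drug_emax", "additive", 0.1, 7.0)
        ]
        m2 = copy.deepcopy(m1)
        m2.covariate_effects[0].cov_mean = 10.0
        shifted = []
        for a in arms:
            c = copy.deepcopy(a.covariates)
            c.duration = c.duration + 3.0
            shifted.append(copy.deepcopy(a))
            shifted[-1].covariates = c
        ll1 = marginal_loglik(records, arms, m1)
        ll2 = marginal_loglik(records, shifted, m2)
        assert ll2 == pytest.approx(ll1, abs=1e-9)


class TestFitModel:
    def test_recovers_truth_and_is_deterministic(self, small_dataset,
                                                 small_truth, fast_cfg):
        records, arms = small_dataset
        fit1 = fit_model(records, arms, small_truth, fast_cfg)
        fit2 = fit_model(records, arms, small_truth, fast_cfg)
        assert fit1.converged
        assert fit1.estimates == fit2.estimates
        assert fit1.aic == pytest.approx(-2 * fit1.loglik + 2 * fit1.n_params)
        assert fit1.estimates["drug.infliximab.Emax"] == pytest.approx(
            1.48, abs=0.6
        )

    def test_fisher_information_scaling(self, small_design):
        # doubling every arm size shrinks standard errors by ~sqrt(2);
        # this binomial-information property requires omega^2 = 0, since
        # with between-arm variability the SE floors at the arm level
        truth = make_small_truth(omega2=0.0)
        cfg = ObjectiveConfig(
            fixed_params=("*.gamma", "cov.*", "omega2"), n_restarts=1, seed=11
        )
        records, arms = generate_dataset(small_design, truth, seed=77)
        doubled = [
            ObservationRecord(r.trial_id, r.arm_id, r.endpoint, r.time,
                              2 * r.n_total, 2 * r.n_response)
            for r in records
        ]
        f1 = fit_model(records, arms, truth, cfg)
        f2 = fit_model(doubled, arms, truth, cfg)
        r1 = f1.se["drug.infliximab.Emax"]
        r2 = f2.se["drug.infliximab.Emax"]
        assert r1 / r2 == pytest.approx(math.sqrt(2.0), rel=0.25)

    def test_null_effect_ci_covers_zero(self, fast_cfg):
        # data generated with Emax = 0: the Wald CI should cover 0 in most
        # replicates (two-sided 95% interval; binomial tolerance at n=8)
        truth = make_small_truth(omega2=0.0)
        truth.drug_spec("infliximab").Emax = 0.0
        truth.drug_spec("adalimumab").Emax = 0.0
        design = make_small_design(n_per_arm=100)
        # the onset rate is unidentifiable when the drug effect is null, so
        # it stays fixed here
        cfg = ObjectiveConfig(
            fixed_params=("*.gamma", "cov.*", "omega2", "onset.*"),
            n_restarts=1, seed=11,
        )
        covered = 0
        for s in range(8):
            records, arms = generate_dataset(design, truth, seed=300 + s)
            fit = fit_model(records, arms, truth, cfg)
            lo, hi = fit.cis["drug.infliximab.Emax"]
            covered += (lo <= 0.0 <= hi)
        assert covered >= 6

    def test_weighted_normal_objective_fits(self, small_dataset, small_truth):
        # the alternative observation model estimates sigma alongside the
        # structural parameters and lands near the generating values
        records, arms = small_dataset
        cfg = ObjectiveConfig(
            likelihood="weighted_normal",
            fixed_params=("*.gamma", "cov.*", "rho"), n_restarts=1, seed=2,
        )
        fit = fit_model(records, arms, small_truth, cfg)
        assert fit.converged
        assert "sigma" in fit.estimates
        assert fit.estimates["sigma"] == pytest.approx(1.0, abs=0.5)
        assert fit.estimates["drug.infliximab.Emax"] == pytest.approx(
            1.48, abs=0.6
        )

    def test_fixed_params_honored(self, small_dataset, small_truth):
        records, arms = small_dataset
        cfg = ObjectiveConfig(
            fixed_params=("*.gamma", "cov.*", "placebo.k_pbo"),
            n_restarts=1,
        )
        fit = fit_model(records, arms, small_truth, cfg)
        assert "placebo.k_pbo" not in fit.estimates
        assert fit.model.placebo.k_pbo == small_truth.placebo.k_pbo


class TestCompareModels:
    def _fit(self, loglik, names):
        return FitResult(
            model=None, loglik=loglik, n_params=len(names),
            aic=-2 * loglik + 2 * len(names), vcov=None, cis={},
            converged=True, n_obs=100, trace=[],
            estimates={n: 0.0 for n in names},
        )

    def test_identical_fits(self):
        a = self._fit(-100.0, ["x"])
        out = compare_models(a, self._fit(-100.0, ["x"]))
        assert out["lrt_stat"] == pytest.approx(0.0)
        assert out["p_value"] == pytest.approx(1.0)

    def test_chi_square_tail(self):
        a = self._fit(-100.0, ["x"])
        b = self._fit(-97.0, ["x", "y"])
        out = compare_models(a, b)
        assert out["lrt_stat"] == pytest.approx(6.0)
        assert out["df"] == 1
        assert out["p_value"] == pytest.approx(0.0143, abs=2e-4)
        assert out["delta_aic"] == pytest.approx(-2 * 3.0 + 2 * 1)

    def test_non_nested_flagged(self):
        a = self._fit(-100.0, ["x"])
        b = self._fit(-99.0, ["y", "z"])
        out = compare_models(a, b)
        assert not out["nested"]
        assert "p_value" not in out


class TestStepwise:
    def _setup(self, theta, seed):
        truth = make_small_truth(omega2=0.0)
        if theta:
            truth.covariate_effects = [
                CovariateEffectSpec("duration", "drug_emax", "additive",
                                    theta, 7.0)
            ]
        design = make_small_design(n_per_arm=150)
        records, arms = generate_dataset(design, truth, seed=seed)
        base = make_small_truth(omega2=0.0)
        return records, arms, base

    def test_strong_effect_selected_first(self, fast_cfg):
        records, arms, base = self._setup(theta=0.5, seed=42)
        cands = [
            CovariateEffectSpec("duration", "drug_emax", "additive", 0.0, 7.0),
            CovariateEffectSpec("age", "drug_emax", "additive", 0.0, 41.0),
        ]
        cfg = ObjectiveConfig(fixed_params=("*.gamma",), n_restarts=1, seed=2)
        final, log = stepwise_covariates(records, arms, base, cands, cfg)
        accepted = [e["accepted"] for e in log if "accepted" in e]
        assert accepted
        assert accepted[0].startswith("cov.duration")
        fitted_rounds = [e for e in log if e.get("status") == "fitted"]
        assert len(fitted_rounds) >= len(cands)

    def test_null_returns_base_with_bookkeeping(self, fast_cfg):
        records, arms, base = self._setup(theta=0.0, seed=7)
        cands = [
            CovariateEffectSpec("age", "drug_emax", "additive", 0.0, 41.0),
        ]
        cfg = ObjectiveConfig(fixed_params=("*.gamma",), n_restarts=1, seed=2)
        final, log = stepwise_covariates(records, arms, base, cands, cfg)
        fitted = [e for e in log if e.get("status") == "fitted"]
        accepted = [e for e in log if "accepted" in e]
        assert len(fitted) == 1
        if not accepted:  # the expected null outcome
            assert set(final.estimates) == {
                "placebo.B", "placebo.A", "placebo.k_pbo",
                "drug.adalimumab.Emax", "drug.infliximab.Emax",
                "onset.adalimumab", "omega2",
            }

    def test_likelihood_never_decreases_on_accepted_path(self, fast_cfg):
        records, arms, base = self._setup(theta=0.5, seed=42)
        cands = [
            CovariateEffectSpec("duration", "drug_emax", "additive", 0.0, 7.0),
        ]
        cfg = ObjectiveConfig(fixed_params=("*.gamma",), n_restarts=1, seed=2)
        base_fit = fit_model(records, arms, base, cfg)
        final, log = stepwise_covariates(records, arms, base, cands, cfg)
        assert final.loglik >= base_fit.loglik - 1e-6
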