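"""Monte-Carlo simulation of comparative efficacy, onset times, and ranking.

Parameter uncertainty is propagated either by multivariate-normal draws from
the fit covariance or by resampling bootstrap replicate rows; an arm-level
eta draw per replicate (optional) makes the bands reflect between-arm
heterogeneity on top of estimation uncertainty.  Placebo is simulated from
the same parameter draw as each treatment so placebo-corrected differences
are computed within draws.

ET90 — the time at which 90% of the asymptotic effect is reached — is
defined on two scales: the onset-factor scale ``ln(10)/k`` (solves
``1 - exp(-k t) = 0.9``) and the response-probability scale (the root of
``P(t) = 0.9 * P(infinity)``), since published onset times mix the two.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data import CovariateProfile
from .estimate import FitResult, ObjectiveConfig, ParameterPacker
from .model import (
    DrugEffectSpec, ModelSpec, PlaceboSpec, drug_effect, inverse_logit,
    placebo_effect,
)
from .validate import BootstrapResult

logger = logging.getLogger(__name__)

__all__ = ["PopulationProfile", "SimulationResult", "simulate_efficacy",
           "et90", "rank_treatments"]

DEFAULT_WEEKS = tuple(range(1, 61))


@dataclass
class PopulationProfile:
    """Hypothetical target population for efficacy simulation."""

    duration: float = 7.0
    age: float = 40.0
    prior_tnf_pct: float = 50.0
    steroid_pct: float = 50.0
    weight: float = 70.0

    def __post_init__(self) -> None:
        for f in ("duration", "age", "weight"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        for f in ("prior_tnf_pct", "steroid_pct"):
            if not 0 <= getattr(self, f) <= 100:
                raise ValueError(f"{f} must be in [0, 100]")

    def to_covariates(self) -> CovariateProfile:
        return CovariateProfile(
            age=self.age, weight=self.weight, duration=self.duration,
            prior_tnf_pct=self.prior_tnf_pct, steroid_pct=self.steroid_pct,
            male_pct=50.0,
        )


@dataclass
class SimulationResult:
    table: pd.DataFrame  # (treatment, week) rows with medians and bands
    n_draws: int
    seed: int
    include_eta: bool

    @property
    def treatments(self) -> list[str]:
        return [t for t in dict.fromkeys(self.table["treatment"])]

    @property
    def weeks(self) -> np.ndarray:
        return np.unique(self.table["week"])


def _default_treatments(model: ModelSpec):
    """(label, drug, dose, regimen_tag) for each drug and override regimen."""
    out = []
    for d in sorted(model.drugs, key=lambda d: d.drug):
        dose = d.reference_dose
        if dose is None:
            dose = 1.0 if d.dose_model == "emax_flat" else 0.0
        out.append((d.drug, d.drug, float(dose), ""))
        for tag in sorted(d.regimen_overrides):
            try:
                tag_dose = float(tag.rstrip("mg").strip())
            except ValueError:
                tag_dose = float(dose)
            out.append((f"{d.drug} {tag}", d.drug, tag_dose, tag))
    return out


def _parameter_draws(fitted: ModelSpec, uncertainty, n_draws, rng, cfg):
    """(names, draw matrix) of parameter vectors from vcov or bootstrap."""
    if uncertainty is None:
        return None, None
    if isinstance(uncertainty, FitResult):
        if uncertainty.vcov is None:
            raise ValueError(
                "fit has no positive-definite covariance; pass a "
                "BootstrapResult instead"
            )
        names = list(uncertainty.vcov.columns)
        mean = np.array([uncertainty.estimates[n] for n in names])
        cov = uncertainty.vcov.to_numpy()
        eigs = np.linalg.eigvalsh(cov)
        if eigs.min() < -1e-10 * max(eigs.max(), 1.0):
            raise ValueError("fit covariance is not positive semi-definite")
        draws = rng.multivariate_normal(
            mean, cov, size=n_draws, method="eigh"
        )
        return names, draws
    if isinstance(uncertainty, BootstrapResult):
        est = uncertainty.estimates
        idx = rng.integers(0, len(est), size=n_draws)
        return list(est.columns), est.to_numpy()[idx]
    raise TypeError(
        "uncertainty must be a FitResult, BootstrapResult, or None"
    )


def simulate_efficacy(
    fitted: ModelSpec,
    uncertainty,
    pop: PopulationProfile | None = None,
    weeks=DEFAULT_WEEKS,
    n_draws: int = 10000,
    seed: int = 0,
    include_eta: bool = True,
    treatments=None,
) -> SimulationResult:
    """Simulate per-treatment response time-courses in a target population.

    ``uncertainty`` is a :class:`FitResult` (multivariate-normal draws from
    its covariance, clipped to the parameter bounds) or a
    :class:`BootstrapResult` (replicate-row resampling); ``None`` gives a
    degenerate (deterministic-parameter) simulation.  A placebo curve is
    evaluated under every parameter draw, so the placebo-corrected summary
    is a median of within-draw differences.
    """
    fitted.validate()
    pop = pop or PopulationProfile()
    covs = pop.to_covariates()
    weeks = np.asarray(list(weeks), dtype=float)
    rng = np.random.default_rng(seed)
    treatments = treatments or _default_treatments(fitted)

    cfg = ObjectiveConfig(fixed_params=())
    packer = ParameterPacker(fitted, cfg)
    names, draws = _parameter_draws(fitted, uncertainty, n_draws, rng, cfg)
    if draws is not None:
        # clip to the structural bounds (k > 0 etc.)
        bidx = {n: i for i, n in enumerate(packer.free_names)}
        for j, name in enumerate(names):
            lo, hi = packer.bounds[bidx[name]]
            draws[:, j] = np.clip(draws[:, j], lo, hi)
        setter_names = names
    else:
        n_draws = n_draws if include_eta and fitted.omega2 > 0 else n_draws
        setter_names = []

    omega = float(np.sqrt(fitted.omega2))

    def curves(model, eta):
        e0 = placebo_effect(weeks, model.placebo, covs, model.covariate_effects)
        placebo = inverse_logit(e0 + eta[0])
        out = {}
        for k, (label, drug, dose, tag) in enumerate(treatments):
            spec = model.drug_spec(drug)
            ed = drug_effect(drug, dose, weeks, spec, covs,
                             model.covariate_effects, tag)
            out[label] = inverse_logit(e0 + ed + eta[k + 1])
        return placebo, out

    n_eta = len(treatments) + 1
    pbo_mat = np.empty((n_draws, weeks.size))
    trt_mat = {label: np.empty((n_draws, weeks.size))
               for label, *_ in treatments}
    work = copy.deepcopy(fitted)
    wpacker = ParameterPacker(work, cfg)
    wsetter = {n: wpacker._setters[n] for n in setter_names}
    for s in range(n_draws):
        if draws is not None:
            for name, v in zip(setter_names, draws[s]):
                wsetter[name](float(v))
            model = wpacker.model
        else:
            model = fitted
        eta = (rng.normal(0.0, omega, size=n_eta)
               if include_eta and omega > 0 else np.zeros(n_eta))
        pbo, trts = curves(model, eta)
        pbo_mat[s] = pbo
        for label, vals in trts.items():
            trt_mat[label][s] = vals

    rows = []
    pbo_med = np.median(pbo_mat, axis=0)
    for label, drug, dose, tag in treatments:
        mat = trt_mat[label]
        lo, med, hi = np.percentile(mat, [2.5, 50.0, 97.5], axis=0)
        diff = mat - pbo_mat
        dlo, dmed, dhi = np.percentile(diff, [2.5, 50.0, 97.5], axis=0)
        for i, w in enumerate(weeks):
            rows.append({
                "treatment": label, "drug": drug, "dose": dose,
                "regimen_tag": tag, "week": w,
                "median": med[i], "lo": lo[i], "hi": hi[i],
                "placebo_median": pbo_med[i],
                "placebo_corrected_median": dmed[i],
                "placebo_corrected_lo": dlo[i],
                "placebo_corrected_hi": dhi[i],
            })
    return SimulationResult(
        table=pd.DataFrame(rows), n_draws=n_draws, seed=seed,
        include_eta=include_eta,
    )


def et90(component, scale: str = "onset_factor",
         covs: CovariateProfile | None = None, effects=(),
         placebo: PlaceboSpec | None = None, dose: float | None = None,
         tol: float = 1e-6) -> float:
    """Time (weeks) to reach 90% of the asymptotic effect.

    ``scale="onset_factor"``: closed form ``ln(10)/k`` from the component's
    rate constant.  ``scale="probability"``: bracketing root-find of
    ``P(t) = 0.9 * P(inf)`` on the response-probability scale; for a drug
    component the placebo spec supplies the background time-course.
    """
    if scale not in ("onset_factor", "probability"):
        raise ValueError(f"unknown scale {scale!r}")
    if isinstance(component, PlaceboSpec):
        if component.form != "exponential":
            raise ValueError(
                "ET90 needs a finite asymptote (exponential placebo)"
            )
        k = component.k_pbo
        if scale == "onset_factor":
            return float(np.log(10.0) / k)

        def prob(t):
            return float(inverse_logit(
                placebo_effect(t, component, covs, effects)
            ))

        p_inf = float(inverse_logit(
            _placebo_asymptote(component, covs, effects)
        ))
    elif isinstance(component, DrugEffectSpec):
        if scale == "onset_factor":
            if component.k_onset is None:
                raise ValueError("no onset defined (time-constant drug effect)")
            return float(np.log(10.0) / component.k_onset)
        if placebo is None or placebo.form != "exponential":
            raise ValueError(
                "probability-scale drug ET90 needs an exponential placebo spec"
            )
        if component.k_onset is None and placebo is None:
            raise ValueError("no onset defined")
        if dose is None:
            dose = component.reference_dose or 1.0

        def prob(t):
            e0 = placebo_effect(t, placebo, covs, effects)
            ed = drug_effect(component.drug, dose, t, component, covs, effects)
            return float(inverse_logit(e0 + ed))

        e0_inf = _placebo_asymptote(placebo, covs, effects)
        ed_inf = _drug_asymptote(component, dose, covs, effects)
        p_inf = float(inverse_logit(e0_inf + ed_inf))
    else:
        raise TypeError("component must be a PlaceboSpec or DrugEffectSpec")

    target = 0.9 * p_inf
    f = lambda t: prob(t) - target
    if f(0.0) >= 0:
        return 0.0
    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("ET90 root bracketing failed")
    return float(brentq(f, 0.0, hi, xtol=tol))


def _placebo_asymptote(spec: PlaceboSpec, covs, effects) -> float:
    from .model import _cov_adjustments
    factor, offset = _cov_adjustments(covs, effects, "placebo_asymptote")
    return float((spec.B + spec.A) * factor + offset)


def _drug_asymptote(spec: DrugEffectSpec, dose, covs, effects) -> float:
    from .model import _cov_adjustments, _dose_magnitude
    mag = float(_dose_magnitude(spec, dose, ""))
    factor, offset = _cov_adjustments(covs, effects, "drug_emax")
    return (mag * float(factor) + float(offset)) if dose > 0 else 0.0


def rank_treatments(sim: SimulationResult, week: float) -> pd.DataFrame:
    """Treatments ordered by placebo-corrected median response at ``week``.

    Ties are broken by narrower 95% band, then lexically; tie-broken rows
    are flagged in the ``tie`` column.
    """
    sub = sim.table[sim.table["week"] == week]
    if sub.empty:
        raise ValueError(
            f"week {week} not simulated; available: "
            f"{sorted(set(sim.table['week']))}"
        )
    sub = sub.copy()
    sub["band_width"] = sub["hi"] - sub["lo"]
    sub = sub.sort_values(
        ["placebo_corrected_median", "band_width", "treatment"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    dup = sub["placebo_corrected_median"].duplicated(keep=False)
    sub["tie"] = dup
    sub["rank"] = np.arange(1, len(sub) + 1)
    return sub[[
        "rank", "treatment", "drug", "dose", "regimen_tag", "week",
        "median", "lo", "hi", "placebo_median", "placebo_corrected_median",
        "placebo_corrected_lo", "placebo_corrected_hi", "tie",
    ]]
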