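"""Structural model on the logit scale.

The probability that a patient in arm *j* of trial *i* meets the endpoint at
week *t* is ``invlogit(E0(t) + E_drug(t) + eta_ij)``:

* ``E0`` — placebo time-course, either exponential
  ``B + A * (1 - exp(-k_pbo * t))`` or a restricted cubic spline / polynomial
  in ``t``;
* ``E_drug`` — drug effect, an onset factor ``1 - exp(-k_onset * t)`` (absent
  for drugs with time-constant efficacy) times a dose-response magnitude:
  Emax (dose-independent when ED50 is fixed to 0), sigmoidal Emax with Hill
  coefficient fixed to 1, or a linear slope * dose;
* arm-level covariates shift the placebo asymptote and the drug magnitude
  through additive or power adjustment around a reference mean;
* ``eta_ij ~ N(0, omega^2)`` is the between-arm random effect.

All evaluation functions broadcast over numpy arrays of ``t``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.special import expit

from .data import ArmDescriptor, CovariateProfile

__all__ = [
    "PlaceboSpec", "DrugEffectSpec", "CovariateEffectSpec", "ModelSpec",
    "inverse_logit", "logit", "rcs_basis", "placebo_effect", "drug_effect",
    "apply_covariate", "response_probability", "load_model", "save_model",
    "load_packaged_model",
]


def inverse_logit(x):
    """Logistic link: map a logit value to a probability in (0, 1)."""
    return expit(x)


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


@dataclass
class PlaceboSpec:
    form: str = "exponential"  # exponential | polynomial | rcs
    B: float | None = None
    A: float | None = None
    k_pbo: float | None = None
    poly_coeffs: list[float] = field(default_factory=list)
    spline_coeffs: list[float] = field(default_factory=list)
    knots: list[float] = field(default_factory=list)

    def validate(self) -> None:
        if self.form == "exponential":
            if self.B is None or self.A is None or self.k_pbo is None:
                raise ValueError("exponential placebo needs B, A, k_pbo")
            if self.k_pbo <= 0:
                raise ValueError("k_pbo must be > 0")
        elif self.form == "rcs":
            k = np.asarray(self.knots, dtype=float)
            if k.size < 3 or np.any(np.diff(k) <= 0):
                raise ValueError("rcs needs >= 3 strictly increasing knots")
            if len(self.spline_coeffs) != k.size:  # intercept + (k-1) basis
                raise ValueError(
                    f"rcs with {k.size} knots needs {k.size} coefficients "
                    f"(intercept + {k.size - 1} basis terms)"
                )
        elif self.form == "polynomial":
            if not self.poly_coeffs or len(self.poly_coeffs) > 4:
                raise ValueError("polynomial placebo: 1-4 coefficients (degree <= 3)")
        else:
            raise ValueError(f"unknown placebo form {self.form!r}")


@dataclass
class DrugEffectSpec:
    drug: str
    dose_model: str = "emax_flat"  # emax_flat | emax | linear
    Emax: float | None = None
    ED50: float | None = None
    gamma: float = 1.0
    slope: float | None = None
    k_onset: float | None = None
    #: drugs sharing one onset rate constant (e.g. the JAK-inhibitor class)
    #: carry the same group label; the group name is the parameter identity
    onset_group: str | None = None
    regimen_overrides: dict = field(default_factory=dict)
    #: labelled dose used for simulation defaults (mg per administration)
    reference_dose: float | None = None

    def validate(self) -> None:
        if self.dose_model == "emax_flat":
            if self.Emax is None:
                raise ValueError(f"{self.drug}: emax_flat needs Emax")
            if self.ED50 not in (None, 0, 0.0):
                raise ValueError(f"{self.drug}: emax_flat implies ED50=0")
        elif self.dose_model == "emax":
            if self.Emax is None or self.ED50 is None:
                raise ValueError(f"{self.drug}: emax needs Emax and ED50")
        elif self.dose_model == "linear":
            if self.slope is None:
                raise ValueError(f"{self.drug}: linear needs slope")
        else:
            raise ValueError(f"unknown dose model {self.dose_model!r}")
        if self.k_onset is not None and self.k_onset <= 0:
            raise ValueError(f"{self.drug}: k_onset must be > 0 when present")


@dataclass
class CovariateEffectSpec:
    covariate: str
    target: str  # placebo_asymptote | drug_emax
    form: str  # additive | power
    theta: float
    cov_mean: float

    def validate(self) -> None:
        if self.target not in ("placebo_asymptote", "drug_emax"):
            raise ValueError(f"unknown covariate target {self.target!r}")
        if self.form not in ("additive", "power"):
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.form == "power" and self.cov_mean <= 0:
            raise ValueError("power form needs cov_mean > 0")


@dataclass
class ModelSpec:
    endpoint: str
    placebo: PlaceboSpec
    drugs: list[DrugEffectSpec] = field(default_factory=list)
    covariate_effects: list[CovariateEffectSpec] = field(default_factory=list)
    omega2: float = 0.0
    sigma: float = 1.0
    autocorr: str = "none"  # none | ar1 | cs
    rho: float = 0.0

    def validate(self) -> None:
        self.placebo.validate()
        for d in self.drugs:
            d.validate()
        for c in self.covariate_effects:
            c.validate()
        if self.omega2 < 0:
            raise ValueError("omega2 must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.autocorr not in ("none", "ar1", "cs"):
            raise ValueError(f"unknown autocorrelation {self.autocorr!r}")
        if self.autocorr != "none" and not abs(self.rho) < 1:
            raise ValueError("|rho| < 1 required with autocorrelation")

    def drug_spec(self, drug: str) -> DrugEffectSpec:
        for d in self.drugs:
            if d.drug == drug:
                return d
        raise KeyError(f"no effect spec for drug {drug!r}")

    def has_drug(self, drug: str) -> bool:
        return any(d.drug == drug for d in self.drugs)


# ---------------------------------------------------------------------------
# basis and effect evaluation


def rcs_basis(t, knots) -> np.ndarray:
    """Restricted cubic spline basis (Harrell parameterization).

    With *k* knots returns ``k - 1`` columns (no intercept): the identity
    term ``t`` plus ``k - 2`` truncated-cubic terms constructed to be linear
    beyond the boundary knots.
    """
    knots = np.asarray(knots, dtype=float)
    if knots.size < 3 or np.any(np.diff(knots) <= 0):
        raise ValueError("rcs_basis needs >= 3 strictly increasing knots")
    t = np.asarray(t, dtype=float)
    k = knots.size
    tau = (knots[-1] - knots[0]) ** 2  # scale normalization

    def cub(x):
        return np.maximum(x, 0.0) ** 3

    cols = [t]
    d_last = knots[-1] - knots[-2]
    for j in range(k - 2):
        term = (
            cub(t - knots[j])
            - cub(t - knots[-2]) * (knots[-1] - knots[j]) / d_last
            + cub(t - knots[-1]) * (knots[-2] - knots[j]) / d_last
        )
        cols.append(term / tau)
    return np.stack(cols, axis=-1)


def apply_covariate(base, cov_value, effect: CovariateEffectSpec):
    """Adjust a parameter for one arm-level covariate.

    additive: ``base + (cov - cov_mean) * theta``
    power:    ``base * (cov / cov_mean) ** theta`` (requires cov > 0)
    """
    effect.validate()
    cov_value = np.asarray(cov_value, dtype=float)
    if effect.form == "additive":
        return base + (cov_value - effect.cov_mean) * effect.theta
    if np.any(cov_value <= 0):
        raise ValueError(
            f"power covariate {effect.covariate!r} needs value > 0"
        )
    return base * (cov_value / effect.cov_mean) ** effect.theta


def _cov_adjustments(covs, effects, target):
    """Split covariate effects on `target` into a multiplicative factor and
    an additive offset, evaluated at this arm's covariate values."""
    factor, offset = 1.0, 0.0
    for eff in effects or ():
        if eff.target != target:
            continue
        v = covs.get(eff.covariate) if covs is not None else None
        if v is None:
            raise ValueError(
                f"covariate {eff.covariate!r} missing for adjustment"
            )
        if eff.form == "additive":
            offset = offset + (np.asarray(v, float) - eff.cov_mean) * eff.theta
        else:
            if np.any(np.asarray(v, float) <= 0):
                raise ValueError(
                    f"power covariate {eff.covariate!r} needs value > 0"
                )
            factor = factor * (np.asarray(v, float) / eff.cov_mean) ** eff.theta
    return factor, offset


def placebo_effect(t, spec: PlaceboSpec, covs: CovariateProfile | None = None,
                   effects=()) -> np.ndarray:
    """Placebo logit E0 at week(s) ``t``.

    Covariate effects targeting the placebo act on the asymptotic placebo
    logit ``B + A`` for the exponential form (the asymptote of E0 itself,
    keeping adjustments on the scale of the predicted response even when B
    and A are individually large and opposite-signed); for spline/polynomial
    forms a power effect scales the time-varying (non-intercept) part and an
    additive effect shifts E0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    spec.validate()
    factor, offset = _cov_adjustments(covs, effects, "placebo_asymptote")
    if spec.form == "exponential":
        asy = (spec.B + spec.A) * factor + offset
        A_adj = asy - spec.B
        return spec.B + A_adj * (1.0 - np.exp(-spec.k_pbo * t))
    if spec.form == "rcs":
        basis = rcs_basis(t, spec.knots)
        coeffs = np.asarray(spec.spline_coeffs, dtype=float)
        varying = basis @ coeffs[1:]
        return coeffs[0] + varying * factor + offset
    coeffs = np.asarray(spec.poly_coeffs, dtype=float)
    varying = sum(c * t ** (i + 1) for i, c in enumerate(coeffs[1:]))
    return coeffs[0] + varying * factor + offset


def _dose_magnitude(spec: DrugEffectSpec, dose, regimen_tag: str = "") -> float:
    """Dose-response magnitude before onset and covariate adjustment."""
    emax = spec.Emax
    if regimen_tag and regimen_tag in spec.regimen_overrides:
        emax = spec.regimen_overrides[regimen_tag]
    if spec.dose_model == "emax_flat":
        return np.where(np.asarray(dose, float) > 0, emax, 0.0)
    if spec.dose_model == "emax":
        dose = np.asarray(dose, dtype=float)
        g = spec.gamma
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(
                dose > 0, dose**g / (dose**g + spec.ED50**g), 0.0
            )
        return emax * frac
    return spec.slope * np.asarray(dose, dtype=float)


def drug_effect(drug: str, dose, t, spec: DrugEffectSpec,
                covs: CovariateProfile | None = None, effects=(),
                regimen_tag: str = "") -> np.ndarray:
    """Drug logit effect E_drug at dose (mg) and week(s) ``t``.

    Covariate effects targeting ``drug_emax`` adjust the dose-response
    magnitude (Emax, or slope*dose for the linear model) before the onset
    factor is applied; placebo / zero dose yields 0.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(np.asarray(dose, float) < 0):
        raise ValueError("dose and time must be >= 0")
    if drug == "placebo":
        return np.zeros_like(t)
    if drug != spec.drug:
        raise KeyError(f"spec is for {spec.drug!r}, not {drug!r}")
    spec.validate()
    mag = _dose_magnitude(spec, dose, regimen_tag)
    factor, offset = _cov_adjustments(covs, effects, "drug_emax")
    mag = np.where(np.asarray(dose, float) > 0, mag * factor + offset, 0.0)
    if spec.k_onset is None:
        return mag * np.ones_like(t)
    return mag * (1.0 - np.exp(-spec.k_onset * t))


def response_probability(arm: ArmDescriptor, t, model: ModelSpec,
                         eta: float = 0.0) -> np.ndarray:
    """P(endpoint) for one arm at week(s) ``t``: invlogit(E0 + E_drug + eta)."""
    e0 = placebo_effect(t, model.placebo, arm.covariates, model.covariate_effects)
    if arm.drug == "placebo":
        ed = 0.0
    else:
        spec = model.drug_spec(arm.drug)
        ed = drug_effect(
            arm.drug, arm.dose_amount, t, spec, arm.covariates,
            model.covariate_effects, arm.regimen_tag,
        )
    return inverse_logit(e0 + ed + eta)


# ---------------------------------------------------------------------------
# serialization


def _spec_to_dict(m: ModelSpec) -> dict:
    d = asdict(m)
    # drop None-valued optional fields for a tidy document
    def clean(x):
        if isinstance(x, dict):
            return {k: clean(v) for k, v in x.items() if v is not None}
        if isinstance(x, list):
            return [clean(v) for v in x]
        return x
    return clean(d)


def save_model(model: ModelSpec, path: str | Path) -> None:
    model.validate()
    with open(path, "w") as fh:
        yaml.safe_dump(_spec_to_dict(model), fh, sort_keys=False)


def model_from_dict(d: dict) -> ModelSpec:
    m = ModelSpec(
        endpoint=d["endpoint"],
        placebo=PlaceboSpec(**d["placebo"]),
        drugs=[DrugEffectSpec(**x) for x in d.get("drugs", [])],
        covariate_effects=[
            CovariateEffectSpec(**x) for x in d.get("covariate_effects", [])
        ],
        omega2=d.get("omega2", 0.0),
        sigma=d.get("sigma", 1.0),
        autocorr=d.get("autocorr", "none"),
        rho=d.get("rho", 0.0),
    )
    m.validate()
    return m


def load_model(path: str | Path) -> ModelSpec:
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


def load_packaged_model(endpoint: str) -> ModelSpec:
    """Load the packaged final model for one endpoint
    (remission, response, or endoscopic)."""
    ref = importlib.resources.files("uc_mbma") / "models" / f"{endpoint}.yaml"
    return model_from_dict(yaml.safe_load(ref.read_text()))
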