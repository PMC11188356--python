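"""Synthetic arm-level trial databases with the structure of the UC study pool.

``paper_design()`` packages a 35-trial / 95-arm / 15,585-patient design whose
per-drug trial, arm and patient counts and baseline-covariate medians (ranges)
match the published summary table exactly, including 32 placebo arms and four
two-drug trials (head-to-head comparator designs).  ``generate_dataset`` draws
arm-level covariates from truncated normals, an arm-level random effect
``eta ~ N(0, omega^2)``, and binomial responder counts from a generating
``ModelSpec`` — so every pipeline stage can be exercised offline against a
known truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import truncnorm

from .data import ArmDescriptor, CovariateProfile, ObservationRecord
from .model import ModelSpec, placebo_effect, drug_effect
from . import data as _data

logger = logging.getLogger(__name__)

INDUCTION_VISITS = (2.0, 4.0, 6.0, 8.0, 12.0)
MAINTENANCE_VISITS = (24.0, 44.0, 52.0, 60.0)


@dataclass(frozen=True)
class ArmDesign:
    drug: str
    dose_amount: float
    n_total: int
    dose_unit: str = "mg"
    regimen_tag: str = ""


@dataclass(frozen=True)
class TrialDesign:
    trial_id: str
    arms: tuple[ArmDesign, ...]
    maintenance: bool = False

    @property
    def visit_weeks(self) -> tuple[float, ...]:
        if self.maintenance:
            return INDUCTION_VISITS + MAINTENANCE_VISITS
        return INDUCTION_VISITS


@dataclass
class StudyDesign:
    """Trial layout plus per-drug covariate distributions (median, lo, hi)."""

    trials: tuple[TrialDesign, ...]
    covariate_distributions: dict  # drug -> {cov: (median, lo, hi) | None}
    endpoint: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for tr in self.trials:
            if not tr.arms:
                raise ValueError(f"trial {tr.trial_id} has no arms")
            if min(tr.visit_weeks) < 2.0 or list(tr.visit_weeks) != sorted(
                tr.visit_weeks
            ):
                raise ValueError(f"trial {tr.trial_id}: bad visit schedule")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_arms(self) -> int:
        return sum(len(t.arms) for t in self.trials)

    @property
    def n_patients(self) -> int:
        return sum(a.n_total for t in self.trials for a in t.arms)

    @property
    def n_placebo_arms(self) -> int:
        return sum(a.drug == "placebo" for t in self.trials for a in t.arms)


# --- published per-drug baseline covariates: median (min, max) ---------------
# male_pct, age, weight, duration, prior_tnf_pct, steroid_pct; None = not
# reported (weight for golimumab, filgotinib, etrasimod).
_COV_TABLE = {
    "infliximab":  {"male_pct": (61.4, 42.0, 66.7), "age": (39.8, 34.1, 42.4),
                    "weight": (70.0, 57.6, 80.0), "duration": (5.9, 3.7, 8.4),
                    "prior_tnf_pct": (0.0, 0.0, 0.0), "steroid_pct": (54.4, 43.5, 80.0)},
    "adalimumab":  {"male_pct": (57.8, 56.0, 67.8), "age": (40.5, 39.6, 44.4),
                    "weight": (75.4, 73.4, 76.8), "duration": (7.8, 6.4, 8.3),
                    "prior_tnf_pct": (0.0, 0.0, 39.1), "steroid_pct": (55.8, 36.3, 72.4)},
    "golimumab":   {"male_pct": (55.6, 54.4, 60.7), "age": (40.7, 40.0, 40.9),
                    "weight": None, "duration": (6.4, 6.4, 6.6),
                    "prior_tnf_pct": (0.0, 0.0, 0.0), "steroid_pct": (43.8, 42.9, 48.6)},
    "vedolizumab": {"male_pct": (60.8, 58.7, 67.1), "age": (40.8, 40.1, 44.0),
                    "weight": (72.4, 58.6, 72.7), "duration": (7.3, 6.1, 8.6),
                    "prior_tnf_pct": (42.2, 20.8, 50.0), "steroid_pct": (36.1, 30.8, 56.0)},
    "etrolizumab": {"male_pct": (59.0, 51.0, 68.0), "age": (40.5, 40.0, 44.4),
                    "weight": (81.8, 74.8, 88.8), "duration": (8.6, 8.0, 9.2),
                    "prior_tnf_pct": (30.5, 0.0, 100.0), "steroid_pct": (43.6, 41.0, 47.0)},
    "ustekinumab": {"male_pct": (60.0, 59.4, 60.6), "age": (42.0, 41.7, 42.2),
                    "weight": (73.4, 73.0, 73.7), "duration": (8.2, 8.1, 8.2),
                    "prior_tnf_pct": (68.4, 67.8, 68.9), "steroid_pct": (53.2, 52.2, 54.1)},
    "mirikizumab": {"male_pct": (61.0, 59.7, 62.8), "age": (42.6, 41.8, 43.4),
                    "weight": (75.6, 73.0, 77.0), "duration": (8.2, 6.0, 9.0),
                    "prior_tnf_pct": (37.4, 37.4, 37.4), "steroid_pct": (46.0, 40.3, 55.7)},
    "tofacitinib": {"male_pct": (57.2, 50.0, 64.0), "age": (41.4, 41.0, 43.8),
                    "weight": (74.2, 72.9, 75.9), "duration": (8.9, 7.6, 10.9),
                    "prior_tnf_pct": (42.2, 29.0, 55.2), "steroid_pct": (45.3, 27.0, 58.0)},
    "upadacitinib": {"male_pct": (61.6, 48.9, 66.1), "age": (42.1, 37.0, 47.0),
                    "weight": (70.3, 69.3, 71.2), "duration": (7.1, 6.6, 7.6),
                    "prior_tnf_pct": (77.2, 69.6, 100.0), "steroid_pct": (49.1, 38.9, 55.4)},
    "filgotinib":  {"male_pct": (56.6, 50.2, 65.3), "age": (42.5, 42.0, 43.0),
                    "weight": None, "duration": (8.5, 6.7, 9.8),
                    "prior_tnf_pct": (46.6, 0.0, 93.3), "steroid_pct": (30.1, 22.0, 36.1)},
    "ozanimod":    {"male_pct": (57.1, 49.2, 71.6), "age": (41.4, 38.8, 41.8),
                    "weight": (74.9, 72.3, 77.4), "duration": (6.7, 5.9, 6.9),
                    "prior_tnf_pct": (22.4, 18.5, 30.3), "steroid_pct": (34.0, 27.7, 40.0)},
    "etrasimod":   {"male_pct": (55.4, 52.6, 57.7), "age": (40.8, 40.3, 43.2),
                    "weight": None, "duration": (6.6, 6.2, 7.0),
                    "prior_tnf_pct": (31.4, 28.8, 34.0), "steroid_pct": (30.5, 25.0, 36.0)},
    "placebo":     {"male_pct": (60.0, 42.0, 72.9), "age": (41.2, 34.5, 44.8),
                    "weight": (72.8, 57.2, 78.7), "duration": (7.1, 3.7, 10.2),
                    "prior_tnf_pct": (30.6, 0.0, 100.0), "steroid_pct": (47.0, 8.0, 67.6)},
}
# baseline total Mayo score, not reported per drug; one loose range for all
_BASELINE_ACTIVITY = (8.8, 7.5, 10.0)

_P = "placebo"


def _trials() -> tuple[TrialDesign, ...]:
    A = ArmDesign
    t: list[TrialDesign] = []

    def trial(tid, arms, maintenance=False, pbo=None):
        full = list(arms)
        if pbo is not None:
            full.append(A(_P, 0.0, pbo))
        t.append(TrialDesign(tid, tuple(full), maintenance))

    # infliximab (5 own trials; 2 more shared below); 5 & 10 mg/kg regimens
    trial("IFX-1", [A("infliximab", 5, 121, "mg_per_kg"),
                    A("infliximab", 10, 122, "mg_per_kg")], True, pbo=128)
    trial("IFX-2", [A("infliximab", 5, 60, "mg_per_kg"),
                    A("infliximab", 10, 61, "mg_per_kg")], pbo=128)
    trial("IFX-3", [A("infliximab", 5, 102, "mg_per_kg"),
                    A("infliximab", 10, 101, "mg_per_kg")], pbo=128)
    trial("IFX-4", [A("infliximab", 5, 80, "mg_per_kg")], pbo=128)
    trial("IFX-5", [A("infliximab", 5, 115, "mg_per_kg")], pbo=128)
    # adalimumab (4 own trials); 160 mg induction, 80 mg lower regimen
    trial("ADA-1", [A("adalimumab", 160, 250), A("adalimumab", 80, 251)],
          True, pbo=128)
    trial("ADA-2", [A("adalimumab", 160, 224), A("adalimumab", 80, 223)],
          pbo=128)
    trial("ADA-3", [A("adalimumab", 160, 150), A("adalimumab", 80, 150)],
          pbo=128)
    trial("ADA-4", [A("adalimumab", 160, 248)], pbo=128)
    # golimumab dose-ranging
    trial("GOL-1", [A("golimumab", 100, 230), A("golimumab", 200, 230),
                    A("golimumab", 400, 230)], pbo=128)
    # vedolizumab (1 more shared below)
    trial("VED-1", [A("vedolizumab", 300, 257)], True, pbo=127)
    trial("VED-2", [A("vedolizumab", 300, 258)], pbo=127)
    # etrolizumab (2 more shared below)
    trial("ETR-1", [A("etrolizumab", 105, 155), A("etrolizumab", 105, 156)],
          True, pbo=128)
    trial("ETR-2", [A("etrolizumab", 105, 158)], pbo=128)
    trial("ETR-3", [A("etrolizumab", 105, 160)], pbo=128)
    # ustekinumab: 130 mg fixed and 6 mg/kg regimens
    trial("UST-1", [A("ustekinumab", 130, 321),
                    A("ustekinumab", 6, 321, "mg_per_kg")], pbo=127)
    # mirikizumab
    trial("MIR-1", [A("mirikizumab", 300, 263), A("mirikizumab", 600, 263)],
          pbo=128)
    trial("MIR-2", [A("mirikizumab", 300, 264), A("mirikizumab", 600, 264)],
          True, pbo=128)
    # tofacitinib
    trial("TOF-1", [A("tofacitinib", 3, 134), A("tofacitinib", 10, 134),
                    A("tofacitinib", 15, 134)], pbo=128)
    trial("TOF-2", [A("tofacitinib", 0.5, 134), A("tofacitinib", 3, 134),
                    A("tofacitinib", 10, 134)], pbo=128)
    trial("TOF-3", [A("tofacitinib", 5, 135), A("tofacitinib", 10, 134)],
          True, pbo=127)
    # upadacitinib: 45 mg regimen carries its own tag (separate Emax in the
    # clinical-response model)
    trial("UPA-1", [A("upadacitinib", 7.5, 108), A("upadacitinib", 15, 108),
                    A("upadacitinib", 30, 108),
                    A("upadacitinib", 45, 108, regimen_tag="45mg")], pbo=127)
    trial("UPA-2", [A("upadacitinib", 45, 216, regimen_tag="45mg")], pbo=127)
    trial("UPA-3", [A("upadacitinib", 45, 216, regimen_tag="45mg")], True,
          pbo=127)
    # filgotinib
    trial("FIL-1", [A("filgotinib", 100, 267), A("filgotinib", 200, 267)],
          pbo=127)
    trial("FIL-2", [A("filgotinib", 100, 267), A("filgotinib", 200, 268)],
          True, pbo=127)
    # ozanimod
    trial("OZA-1", [A("ozanimod", 0.5, 187), A("ozanimod", 1, 187)], pbo=127)
    trial("OZA-2", [A("ozanimod", 1, 187)], True, pbo=127)
    # etrasimod
    trial("ETS-1", [A("etrasimod", 1, 150), A("etrasimod", 2, 150)], pbo=127)
    trial("ETS-2", [A("etrasimod", 2, 149)], pbo=127)
    trial("ETS-3", [A("etrasimod", 2, 149)], True, pbo=127)
    # shared / head-to-head trials (close the published per-drug trial counts:
    # per-drug counts sum to 39 over 35 distinct trials, so 4 trials carry two
    # drugs; three of them are active-controlled with no placebo arm)
    trial("HH-1", [A("etrolizumab", 105, 161), A("adalimumab", 160, 264)],
          pbo=127)
    trial("HH-2", [A("etrolizumab", 105, 158), A("infliximab", 5, 117,
                                                 "mg_per_kg")])
    trial("HH-3", [A("vedolizumab", 300, 257), A("adalimumab", 160, 261)])
    trial("HH-4", [A("infliximab", 5, 117, "mg_per_kg"),
                   A("adalimumab", 160, 216)])
    return tuple(t)


def paper_design() -> StudyDesign:
    """The packaged study design replicating the published Table 1 marginals:
    35 trials, 95 arms, 15,585 patients, 32 placebo arms."""
    dists = {
        drug: {
            **{k: v for k, v in covs.items()},
            "baseline_activity": _BASELINE_ACTIVITY,
        }
        for drug, covs in _COV_TABLE.items()
    }
    return StudyDesign(trials=_trials(), covariate_distributions=dists)


def perturb_design(design: StudyDesign, scale: float) -> StudyDesign:
    """Scale all arm sizes by ``scale`` (rounded, floored at 10 patients)."""
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    if scale == 1:
        return design
    trials = tuple(
        replace(
            tr,
            arms=tuple(
                replace(a, n_total=max(10, round(a.n_total * scale)))
                for a in tr.arms
            ),
        )
        for tr in design.trials
    )
    return replace(design, trials=trials)


def _draw_covariates(drug: str, dists: dict, rng: np.random.Generator) -> CovariateProfile:
    vals: dict[str, float | None] = {}
    for name in _data.COVARIATE_FIELDS:
        spec = dists.get(drug, {}).get(name)
        if spec is None:
            vals[name] = None
            continue
        med, lo, hi = spec
        spread = (hi - lo) / 4.0
        if spread <= 0:
            vals[name] = float(med)
            continue
        a, b = (lo - med) / spread, (hi - med) / spread
        v = float(truncnorm.rvs(a, b, loc=med, scale=spread, random_state=rng))
        vals[name] = float(np.clip(v, lo, hi))
    return CovariateProfile(**vals)


def generate_dataset(
    design: StudyDesign,
    truth: ModelSpec,
    seed: int,
    missingness: float = 0.0,
    reference_weight: float = 70.0,
) -> tuple[list[ObservationRecord], list[ArmDescriptor]]:
    """Simulate a dataset from ``truth`` under ``design``.

    Per arm: covariates ~ truncated normal (published median, range/4 spread),
    eta ~ N(0, omega^2), responder counts ~ Binomial(N, P(t)) at each visit.
    Arms of drugs absent from ``truth`` are dropped (then whole trials left
    without an active arm, emulating endpoints not reported by every trial).
    ``missingness`` injects missing covariate cells into the *emitted* arms
    only (generation always uses the complete draw).  Deterministic per seed.
    """
    if design.endpoint is not None and design.endpoint != truth.endpoint:
        raise ValueError("design endpoint does not match truth endpoint")
    truth.validate()
    rng = np.random.default_rng(seed)
    omega = float(np.sqrt(truth.omega2))

    records: list[ObservationRecord] = []
    arms_out: list[ArmDescriptor] = []
    for tr in design.trials:
        kept = [a for a in tr.arms if a.drug == "placebo" or truth.has_drug(a.drug)]
        if not any(a.drug != "placebo" for a in kept):
            logger.info(
                "trial %s dropped: no active arm reports endpoint %s",
                tr.trial_id, truth.endpoint,
            )
            continue
        for idx, ad in enumerate(kept, start=1):
            covs = _draw_covariates(ad.drug, design.covariate_distributions, rng)
            dose = ad.dose_amount
            if ad.dose_unit == "mg_per_kg":
                dose = dose * reference_weight
            arm = ArmDescriptor(
                trial_id=tr.trial_id,
                arm_id=f"{tr.trial_id}-a{idx}",
                drug=ad.drug,
                dose_amount=float(dose),
                dose_unit="mg",
                regimen_tag=ad.regimen_tag,
                covariates=covs,
            )
            eta = rng.normal(0.0, omega) if omega > 0 else 0.0
            t = np.asarray(tr.visit_weeks, dtype=float)
            e0 = placebo_effect(t, truth.placebo, covs, truth.covariate_effects)
            if arm.drug == "placebo":
                lin = e0
            else:
                dspec = truth.drug_spec(arm.drug)
                lin = e0 + drug_effect(
                    arm.drug, arm.dose_amount, t, dspec, covs,
                    truth.covariate_effects, arm.regimen_tag,
                )
            p = 1.0 / (1.0 + np.exp(-(lin + eta)))
            if np.any(~np.isfinite(p)) or np.any((p <= 0) | (p >= 1)):
                raise RuntimeError(
                    f"degenerate probability for arm {arm.arm_id}"
                )
            counts = rng.binomial(ad.n_total, p)
            for week, c in zip(t, counts):
                records.append(
                    ObservationRecord(
                        trial_id=arm.trial_id,
                        arm_id=arm.arm_id,
                        endpoint=truth.endpoint,
                        time=float(week),
                        n_total=ad.n_total,
                        n_response=int(c),
                    )
                )
            arms_out.append(arm)

    if missingness > 0:
        injected = []
        for arm in arms_out:
            c = arm.covariates
            kwargs = {
                f: (None if (c.get(f) is not None and rng.random() < missingness) else c.get(f))
                for f in _data.COVARIATE_FIELDS
            }
            injected.append(replace(arm, covariates=CovariateProfile(**kwargs)))
        arms_out = injected
    return records, arms_out
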