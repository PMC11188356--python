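"""Arm-level aggregate trial data: ingestion, validation, normalization, summary.

The canonical interchange format is a flat CSV with one row per
trial x arm x visit (wide covariate columns).  Times are weeks since
randomization; doses are mg per administration after normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ENDPOINTS = ("remission", "response", "endoscopic")

DRUGS = (
    "placebo",
    "infliximab",
    "adalimumab",
    "golimumab",
    "vedolizumab",
    "etrolizumab",
    "ustekinumab",
    "mirikizumab",
    "tofacitinib",
    "upadacitinib",
    "filgotinib",
    "ozanimod",
    "etrasimod",
)

#: covariate fields subject to mean imputation
COVARIATE_FIELDS = (
    "age",
    "weight",
    "male_pct",
    "duration",
    "prior_tnf_pct",
    "steroid_pct",
    "baseline_activity",
)

PERCENT_FIELDS = ("male_pct", "prior_tnf_pct", "steroid_pct")

CSV_COLUMNS = [
    "trial_id", "arm_id", "drug", "dose_amount", "dose_unit", "regimen_tag",
    "endpoint", "time_weeks", "n_total", "n_response",
    "age", "weight", "male_pct", "duration", "prior_tnf_pct", "steroid_pct",
    "baseline_activity",
]


class SchemaError(ValueError):
    """Malformed input file (missing column, unparsable row)."""


class ValidationError(ValueError):
    """Row parsed but violates a data invariant."""


@dataclass
class CovariateProfile:
    """Arm-level baseline covariates; ``None`` marks a missing value.

    ``missing_flags`` records, after imputation, which fields were filled.
    """

    age: float | None = None
    weight: float | None = None
    male_pct: float | None = None
    duration: float | None = None
    prior_tnf_pct: float | None = None
    steroid_pct: float | None = None
    baseline_activity: float | None = None
    missing_flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in PERCENT_FIELDS:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValidationError(f"{name}={v} outside [0, 100]")
        for name in ("age", "weight", "duration"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{name}={v} must be > 0 when present")

    def get(self, name: str) -> float | None:
        return getattr(self, name)


@dataclass
class ArmDescriptor:
    """One treatment arm of one trial (drug, dose regimen, covariates)."""

    trial_id: str
    arm_id: str
    drug: str
    dose_amount: float = 0.0
    dose_unit: str = "mg"
    dose_interval: str = ""
    regimen_tag: str = ""
    covariates: CovariateProfile = field(default_factory=CovariateProfile)

    def __post_init__(self) -> None:
        if self.drug not in DRUGS:
            raise ValidationError(f"unknown drug {self.drug!r}")
        if self.dose_amount < 0:
            raise ValidationError(f"negative dose for arm {self.arm_id}")
        if self.drug == "placebo" and self.dose_amount != 0:
            raise ValidationError(
                f"placebo arm {self.arm_id} must have dose_amount=0"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.trial_id, self.arm_id)


@dataclass(frozen=True)
class ObservationRecord:
    """Responder count in one arm at one visit: n_response of n_total."""

    trial_id: str
    arm_id: str
    endpoint: str
    time: float
    n_total: int
    n_response: int

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")
        if self.time < 0:
            raise ValidationError(f"negative time {self.time}")
        if self.n_total < 1:
            raise ValidationError(f"n_total={self.n_total} < 1")
        if not (0 <= self.n_response <= self.n_total):
            raise ValidationError(
                f"n_response={self.n_response} outside [0, {self.n_total}] "
                f"({self.trial_id}/{self.arm_id} t={self.time})"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.trial_id, self.arm_id)


def _cell(row, col, rownum):
    if col not in row.index:
        raise SchemaError(f"missing column {col!r}")
    v = row[col]
    if pd.isna(v):
        return None
    return v


def load_dataset(
    path: str | Path, endpoint: str
) -> tuple[list[ObservationRecord], list[ArmDescriptor]]:
    """Read the CSV schema and return validated records and arm descriptors.

    Only rows of the requested ``endpoint`` are kept; arms that end up with no
    observation are dropped with a warning.  Duplicate (trial, arm, endpoint,
    time) rows raise :class:`ValidationError`.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    records: list[ObservationRecord] = []
    arms: dict[tuple[str, str], ArmDescriptor] = {}
    seen: set[tuple] = set()
    for i, row in df.iterrows():
        if row["endpoint"] != endpoint:
            continue
        try:
            rec = ObservationRecord(
                trial_id=str(row["trial_id"]),
                arm_id=str(row["arm_id"]),
                endpoint=str(row["endpoint"]),
                time=float(row["time_weeks"]),
                n_total=int(row["n_total"]),
                n_response=int(row["n_response"]),
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ValidationError):
                raise
            raise SchemaError(f"{path}: malformed row {i}: {exc}") from exc
        k = (rec.trial_id, rec.arm_id, rec.endpoint, rec.time)
        if k in seen:
            raise ValidationError(f"duplicate record {k}")
        seen.add(k)
        records.append(rec)
        if rec.key not in arms:
            covs = CovariateProfile(
                **{f: _cell(row, f, i) for f in COVARIATE_FIELDS}
            )
            arms[rec.key] = ArmDescriptor(
                trial_id=rec.trial_id,
                arm_id=rec.arm_id,
                drug=str(row["drug"]),
                dose_amount=float(row["dose_amount"]),
                dose_unit=str(_cell(row, "dose_unit", i) or "mg"),
                regimen_tag=str(_cell(row, "regimen_tag", i) or ""),
                covariates=covs,
            )
    # arms without observations cannot occur here by construction, but a
    # caller-supplied arm list can have them after endpoint filtering
    if not records:
        logger.warning("%s: no records for endpoint %s", path, endpoint)
    return records, list(arms.values())


def write_dataset(
    path: str | Path,
    records: list[ObservationRecord],
    arms: list[ArmDescriptor],
) -> None:
    """Write records+arms back to the canonical CSV schema."""
    by_key = {a.key: a for a in arms}
    rows = []
    for rec in records:
        a = by_key[rec.key]
        row = {
            "trial_id": rec.trial_id,
            "arm_id": rec.arm_id,
            "drug": a.drug,
            "dose_amount": a.dose_amount,
            "dose_unit": a.dose_unit,
            "regimen_tag": a.regimen_tag or None,
            "endpoint": rec.endpoint,
            "time_weeks": rec.time,
            "n_total": rec.n_total,
            "n_response": rec.n_response,
        }
        for f in COVARIATE_FIELDS:
            row[f] = a.covariates.get(f)
        rows.append(row)
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def normalize_dose(arm: ArmDescriptor, reference_weight: float = 70.0) -> ArmDescriptor:
    """Convert mg/kg doses to absolute mg at a reference body weight.

    Fixed-mg doses pass through unchanged.  The study convention is a typical
    patient weight of 70 kg.
    """
    if arm.dose_amount < 0:
        raise ValidationError(f"negative dose for arm {arm.arm_id}")
    if arm.dose_unit == "mg_per_kg":
        mg = arm.dose_amount * reference_weight
        logger.info(
            "normalized %s/%s: %.3g mg/kg -> %.4g mg at %g kg",
            arm.trial_id, arm.arm_id, arm.dose_amount, mg, reference_weight,
        )
        return replace(arm, dose_amount=mg, dose_unit="mg")
    if arm.dose_unit != "mg":
        raise ValidationError(f"unknown dose unit {arm.dose_unit!r}")
    return arm


def impute_covariates(
    arms: list[ArmDescriptor], patient_weighted: bool = False,
    weights: dict[tuple[str, str], float] | None = None,
) -> list[ArmDescriptor]:
    """Fill missing covariates with the mean of the available values.

    The default is the unweighted mean across arms; ``patient_weighted=True``
    weights arms by patient count (supply ``weights`` keyed by arm key).
    Filled fields are flagged in ``missing_flags``.  A covariate missing in
    every arm raises ``ValidationError``.
    """
    means: dict[str, float] = {}
    for name in COVARIATE_FIELDS:
        vals, w = [], []
        for a in arms:
            v = a.covariates.get(name)
            if v is not None:
                vals.append(v)
                w.append(weights.get(a.key, 1.0) if (patient_weighted and weights) else 1.0)
        if vals:
            means[name] = float(np.average(vals, weights=w))

    any_missing = {
        name
        for a in arms
        for name in COVARIATE_FIELDS
        if a.covariates.get(name) is None
    }
    unimputable = any_missing - set(means)
    if unimputable:
        raise ValidationError(
            f"covariates missing in all arms: {sorted(unimputable)}"
        )

    out = []
    for a in arms:
        c = a.covariates
        filled = dict(c.missing_flags)
        kwargs = {}
        for name in COVARIATE_FIELDS:
            v = c.get(name)
            if v is None and name in means:
                kwargs[name] = means[name]
                filled[name] = True
            else:
                kwargs[name] = v
                filled.setdefault(name, False)
        out.append(
            replace(a, covariates=CovariateProfile(missing_flags=filled, **kwargs))
        )
    return out


def summarize_dataset(
    arms: list[ArmDescriptor], records: list[ObservationRecord]
) -> pd.DataFrame:
    """Per-drug summary: trial/patient/arm counts and median (min, max) covariates.

    Mirrors the familiar baseline-characteristics table layout; the last row
    aggregates the whole dataset.  Patient counts take each arm's size once
    (the maximum n_total across that arm's visits, robust to dropouts).
    """
    if not arms or not records:
        raise ValueError("empty dataset")
    n_by_arm: dict[tuple[str, str], int] = {}
    for r in records:
        n_by_arm[r.key] = max(n_by_arm.get(r.key, 0), r.n_total)

    def _row(drug: str, sel: list[ArmDescriptor]) -> dict:
        row = {
            "drug": drug,
            "trials": len({a.trial_id for a in sel}),
            "patients": int(sum(n_by_arm.get(a.key, 0) for a in sel)),
            "arms": len(sel),
        }
        for f in COVARIATE_FIELDS:
            vals = [a.covariates.get(f) for a in sel]
            vals = [v for v in vals if v is not None]
            if vals:
                row[f] = f"{np.median(vals):.1f} ({min(vals):.1f}, {max(vals):.1f})"
            else:
                row[f] = "NA"
        return row

    order = [d for d in DRUGS if d != "placebo"] + ["placebo"]
    rows = [
        _row(d, [a for a in arms if a.drug == d])
        for d in order
        if any(a.drug == d for a in arms)
    ]
    rows.append(_row("total", list(arms)))
    return pd.DataFrame(rows)
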