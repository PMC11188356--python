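import numpy as np
import pytest

from uc_mbma.estimate import ObjectiveConfig
from uc_mbma.model import (DrugEffectSpec, ModelSpec, PlaceboSpec,
                           load_packaged_model)
from uc_mbma.synthetic import (ArmDesign, StudyDesign, TrialDesign,
                               generate_dataset)

_SMALL_COVS = {
    "infliximab": {"age": (40.0, 35.0, 45.0), "weight": (72.0, 60.0, 85.0),
                   "male_pct": (60.0, 45.0, 70.0), "duration": (6.0, 4.0, 9.0),
                   "prior_tnf_pct": (0.0, 0.0, 0.0),
                   "steroid_pct": (50.0, 35.0, 65.0),
                   "baseline_activity": (8.8, 7.5, 10.0)},
    "adalimumab": {"age": (41.0, 36.0, 46.0), "weight": (74.0, 62.0, 86.0),
                   "male_pct": (58.0, 45.0, 70.0), "duration": (7.5, 5.0, 10.0),
                   "prior_tnf_pct": (10.0, 0.0, 40.0),
                   "steroid_pct": (52.0, 35.0, 70.0),
                   "baseline_activity": (8.8, 7.5, 10.0)},
    "placebo": {"age": (41.0, 35.0, 46.0), "weight": (73.0, 60.0, 85.0),
                "male_pct": (59.0, 45.0, 72.0), "duration": (7.0, 4.0, 10.0),
                "prior_tnf_pct": (20.0, 0.0, 60.0),
                "steroid_pct": (47.0, 30.0, 68.0),
                "baseline_activity": (8.8, 7.5, 10.0)},
}


@pytest.fixture(scope="session")
def remission_model():
    return load_packaged_model("remission")


@pytest.fixture(scope="session")
def response_model():
    return load_packaged_model("response")


@pytest.fixture(scope="session")
def endoscopic_model():
    return load_packaged_model("endoscopic")


def make_small_truth(omega2=0.05) -> ModelSpec:
    """Two-drug exponential-placebo model for fast fitting tests."""
    return ModelSpec(
        endpoint="remission",
        placebo=PlaceboSpec(form="exponential", B=-8.0, A=5.8, k_pbo=0.66),
        drugs=[
            DrugEffectSpec("infliximab", Emax=1.48, reference_dose=350.0),
            DrugEffectSpec("adalimumab", Emax=0.864, k_onset=0.198,
                           onset_group="adalimumab", reference_dose=160.0),
        ],
        omega2=omega2,
    )


def make_small_design(n_per_arm=120) -> StudyDesign:
    A = ArmDesign
    trials = (
        TrialDesign("T1", (A("infliximab", 350, n_per_arm),
                           A("placebo", 0, n_per_arm))),
        TrialDesign("T2", (A("infliximab", 350, n_per_arm),
                           A("placebo", 0, n_per_arm)), maintenance=True),
        TrialDesign("T3", (A("adalimumab", 160, n_per_arm),
                           A("placebo", 0, n_per_arm))),
        TrialDesign("T4", (A("adalimumab", 160, n_per_arm),
                           A("infliximab", 350, n_per_arm),
                           A("placebo", 0, n_per_arm)), maintenance=True),
    )
    return StudyDesign(trials=trials, covariate_distributions=_SMALL_COVS)


@pytest.fixture(scope="session")
def small_truth():
    return make_small_truth()


@pytest.fixture(scope="session")
def small_design():
    return make_small_design()


@pytest.fixture(scope="session")
def small_dataset(small_design, small_truth):
    return generate_dataset(small_design, small_truth, seed=2024)


@pytest.fixture()
def fast_cfg():
    """Single-start objective config with covariates/gamma fixed at truth."""
    return ObjectiveConfig(
        fixed_params=("*.gamma", "cov.*"), n_restarts=1, seed=11
    )
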