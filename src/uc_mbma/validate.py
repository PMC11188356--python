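"""Model validation: bootstrap, visual predictive check, residual diagnostics.

The bootstrap resamples *arms* with replacement, stratified into placebo and
active strata (the arm is the model's exchangeability unit — one eta per
arm — and stratification preserves both strata in every replicate).
Replicates that fail to converge are dropped and counted, not retried.

The VPC simulates responder counts from the fitted model (eta draw plus
binomial sampling) and summarizes 2.5/50/97.5 percentile bands at each
observed design point (no time binning: visit times are few and shared).
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .estimate import FitResult, ObjectiveConfig, Predictor, fit_model
from .model import ModelSpec

logger = logging.getLogger(__name__)

__all__ = ["BootstrapResult", "VPCResult", "bootstrap", "vpc",
           "residual_diagnostics", "plot_vpc"]


@dataclass
class BootstrapResult:
    n_requested: int
    n_converged: int
    estimates: pd.DataFrame  # one row per converged replicate
    medians: dict
    percentile_cis: dict  # name -> (2.5th, 97.5th)
    seed: int
    resampling_unit: str = "arm (stratified placebo/active)"

    def __post_init__(self) -> None:
        if self.n_converged > self.n_requested:
            raise ValueError("n_converged > n_requested")


@dataclass
class VPCResult:
    n_sim: int
    bands: pd.DataFrame  # per (arm, time): sim_p2.5/sim_p50/sim_p97.5, observed
    coverage: float
    seed: int


def _resample(records, arms, rng):
    """One stratified arm bootstrap replicate (clones keep unique arm ids)."""
    by_key = {}
    for r in records:
        by_key.setdefault(r.key, []).append(r)
    placebo = [a for a in arms if a.drug == "placebo"]
    active = [a for a in arms if a.drug != "placebo"]
    chosen = []
    for stratum in (placebo, active):
        if stratum:
            idx = rng.integers(0, len(stratum), size=len(stratum))
            chosen.extend(stratum[i] for i in idx)
    new_arms, new_records = [], []
    for i, a in enumerate(chosen):
        clone = copy.deepcopy(a)
        clone.arm_id = f"{a.arm_id}#b{i}"
        new_arms.append(clone)
        for r in by_key.get(a.key, []):
            new_records.append(
                type(r)(
                    trial_id=r.trial_id, arm_id=clone.arm_id,
                    endpoint=r.endpoint, time=r.time,
                    n_total=r.n_total, n_response=r.n_response,
                )
            )
    return new_records, new_arms


def bootstrap(records, arms, spec: ModelSpec,
              cfg: ObjectiveConfig | None = None, n: int = 1000,
              seed: int = 0) -> BootstrapResult:
    """Arm-level stratified bootstrap: resample, refit, summarize.

    ``spec`` provides the starting values (normally the full-data fit).
    Reports percentile 95% intervals and per-parameter medians over the
    converged replicates; fully reproducible by ``seed``.
    """
    cfg = cfg or ObjectiveConfig()
    rng = np.random.default_rng(seed)
    rows = []
    n_conv = 0
    failures = []
    for b in range(n):
        rec_b, arms_b = _resample(records, arms, rng)
        cfg_b = copy.deepcopy(cfg)
        cfg_b.seed = int(rng.integers(0, 2**31 - 1))
        try:
            fit = fit_model(rec_b, arms_b, spec, cfg_b)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError) as exc:
            failures.append(str(exc))
            continue
        if not fit.converged:
            failures.append("nonconverged")
            continue
        n_conv += 1
        rows.append(fit.estimates)
    if not rows:
        raise RuntimeError(
            f"all {n} bootstrap replicates failed; examples: {failures[:3]}"
        )
    est = pd.DataFrame(rows)
    medians = est.median().to_dict()
    cis = {
        c: (float(est[c].quantile(0.025)), float(est[c].quantile(0.975)))
        for c in est.columns
    }
    return BootstrapResult(
        n_requested=n, n_converged=n_conv, estimates=est,
        medians=medians, percentile_cis=cis, seed=seed,
    )


def vpc(records, arms, fitted: ModelSpec, n_sim: int = 1000,
        seed: int = 0) -> VPCResult:
    """Visual predictive check against the fitted model.

    Simulates responder counts per (arm, visit) — eta ~ N(0, omega^2) plus
    binomial sampling — and reports simulated percentile bands with the
    observed proportions overlaid; ``coverage`` is the fraction of observed
    points inside the central 95% band.
    """
    if n_sim < 100:
        raise ValueError("n_sim >= 100 required for stable percentile bands")
    rng = np.random.default_rng(seed)
    pred = Predictor(records, arms)
    lp = pred.linpred(fitted)
    omega = float(np.sqrt(fitted.omega2))
    props = np.empty((n_sim, pred.R))
    for s in range(n_sim):
        eta = rng.normal(0.0, omega, size=pred.M) if omega > 0 else np.zeros(pred.M)
        P = expit(lp + eta[pred.arm_idx])
        counts = rng.binomial(pred.N.astype(int), P)
        props[s] = counts / pred.N
    lo, med, hi = np.percentile(props, [2.5, 50.0, 97.5], axis=0)
    obs = pred.n / pred.N
    inside = (obs >= lo) & (obs <= hi)
    bands = pd.DataFrame({
        "trial_id": [r.trial_id for r in pred.records],
        "arm_id": [r.arm_id for r in pred.records],
        "time": pred.t,
        "observed": obs,
        "sim_p2.5": lo,
        "sim_p50": med,
        "sim_p97.5": hi,
        "inside": inside,
    })
    return VPCResult(
        n_sim=n_sim, bands=bands, coverage=float(inside.mean()), seed=seed
    )


def residual_diagnostics(records, arms, fitted: ModelSpec) -> pd.DataFrame:
    """Conditional weighted residuals (obs - pred) / sqrt(pred(1-pred)/N).

    Predictions are conditional on the per-arm posterior mode of eta (the
    empirical-Bayes estimate); with omega^2 = 0 this is the population
    prediction.  The returned table has one row per observation, with
    overall mean/variance in ``df.attrs``.
    """
    pred = Predictor(records, arms)
    lp = pred.linpred(fitted)
    omega2 = fitted.omega2
    eta = np.zeros(pred.M)
    if omega2 > 0:
        for _ in range(60):
            P = expit(lp + eta[pred.arm_idx])
            g = pred._per_arm(pred.n - pred.N * P) - eta / omega2
            h = -pred._per_arm(pred.N * P * (1 - P)) - 1.0 / omega2
            step = np.clip(g / h, -1.0, 1.0)
            eta = eta - step
            if np.max(np.abs(step)) < 1e-12:
                break
    P = expit(lp + eta[pred.arm_idx])
    obs = pred.n / pred.N
    wres = (obs - P) / np.sqrt(P * (1 - P) / pred.N)
    df = pd.DataFrame({
        "trial_id": [r.trial_id for r in pred.records],
        "arm_id": [r.arm_id for r in pred.records],
        "time": pred.t,
        "predicted": P,
        "observed": obs,
        "weighted_residual": wres,
    })
    df.attrs["residual_mean"] = float(wres.mean())
    df.attrs["residual_var"] = float(wres.var(ddof=1))
    return df


def plot_vpc(result: VPCResult, path, max_panels: int = 36) -> None:
    """Time-course overlay per trial: observed points on 2.5/50/97.5 bands."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    trials = list(dict.fromkeys(result.bands["trial_id"]))[:max_panels]
    ncol = int(np.ceil(np.sqrt(len(trials))))
    nrow = int(np.ceil(len(trials) / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(3 * ncol, 2.4 * nrow), squeeze=False,
        sharex=True, sharey=True,
    )
    for ax, trial in zip(axes.flat, trials):
        sub = result.bands[result.bands["trial_id"] == trial]
        for arm, g in sub.groupby("arm_id"):
            g = g.sort_values("time")
            ax.fill_between(g["time"], g["sim_p2.5"], g["sim_p97.5"], alpha=0.2)
            ax.plot(g["time"], g["sim_p50"], lw=1)
            ax.plot(g["time"], g["observed"], "o", ms=3)
        ax.set_title(trial, fontsize=8)
    for ax in axes.flat[len(trials):]:
        ax.set_visible(False)
    fig.supxlabel("week")
    fig.supylabel("proportion responding")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
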