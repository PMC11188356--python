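"""Maximum-likelihood estimation of the longitudinal binomial logit models.

Two observation models are provided: the exact arm-level binomial likelihood
(default; self-weighting and well defined at extreme proportions) and a
weighted-normal approximation on observed proportions with residual standard
deviation ``sigma * sqrt(P(1-P)/N)`` and optional AR1 / compound-symmetry
autocorrelation across visits within an arm.  The arm-level random effect
``eta ~ N(0, omega^2)`` on the logit linear predictor is integrated out by
adaptive Gauss-Hermite quadrature (mode/curvature-rescaled nodes; a Laplace
approximation is available).  Optimization is bounded quasi-Newton (L-BFGS-B)
with seeded, jittered restarts since exponential-onset likelihoods can be
multimodal in the rate constants.
"""

from __future__ import annotations

import copy
import fnmatch
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import chi2
from statsmodels.tools.numdiff import approx_hess

from .data import ArmDescriptor, ObservationRecord
from .model import ModelSpec, rcs_basis

logger = logging.getLogger(__name__)

__all__ = [
    "ObjectiveConfig", "FitResult", "binomial_loglik",
    "weighted_normal_objective", "marginal_loglik", "fit_model",
    "compare_models", "stepwise_covariates",
]


@dataclass
class ObjectiveConfig:
    likelihood: str = "binomial"  # binomial | weighted_normal
    integration: str = "aghq"  # aghq | laplace
    quad_points: int = 9
    #: fnmatch patterns of parameter names held at their initial values
    fixed_params: tuple = ("*.gamma",)
    bounds: dict = field(default_factory=dict)
    seed: int = 0
    tol: float = 1e-8
    n_restarts: int = 5
    jitter: float = 0.15
    prob_floor: float = 1e-8
    maxiter: int = 2000

    def __post_init__(self) -> None:
        if self.quad_points < 1:
            raise ValueError("quad_points >= 1 required")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.likelihood not in ("binomial", "weighted_normal"):
            raise ValueError(f"unknown likelihood {self.likelihood!r}")
        if self.integration not in ("aghq", "laplace"):
            raise ValueError(f"unknown integration {self.integration!r}")


@dataclass
class FitResult:
    model: ModelSpec
    loglik: float
    n_params: int
    aic: float
    vcov: pd.DataFrame | None
    cis: dict
    converged: bool
    n_obs: int
    trace: list
    estimates: dict
    se: dict = field(default_factory=dict)

    @property
    def param_names(self) -> list[str]:
        return list(self.estimates)


# ---------------------------------------------------------------------------
# parameter packing


_DEFAULT_BOUNDS = [
    ("placebo.B", (-80.0, 20.0)),
    ("placebo.A", (-30.0, 130.0)),
    ("placebo.k_pbo", (1e-4, 10.0)),
    ("placebo.c*", (-60.0, 60.0)),
    ("onset.*", (1e-4, 10.0)),
    ("drug.*.ED50", (1e-6, 1e5)),
    ("drug.*.gamma", (0.1, 10.0)),
    ("drug.*.slope", (-5.0, 5.0)),
    ("drug.*", (-12.0, 12.0)),
    ("cov.*", (-25.0, 25.0)),
    ("omega2", (0.0, 4.0)),
    ("sigma", (1e-3, 100.0)),
    ("rho", (-0.99, 0.99)),
]


def _default_bound(name: str):
    for pat, b in _DEFAULT_BOUNDS:
        if fnmatch.fnmatch(name, pat):
            return b
    return (-np.inf, np.inf)


class ParameterPacker:
    """Bidirectional map between a ModelSpec and a flat parameter vector.

    Parameter names: ``placebo.B``, ``placebo.c0``..., ``drug.<name>.Emax``
    (``drug.<name>.Emax[<tag>]`` for regimen overrides), ``drug.<name>.slope``,
    ``onset.<group>`` (one shared rate constant per onset group),
    ``cov.<covariate>.<target>``, ``omega2``, ``sigma``, ``rho``.  Patterns in
    ``cfg.fixed_params`` freeze parameters at their initial values.
    """

    def __init__(self, init: ModelSpec, cfg: ObjectiveConfig):
        init.validate()
        self.model = copy.deepcopy(init)
        self.cfg = cfg
        self._setters: dict = {}
        names: list[str] = []
        values: list[float] = []

        def add(name, value, setter):
            names.append(name)
            values.append(float(value))
            self._setters[name] = setter

        pl = self.model.placebo
        if pl.form == "exponential":
            add("placebo.B", pl.B, lambda v: setattr(pl, "B", v))
            add("placebo.A", pl.A, lambda v: setattr(pl, "A", v))
            add("placebo.k_pbo", pl.k_pbo, lambda v: setattr(pl, "k_pbo", v))
        elif pl.form == "rcs":
            for i in range(len(pl.spline_coeffs)):
                add(f"placebo.c{i}", pl.spline_coeffs[i],
                    lambda v, i=i: pl.spline_coeffs.__setitem__(i, v))
        else:
            for i in range(len(pl.poly_coeffs)):
                add(f"placebo.c{i}", pl.poly_coeffs[i],
                    lambda v, i=i: pl.poly_coeffs.__setitem__(i, v))

        onset_groups: dict[str, list] = {}
        for d in sorted(self.model.drugs, key=lambda d: d.drug):
            if d.dose_model in ("emax_flat", "emax"):
                add(f"drug.{d.drug}.Emax", d.Emax,
                    lambda v, d=d: setattr(d, "Emax", v))
                for tag in sorted(d.regimen_overrides):
                    add(f"drug.{d.drug}.Emax[{tag}]", d.regimen_overrides[tag],
                        lambda v, d=d, tag=tag: d.regimen_overrides.__setitem__(tag, v))
            if d.dose_model == "emax":
                add(f"drug.{d.drug}.ED50", d.ED50,
                    lambda v, d=d: setattr(d, "ED50", v))
                add(f"drug.{d.drug}.gamma", d.gamma,
                    lambda v, d=d: setattr(d, "gamma", v))
            if d.dose_model == "linear":
                add(f"drug.{d.drug}.slope", d.slope,
                    lambda v, d=d: setattr(d, "slope", v))
            if d.k_onset is not None:
                group = d.onset_group or d.drug
                onset_groups.setdefault(group, []).append(d)
        for group in sorted(onset_groups):
            members = onset_groups[group]
            ks = {m.k_onset for m in members}
            if len(ks) > 1:
                raise ValueError(
                    f"onset group {group!r} members disagree on k_onset"
                )
            add(f"onset.{group}", members[0].k_onset,
                lambda v, members=members: [setattr(m, "k_onset", v) for m in members])

        seen: dict = {}
        for eff in self.model.covariate_effects:
            base = f"cov.{eff.covariate}.{eff.target}"
            k = seen.get(base, 0)
            seen[base] = k + 1
            name = base if k == 0 else f"{base}.{k}"
            add(name, eff.theta, lambda v, eff=eff: setattr(eff, "theta", v))

        add("omega2", self.model.omega2,
            lambda v: setattr(self.model, "omega2", v))
        if cfg.likelihood == "weighted_normal":
            add("sigma", self.model.sigma,
                lambda v: setattr(self.model, "sigma", v))
            if self.model.autocorr != "none":
                add("rho", self.model.rho,
                    lambda v: setattr(self.model, "rho", v))

        fixed = [
            any(fnmatch.fnmatch(n, pat) for pat in cfg.fixed_params)
            for n in names
        ]
        self.all_names = names
        self.free_names = [n for n, f in zip(names, fixed) if not f]
        self.x0 = np.array([v for v, f in zip(values, fixed) if not f])
        self.bounds = [
            cfg.bounds.get(n, _default_bound(n)) for n in self.free_names
        ]

    def apply(self, x: np.ndarray) -> ModelSpec:
        for name, v in zip(self.free_names, x):
            self._setters[name](float(v))
        return self.model


# ---------------------------------------------------------------------------
# vectorized model evaluation over a dataset


class Predictor:
    """Precomputed design arrays for fast repeated likelihood evaluation.

    Records are sorted by arm; per-arm segments allow ``reduceat`` sums.
    """

    def __init__(self, records: list[ObservationRecord], arms: list[ArmDescriptor]):
        if not records:
            raise ValueError("no records")
        self.arms = sorted(arms, key=lambda a: a.key)
        index = {a.key: i for i, a in enumerate(self.arms)}
        missing = [r.key for r in records if r.key not in index]
        if missing:
            raise ValueError(f"records reference unknown arms: {missing[:3]}")
        recs = sorted(records, key=lambda r: (index[r.key], r.time))
        self.records = recs
        self.R = len(recs)
        self.M = len(self.arms)
        self.t = np.array([r.time for r in recs])
        self.N = np.array([r.n_total for r in recs], dtype=float)
        self.n = np.array([r.n_response for r in recs], dtype=float)
        self.arm_idx = np.array([index[r.key] for r in recs])
        self.logC = (
            gammaln(self.N + 1) - gammaln(self.n + 1) - gammaln(self.N - self.n + 1)
        )
        # segment starts for reduceat (arms with records, in order)
        self.seg_starts = np.searchsorted(self.arm_idx, np.arange(self.M))
        self.dose = np.array(
            [self.arms[i].dose_amount for i in self.arm_idx], dtype=float
        )
        # per-drug record groups: drug -> (indices, regimen tags present)
        self.drug_groups: dict[str, np.ndarray] = {}
        self.tag_groups: dict[tuple[str, str], np.ndarray] = {}
        drugs_per_rec = [self.arms[i].drug for i in self.arm_idx]
        tags_per_rec = [self.arms[i].regimen_tag for i in self.arm_idx]
        for drug in sorted(set(drugs_per_rec)):
            if drug == "placebo":
                continue
            sel = np.array([d == drug for d in drugs_per_rec])
            self.drug_groups[drug] = np.flatnonzero(sel)
            for tag in sorted({t for t, d in zip(tags_per_rec, drugs_per_rec)
                               if d == drug and t}):
                tsel = sel & np.array([t == tag for t in tags_per_rec])
                self.tag_groups[(drug, tag)] = np.flatnonzero(tsel)
        self._cov_cache: dict[str, np.ndarray] = {}
        self._basis_cache: dict[tuple, np.ndarray] = {}

    # -- helpers ------------------------------------------------------------

    def _cov_values(self, name: str) -> np.ndarray:
        if name not in self._cov_cache:
            vals = []
            for a in self.arms:
                v = a.covariates.get(name)
                if v is None:
                    raise ValueError(
                        f"covariate {name!r} missing for arm {a.arm_id}; "
                        "impute before fitting"
                    )
                vals.append(v)
            self._cov_cache[name] = np.array(vals, dtype=float)
        return self._cov_cache[name]

    def _adjustments(self, model: ModelSpec, target: str):
        factor = np.ones(self.M)
        offset = np.zeros(self.M)
        for eff in model.covariate_effects:
            if eff.target != target:
                continue
            v = self._cov_values(eff.covariate)
            if eff.form == "additive":
                offset += (v - eff.cov_mean) * eff.theta
            else:
                if np.any(v <= 0):
                    raise ValueError(
                        f"power covariate {eff.covariate!r} needs values > 0"
                    )
                factor *= (v / eff.cov_mean) ** eff.theta
        return factor, offset

    def _basis(self, knots) -> np.ndarray:
        key = tuple(knots)
        if key not in self._basis_cache:
            self._basis_cache[key] = rcs_basis(self.t, knots)
        return self._basis_cache[key]

    # -- linear predictor at eta = 0 ----------------------------------------

    def linpred(self, model: ModelSpec) -> np.ndarray:
        pl = model.placebo
        factor, offset = self._adjustments(model, "placebo_asymptote")
        if pl.form == "exponential":
            asy = (pl.B + pl.A) * factor + offset
            A_arm = asy - pl.B
            e0 = pl.B + A_arm[self.arm_idx] * (1.0 - np.exp(-pl.k_pbo * self.t))
        elif pl.form == "rcs":
            c = np.asarray(pl.spline_coeffs)
            varying = self._basis(pl.knots) @ c[1:]
            e0 = c[0] + varying * factor[self.arm_idx] + offset[self.arm_idx]
        else:
            c = np.asarray(pl.poly_coeffs)
            varying = sum(ci * self.t ** (i + 1) for i, ci in enumerate(c[1:]))
            e0 = c[0] + varying * factor[self.arm_idx] + offset[self.arm_idx]

        dfac, doff = self._adjustments(model, "drug_emax")
        ed = np.zeros(self.R)
        for drug, idx in self.drug_groups.items():
            spec = model.drug_spec(drug)
            dose = self.dose[idx]
            if spec.dose_model == "emax_flat":
                mag = np.full(idx.shape, float(spec.Emax))
            elif spec.dose_model == "emax":
                g = spec.gamma
                mag = spec.Emax * dose**g / (dose**g + spec.ED50**g)
            else:
                mag = spec.slope * dose
            ed[idx] = mag
        for (drug, tag), idx in self.tag_groups.items():
            spec = model.drug_spec(drug)
            if tag in spec.regimen_overrides and spec.dose_model != "linear":
                ed[idx] = float(spec.regimen_overrides[tag])
        active = self.dose > 0
        ed = np.where(
            active, ed * dfac[self.arm_idx] + doff[self.arm_idx], 0.0
        )
        for drug, idx in self.drug_groups.items():
            spec = model.drug_spec(drug)
            if spec.k_onset is not None:
                ed[idx] = ed[idx] * (1.0 - np.exp(-spec.k_onset * self.t[idx]))
        return e0 + ed

    # -- conditional binomial log-likelihood --------------------------------

    def _binom_ll_records(self, lp, floor):
        """Per-record binomial log-likelihood; ``lp`` may be (R,) or (R, Q)."""
        P = expit(lp)
        P = np.clip(P, floor, 1.0 - floor)
        if lp.ndim == 2:
            return (
                self.logC[:, None]
                + self.n[:, None] * np.log(P)
                + (self.N - self.n)[:, None] * np.log1p(-P)
            )
        return self.logC + self.n * np.log(P) + (self.N - self.n) * np.log1p(-P)

    def _per_arm(self, rec_vals: np.ndarray) -> np.ndarray:
        """Sum per-record values into per-arm sums (handles (R,) or (R, Q))."""
        return np.add.reduceat(rec_vals, self.seg_starts, axis=0)

    def binomial_conditional(self, model, eta_arm, floor=1e-8) -> float:
        lp = self.linpred(model) + np.asarray(eta_arm)[self.arm_idx]
        return float(np.sum(self._binom_ll_records(lp, floor)))

    # -- weighted normal conditional ----------------------------------------

    def _corr_inv(self, model):
        """Per-visit-count correlation inverse and log-determinant."""
        out = {}
        counts = np.diff(np.append(self.seg_starts, self.R))
        for m in sorted(set(counts)):
            if model.autocorr == "ar1":
                Rm = model.rho ** np.abs(
                    np.subtract.outer(np.arange(m), np.arange(m))
                )
            elif model.autocorr == "cs":
                Rm = np.full((m, m), model.rho) + (1 - model.rho) * np.eye(m)
            else:
                Rm = np.eye(m)
            sign, logdet = np.linalg.slogdet(Rm)
            if sign <= 0:
                raise np.linalg.LinAlgError(
                    "singular residual correlation matrix"
                )
            out[m] = (np.linalg.inv(Rm), logdet)
        return out, counts

    def weighted_normal_conditional(self, model, eta_arm, floor=1e-8) -> float:
        lp = self.linpred(model) + np.asarray(eta_arm)[self.arm_idx]
        P = np.clip(expit(lp), floor, 1 - floor)
        y = self.n / self.N
        d = P * (1 - P) / self.N  # squared weight
        resid = (y - P) / np.sqrt(d)
        corr, counts = self._corr_inv(model)
        s2 = model.sigma**2
        total = 0.0
        for a in range(self.M):
            i0 = self.seg_starts[a]
            m = counts[a]
            Rinv, logdetR = corr[m]
            r = resid[i0:i0 + m]
            quad = r @ Rinv @ r / s2
            logdet = m * np.log(s2) + logdetR + np.sum(np.log(d[i0:i0 + m]))
            total += -0.5 * (m * np.log(2 * np.pi) + logdet + quad)
        return float(total)


# ---------------------------------------------------------------------------
# public objectives


def binomial_loglik(records, arms, model: ModelSpec, eta_by_arm: dict,
                    prob_floor: float = 1e-8) -> float:
    """Exact binomial log-likelihood conditional on per-arm eta values.

    ``eta_by_arm`` maps (trial_id, arm_id) to a logit offset; every arm with
    records must have an entry.
    """
    pred = Predictor(records, arms)
    try:
        eta = np.array([eta_by_arm[a.key] for a in pred.arms])
    except KeyError as exc:
        raise KeyError(f"missing eta for arm {exc}") from exc
    return pred.binomial_conditional(model, eta, prob_floor)


def weighted_normal_objective(records, arms, model: ModelSpec,
                              eta_by_arm: dict | None = None) -> float:
    """Gaussian log-likelihood of observed proportions with binomial-SE
    weights ``sigma*sqrt(P(1-P)/N)`` and the configured autocorrelation."""
    pred = Predictor(records, arms)
    if eta_by_arm is None:
        eta = np.zeros(pred.M)
    else:
        eta = np.array([eta_by_arm[a.key] for a in pred.arms])
    return pred.weighted_normal_conditional(model, eta)


def _marginal_from_pred(pred: Predictor, model: ModelSpec,
                        cfg: ObjectiveConfig) -> float:
    floor = cfg.prob_floor
    omega2 = model.omega2
    lp = pred.linpred(model)
    if omega2 <= 1e-12:
        if cfg.likelihood == "weighted_normal":
            return pred.weighted_normal_conditional(model, np.zeros(pred.M), floor)
        return float(np.sum(pred._binom_ll_records(lp, floor)))

    if cfg.likelihood == "weighted_normal":
        # plain Gauss-Hermite on the prior scale (the Gaussian conditional is
        # comparatively flat in eta)
        x, w = hermgauss(cfg.quad_points)
        nodes = np.sqrt(2.0 * omega2) * x
        lls = np.stack(
            [_wn_per_arm(pred, model, np.full(pred.M, e), floor) for e in nodes]
        )  # (Q, M)
        return float(np.sum(logsumexp(lls.T + np.log(w / np.sqrt(np.pi)), axis=1)))

    # binomial likelihood: adaptive GH centered at the per-arm mode
    eta = np.zeros(pred.M)
    for _ in range(60):
        P = expit(lp + eta[pred.arm_idx])
        g = pred._per_arm(pred.n - pred.N * P) - eta / omega2
        h = -pred._per_arm(pred.N * P * (1.0 - P)) - 1.0 / omega2
        step = g / h
        step = np.clip(step, -1.0, 1.0)
        eta = eta - step
        if np.max(np.abs(step)) < 1e-12:
            break
    P = expit(lp + eta[pred.arm_idx])
    h = -pred._per_arm(pred.N * P * (1.0 - P)) - 1.0 / omega2
    sd = 1.0 / np.sqrt(-h)

    def logjoint(eta_nodes):  # (M, Q) -> (M, Q)
        lls = pred._binom_ll_records(
            lp[:, None] + eta_nodes[pred.arm_idx, :], floor
        )
        per_arm = pred._per_arm(lls)
        prior = (
            -0.5 * eta_nodes**2 / omega2 - 0.5 * np.log(2 * np.pi * omega2)
        )
        return per_arm + prior

    if cfg.integration == "laplace":
        lj = logjoint(eta[:, None])[:, 0]
        return float(np.sum(lj + 0.5 * np.log(2 * np.pi) + np.log(sd)))

    x, w = hermgauss(cfg.quad_points)
    nodes = eta[:, None] + np.sqrt(2.0) * sd[:, None] * x[None, :]
    lj = logjoint(nodes)
    # AGHQ: integral = sqrt(2)*sd * sum_q w_q exp(x_q^2) f(node_q)
    arm_ll = logsumexp(lj + (x**2 + np.log(w))[None, :], axis=1) + 0.5 * np.log(
        2.0
    ) + np.log(sd)
    if not np.all(np.isfinite(arm_ll)):
        bad = [pred.arms[i].arm_id for i in np.flatnonzero(~np.isfinite(arm_ll))]
        raise FloatingPointError(f"non-finite integrand for arms {bad[:3]}")
    return float(np.sum(arm_ll))


def _wn_per_arm(pred, model, eta, floor):
    """Per-arm weighted-normal conditional log-likelihoods."""
    lp = pred.linpred(model) + np.asarray(eta)[pred.arm_idx]
    P = np.clip(expit(lp), floor, 1 - floor)
    y = pred.n / pred.N
    d = P * (1 - P) / pred.N
    resid = (y - P) / np.sqrt(d)
    corr, counts = pred._corr_inv(model)
    s2 = model.sigma**2
    out = np.empty(pred.M)
    for a in range(pred.M):
        i0 = pred.seg_starts[a]
        m = counts[a]
        Rinv, logdetR = corr[m]
        r = resid[i0:i0 + m]
        quad = r @ Rinv @ r / s2
        logdet = m * np.log(s2) + logdetR + np.sum(np.log(d[i0:i0 + m]))
        out[a] = -0.5 * (m * np.log(2 * np.pi) + logdet + quad)
    return out


def marginal_loglik(records, arms, model: ModelSpec,
                    cfg: ObjectiveConfig | None = None) -> float:
    """Marginal log-likelihood with eta integrated out per arm.

    ``omega2 = 0`` reduces exactly to the conditional likelihood at eta = 0.
    """
    cfg = cfg or ObjectiveConfig()
    if model.omega2 < 0:
        raise ValueError("omega2 must be >= 0")
    return _marginal_from_pred(Predictor(records, arms), model, cfg)


# ---------------------------------------------------------------------------
# fitting


def fit_model(records, arms, init: ModelSpec,
              cfg: ObjectiveConfig | None = None) -> FitResult:
    """Maximize the marginal likelihood from ``init`` by bounded quasi-Newton.

    Honors ``cfg.fixed_params`` (e.g. Hill gamma, covariate thetas);
    deterministic given ``cfg.seed`` and the initial values.  Wald 95%
    intervals come from the inverse Hessian when it is positive definite.
    """
    cfg = cfg or ObjectiveConfig()
    pred = Predictor(records, arms)
    packer = ParameterPacker(init, cfg)
    if len(packer.free_names) > pred.R:
        logger.warning(
            "more free parameters (%d) than observations (%d): "
            "likely unidentifiable", len(packer.free_names), pred.R,
        )

    def nll(x):
        model = packer.apply(x)
        try:
            return -_marginal_from_pred(pred, model, cfg)
        except (FloatingPointError, np.linalg.LinAlgError):
            return 1e12

    rng = np.random.default_rng(cfg.seed)
    lo = np.array([b[0] for b in packer.bounds])
    hi = np.array([b[1] for b in packer.bounds])
    trace = []
    best = None
    for restart in range(max(1, cfg.n_restarts)):
        if restart == 0:
            x0 = packer.x0.copy()
        else:
            scale = np.maximum(np.abs(packer.x0), 0.1)
            x0 = packer.x0 + cfg.jitter * scale * rng.standard_normal(
                packer.x0.shape
            )
        x0 = np.clip(x0, lo, hi)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = optimize.minimize(
                nll, x0, method="L-BFGS-B", bounds=packer.bounds,
                options={"maxiter": cfg.maxiter, "ftol": cfg.tol},
            )
        trace.append(
            {"restart": restart, "loglik": -float(res.fun),
             "success": bool(res.success), "nit": int(res.nit),
             "message": str(res.message)}
        )
        if best is None or res.fun < best.fun:
            best = res
    converged = any(t["success"] for t in trace) and best.fun < 1e11

    xhat = best.x
    model_hat = copy.deepcopy(packer.apply(xhat))
    loglik = -float(best.fun)
    k = len(packer.free_names)
    aic = -2.0 * loglik + 2.0 * k

    vcov = None
    cis: dict = {}
    se: dict = {}
    if converged and k > 0:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                H = approx_hess(xhat, nll)
            eigs = np.linalg.eigvalsh(H)
            if np.all(eigs > 0):
                V = np.linalg.inv(H)
                vcov = pd.DataFrame(
                    V, index=packer.free_names, columns=packer.free_names
                )
                sd = np.sqrt(np.diag(V))
                for name, est, s in zip(packer.free_names, xhat, sd):
                    se[name] = float(s)
                    cis[name] = (float(est - 1.959964 * s),
                                 float(est + 1.959964 * s))
        except (np.linalg.LinAlgError, FloatingPointError):
            pass

    estimates = {n: float(v) for n, v in zip(packer.free_names, xhat)}
    return FitResult(
        model=model_hat, loglik=loglik, n_params=k, aic=aic, vcov=vcov,
        cis=cis, converged=converged, n_obs=pred.R, trace=trace,
        estimates=estimates, se=se,
    )


def compare_models(fit_a: FitResult, fit_b: FitResult) -> dict:
    """Likelihood-ratio test of nested fits (b extends a) plus AIC difference.

    Non-nested pairs are flagged and compared by AIC only.
    """
    nested = set(fit_a.param_names) <= set(fit_b.param_names)
    out = {
        "nested": nested,
        "delta_aic": fit_b.aic - fit_a.aic,
        "delta_loglik": fit_b.loglik - fit_a.loglik,
    }
    if nested:
        stat = 2.0 * (fit_b.loglik - fit_a.loglik)
        df = fit_b.n_params - fit_a.n_params
        out["lrt_stat"] = stat
        out["df"] = df
        if df > 0:
            out["p_value"] = float(chi2.sf(max(stat, 0.0), df))
        else:
            out["p_value"] = 1.0 if stat <= 0 else 0.0
    return out


def stepwise_covariates(records, arms, base: ModelSpec, candidates,
                        cfg: ObjectiveConfig | None = None,
                        alpha: float = 0.05):
    """Forward stepwise covariate selection by LRT p-value and AIC.

    Each round fits every remaining candidate effect added to the current
    model; the smallest-p candidate is accepted if ``p < alpha`` and the AIC
    improves, otherwise selection stops.  Returns (final FitResult, log).
    """
    cfg = cfg or ObjectiveConfig()
    current = fit_model(records, arms, base, cfg)
    remaining = list(candidates)
    log: list[dict] = []
    round_no = 0
    while remaining:
        round_no += 1
        fits = []
        for cand in remaining:
            spec = copy.deepcopy(current.model)
            spec.covariate_effects = spec.covariate_effects + [copy.deepcopy(cand)]
            try:
                fit = fit_model(records, arms, spec, cfg)
            except (ValueError, FloatingPointError) as exc:
                logger.warning("candidate %s/%s failed: %s",
                               cand.covariate, cand.target, exc)
                log.append({"round": round_no, "candidate": _cand_name(cand),
                            "status": "error", "message": str(exc)})
                continue
            if not fit.converged:
                logger.warning("candidate %s/%s did not converge; skipped",
                               cand.covariate, cand.target)
                log.append({"round": round_no, "candidate": _cand_name(cand),
                            "status": "nonconverged"})
                continue
            cmp = compare_models(current, fit)
            log.append({
                "round": round_no, "candidate": _cand_name(cand),
                "status": "fitted", "loglik": fit.loglik, "aic": fit.aic,
                "p_value": cmp.get("p_value"),
            })
            fits.append((cmp.get("p_value", 1.0), cand, fit, cmp))
        if not fits:
            break
        fits.sort(key=lambda x: (x[0], _cand_name(x[1])))
        p, cand, fit, cmp = fits[0]
        if p < alpha and cmp["delta_aic"] < 0:
            log.append({"round": round_no, "accepted": _cand_name(cand),
                        "p_value": p, "aic": fit.aic})
            current = fit
            remaining = [c for c in remaining if c is not cand]
        else:
            break
    return current, log


def _cand_name(c) -> str:
    return f"cov.{c.covariate}.{c.target}({c.form})"
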