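"""Fit the clinical-remission model to a synthetic dataset by maximum
likelihood and compare the estimates with the generating values.

The dataset is generated at quarter scale to keep this example fast; the
fit frees the placebo time-course (B, A, k_pbo), all drug effects, the
onset rate constants, and the between-arm variance, holding the covariate
coefficients at their packaged values.
"""

from uc_mbma import ObjectiveConfig, fit_model, load_packaged_model
from uc_mbma.synthetic import generate_dataset, paper_design, perturb_design

truth = load_packaged_model("remission")
design = perturb_design(paper_design(), 0.25)
records, arms = generate_dataset(design, truth, seed=7)

cfg = ObjectiveConfig(fixed_params=("*.gamma", "cov.*"), n_restarts=1, seed=1)
fit = fit_model(records, arms, truth, cfg)

print(f"converged: {fit.converged}   loglik {fit.loglik:.1f}   "
      f"AIC {fit.aic:.1f}   ({fit.n_obs} observations)\n")
print(f"{'parameter':<28}{'estimate':>10}{'truth':>10}  wald 95% CI")
truth_vals = {
    "placebo.B": truth.placebo.B, "placebo.A": truth.placebo.A,
    "placebo.k_pbo": truth.placebo.k_pbo,
    "drug.infliximab.Emax": truth.drug_spec("infliximab").Emax,
    "drug.adalimumab.Emax": truth.drug_spec("adalimumab").Emax,
    "onset.adalimumab": truth.drug_spec("adalimumab").k_onset,
    "omega2": truth.omega2,
}
for name, tv in truth_vals.items():
    est = fit.estimates[name]
    ci = fit.cis.get(name)
    ci_s = f"({ci[0]:.3g}, {ci[1]:.3g})" if ci else "--"
    print(f"{name:<28}{est:>10.4g}{tv:>10.4g}  {ci_s}")
print("\nEstimates should sit near the generating values; the placebo "
      "intercept/asymptote pair (B, A) is weakly identified individually "
      "(their sum B+A, the asymptotic placebo logit, is what the data pin "
      "down), mirroring the wide published intervals.  Drug onset rates "
      "can run to their upper bound in single replicates when a dataset "
      "is consistent with instant onset — across replicates the medians "
      "center on the truth.")
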