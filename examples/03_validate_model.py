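"""Validate a fitted model: visual predictive check, residual diagnostics,
and a small stratified-arm bootstrap.

Data are simulated from the packaged remission model itself, so the VPC
coverage should sit near the nominal 95% and the weighted residuals near
mean 0 — this is a calibration check of the machinery, not evidence about
real data.
"""

from uc_mbma import (ObjectiveConfig, bootstrap, load_packaged_model,
                     residual_diagnostics, vpc)
from uc_mbma.synthetic import generate_dataset, paper_design, perturb_design

truth = load_packaged_model("remission")
design = perturb_design(paper_design(), 0.25)
records, arms = generate_dataset(design, truth, seed=11)

v = vpc(records, arms, truth, n_sim=500, seed=1)
print(f"VPC: {v.coverage:.1%} of {len(v.bands)} observations inside the "
      "simulated 95% band (nominal 95%)")

resid = residual_diagnostics(records, arms, truth)
print(f"conditional weighted residuals: mean {resid.attrs['residual_mean']:+.3f}, "
      f"variance {resid.attrs['residual_var']:.3f} (ideal: 0 and 1)")

cfg = ObjectiveConfig(fixed_params=("*.gamma", "cov.*"), n_restarts=1, seed=2)
boot = bootstrap(records, arms, truth, cfg, n=8, seed=5)
print(f"\nbootstrap ({boot.resampling_unit}): "
      f"{boot.n_converged}/{boot.n_requested} replicates converged")
for name in ("drug.infliximab.Emax", "placebo.k_pbo"):
    lo, hi = boot.percentile_cis[name]
    print(f"  {name:<24} median {boot.medians[name]:.3f}  "
          f"95% percentile CI ({lo:.3f}, {hi:.3f})")
print("Medians should sit near the generating values "
      "(infliximab Emax 1.48, k_pbo 0.66 per week).")
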