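endpoint: endoscopic
placebo:
  form: rcs
  poly_coeffs: []
  spline_coeffs:
  - -1.734484
  - 0.043674
  - -0.066658
  knots:
  - 2.0
  - 8.0
  - 24.0
drugs:
- drug: infliximab
  dose_model: emax_flat
  Emax: 1.22
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 350.0
- drug: adalimumab
  dose_model: emax_flat
  Emax: 0.586
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 160.0
- drug: golimumab
  dose_model: emax_flat
  Emax: 1.12
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 200.0
- drug: vedolizumab
  dose_model: emax_flat
  Emax: 1.18
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 300.0
- drug: etrolizumab
  dose_model: emax_flat
  Emax: 0.715
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 105.0
- drug: ustekinumab
  dose_model: emax_flat
  Emax: 0.751
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 420.0
- drug: mirikizumab
  dose_model: emax_flat
  Emax: 0.763
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 300.0
- drug: tofacitinib
  dose_model: emax_flat
  Emax: 0.732
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 10.0
- drug: upadacitinib
  dose_model: linear
  gamma: 1.0
  slope: 0.0318
  regimen_overrides: {}
  reference_dose: 45.0
- drug: filgotinib
  dose_model: emax_flat
  Emax: 0.721
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 200.0
- drug: ozanimod
  dose_model: emax_flat
  Emax: 0.348
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 1.0
- drug: etrasimod
  dose_model: linear
  gamma: 1.0
  slope: 0.442
  regimen_overrides: {}
  reference_dose: 2.0
covariate_effects:
- covariate: duration
  target: drug_emax
  form: additive
  theta: -0.000538
  cov_mean: 7.53
- covariate: prior_tnf_pct
  target: drug_emax
  form: additive
  theta: -0.0285
  cov_mean: 22.4
- covariate: duration
  target: placebo_asymptote
  form: power
  theta: -1.24
  cov_mean: 7.53
omega2: 0.05
sigma: 1.0
autocorr: none
rho: 0.0
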