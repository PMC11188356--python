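endpoint: response
placebo:
  form: rcs
  poly_coeffs: []
  spline_coeffs:
  - -1.633073
  - 0.094859
  - -0.133432
  knots:
  - 2.0
  - 8.0
  - 24.0
drugs:
- drug: infliximab
  dose_model: emax_flat
  Emax: 1.03
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 350.0
- drug: adalimumab
  dose_model: emax_flat
  Emax: 0.704
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 160.0
- drug: golimumab
  dose_model: emax_flat
  Emax: 0.616
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 200.0
- drug: vedolizumab
  dose_model: emax_flat
  Emax: 1.15
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 300.0
- drug: etrolizumab
  dose_model: emax_flat
  Emax: 0.661
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 105.0
- drug: ustekinumab
  dose_model: emax_flat
  Emax: 1.3
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 420.0
- drug: mirikizumab
  dose_model: emax_flat
  Emax: 1.27
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 300.0
- drug: tofacitinib
  dose_model: emax_flat
  Emax: 1.88
  gamma: 1.0
  k_onset: 0.103
  onset_group: jak
  regimen_overrides: {}
  reference_dose: 10.0
- drug: upadacitinib
  dose_model: emax_flat
  Emax: 0.234
  gamma: 1.0
  k_onset: 0.103
  onset_group: jak
  regimen_overrides:
    45mg: 2.9
  reference_dose: 30.0
- drug: filgotinib
  dose_model: linear
  gamma: 1.0
  slope: 0.00687
  k_onset: 0.103
  onset_group: jak
  regimen_overrides: {}
  reference_dose: 200.0
- drug: ozanimod
  dose_model: emax_flat
  Emax: 0.428
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 1.0
- drug: etrasimod
  dose_model: linear
  gamma: 1.0
  slope: 0.544
  regimen_overrides: {}
  reference_dose: 2.0
covariate_effects:
- covariate: duration
  target: drug_emax
  form: power
  theta: -0.829
  cov_mean: 7.53
- covariate: steroid_pct
  target: drug_emax
  form: power
  theta: -0.759
  cov_mean: 46.0
- covariate: age
  target: drug_emax
  form: additive
  theta: -0.00231
  cov_mean: 41.2
- covariate: prior_tnf_pct
  target: placebo_asymptote
  form: additive
  theta: -0.0029
  cov_mean: 22.4
omega2: 0.05
sigma: 1.0
autocorr: none
rho: 0.0
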