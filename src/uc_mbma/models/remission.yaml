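endpoint: remission
placebo:
  form: exponential
  B: -39.26
  A: 37.04
  k_pbo: 0.66
  poly_coeffs: []
  spline_coeffs: []
  knots: []
drugs:
- drug: infliximab
  dose_model: emax_flat
  Emax: 1.48
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 350.0
- drug: adalimumab
  dose_model: emax_flat
  Emax: 0.864
  gamma: 1.0
  k_onset: 0.198
  onset_group: adalimumab
  regimen_overrides: {}
  reference_dose: 160.0
- drug: golimumab
  dose_model: emax_flat
  Emax: 1.35
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 200.0
- drug: vedolizumab
  dose_model: emax_flat
  Emax: 1.24
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 300.0
- drug: etrolizumab
  dose_model: emax_flat
  Emax: 0.859
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 105.0
- drug: ustekinumab
  dose_model: emax_flat
  Emax: 0.864
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 420.0
- drug: mirikizumab
  dose_model: emax_flat
  Emax: 1.06
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 300.0
- drug: tofacitinib
  dose_model: emax_flat
  Emax: 1.15
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 10.0
- drug: filgotinib
  dose_model: emax_flat
  Emax: 1.54
  gamma: 1.0
  k_onset: 0.0476
  onset_group: filgotinib
  regimen_overrides: {}
  reference_dose: 200.0
- drug: upadacitinib
  dose_model: emax_flat
  Emax: 1.35
  gamma: 1.0
  regimen_overrides: {}
  reference_dose: 45.0
- drug: ozanimod
  dose_model: emax_flat
  Emax: 0.934
  gamma: 1.0
  k_onset: 0.0978
  onset_group: ozanimod
  regimen_overrides: {}
  reference_dose: 1.0
covariate_effects:
- covariate: duration
  target: drug_emax
  form: power
  theta: 0.589
  cov_mean: 7.53
- covariate: duration
  target: placebo_asymptote
  form: power
  theta: 0.695
  cov_mean: 7.53
omega2: 0.05
sigma: 1.0
autocorr: none
rho: 0.0
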