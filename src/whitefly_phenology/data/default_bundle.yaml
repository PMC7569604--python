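species: Trialeurodes vaporariorum
metadata:
  species: Trialeurodes vaporariorum (greenhouse whitefly)
  host: potato (cv. Canchan)
  source: constant-temperature life tables at 10-32 C; fecundity curve refit to the
    published mean fecundities
development:
  egg:
    d_min: 4.98
    t_opt: 27.4
    k: 0.15
    link:
      family: loglogistic
      delta: 0.044
  nymph:
    d_min: 9.94
    t_opt: 25.4
    k: 0.11
    link:
      family: loglogistic
      delta: 0.072
  puparium:
    d_min: 3.46
    t_opt: 23.0
    k: 0.24
    link:
      family: weibull
      delta: 0.298
mortality:
  egg:
    h: 3.9e-06
    b: 0.903
    t_opt: 21.8
  nymph:
    h: 6.32e-06
    b: 1.179
    t_opt: 21.8
  puparium:
    h: 0.018
    b: 2.389
    t_opt: 21.8
adult:
  intercept: 0.068
  slope: 0.0405
  factor_female: -0.0106
  factor_male: -0.3615
  senescence_link:
    family: lognormal
    delta: 0.9271
  oviposition_link:
    family: lognormal
    delta: 0.7741
fecundity:
  h: 8.925221
  tl: 14.6882
  bl: 1.625516
  bh: 19.748725
  multiplier: 1.0
  sigma_ln: 0.015824
adjustment:
  mortality_b: 1.3
  adult_time: 2.0
  fecundity: 4.0
sex_ratio: 0.5
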