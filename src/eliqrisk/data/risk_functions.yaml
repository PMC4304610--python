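# Concentration risk functions and survey descriptive statistics per agent
# (54-sample e-liquid market survey).  Sparse agents use empirical
# resampling of the full measurement vector with non-detects as zeros; the
# 1,3-propanediol and ethyl vanillin raw vectors were never published, so
# they are reconstructed synthetically to match the printed incidence,
# mean, SD and concentration range (see synthetic.reconstruct_sparse_vector).
n_samples: 54
agents:
  nicotine:
    unit: mg/ml
    incidence: 0.65
    summary: {mean: 11, median: 6.8, sd: 13}
    risk_function:
      family: normal
      params: [11.023, 13.134]
      truncate: [0, null]
  glycerol:
    unit: g/100g
    incidence: 0.94
    summary: {mean: 37, median: 35, sd: 23}
    range: [0.3, 95]
    risk_function:
      family: weibull_shifted
      params: [1.8104, 44.812]
      shift: -2.8327
      truncate: [0, null]
  1,2-propanediol:
    unit: g/100g
    incidence: 0.94
    summary: {mean: 57, median: 64, sd: 30}
    range: [0.4, 98]
    risk_function:
      family: triangular
      params: [-18.939, 91.8, 100.45]
      truncate: [0, null]
  ethylene glycol:
    unit: g/100g
    incidence: 0.91
    summary: {mean: 10, median: 5, sd: 18}
    risk_function:
      family: loglogistic
      params: [-0.40204, 5.15, 1.8215]
      truncate: [0, null]
  1,3-propanediol:
    unit: g/100g
    incidence: 0.13
    summary: {mean: 0.60, median: 0, sd: 1.7}
    range: [3.3, 10]
    risk_function:
      family: empirical_resample
      reconstruct: {n: 54, n_positive: 7, mean: 0.60, sd: 1.7, lo: 3.3, hi: 10}
  thujone:
    unit: mg/L
    incidence: 0.037
    summary: {mean: 6.7, median: 0, sd: 34}
    risk_function:
      family: empirical_resample
      resample_data: {zeros: 52, values: [183, 178]}
  ethyl vanillin:
    unit: mg/L
    incidence: 0.26
    summary: {mean: 30, median: 0, sd: 68}
    range: [7.7, 335]
    risk_function:
      family: empirical_resample
      reconstruct: {n: 54, n_positive: 14, mean: 30, sd: 68, lo: 7.7, hi: 335}
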