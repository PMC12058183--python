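# Two identical insecticides deployed in sequence: the standard
# strategy-comparison scenario (no decay, fixed sigma, 10-generation
# deployment interval, 10%/8% withdrawal/return thresholds).
# NOTE: sigma.phi3 / sigma.phi4 (linear sigma-vs-mean coefficients) are
# unvalidated placeholder values; only sigma.mode=fixed is calibrated.
insecticides:
- id: i
  z50: 900.0
  kmax: 1.0
  n: 1.0
  omega0: 1.0
  delta_b: 0.0
  delta_r: 0.0
  tau_b: 20.0
  decay_exponent: 2.0
- id: j
  z50: 900.0
  kmax: 1.0
  n: 1.0
  omega0: 1.0
  delta_b: 0.0
  delta_r: 0.0
  tau_b: 20.0
  decay_exponent: 2.0
field_calibration:
  phi1: 0.48
  phi2: 0.15
sigma:
  mode: fixed
  sigma_fixed: 30.0
  phi3: 0.05
  phi4: 25.0
exposure:
  x: 0.7
  m: 0.7
fitness:
  mode: fixed
  female: 0.2
  male: 0.2
genetics:
  h2: 0.2
  beta: 56.234
cross_resistance:
  i:
    j: 0.0
  j:
    i: 0.0
landscape:
  coverage: 0.7
  theta: 0.3
  normalized_mixing: false
cycle:
  d: 0.8
  g: 3
  gmax: 5
strategy:
  kind: sequence
  arsenal:
  - i
  - j
  withdrawal_threshold: 0.1
  return_threshold: 0.08
  deployment_interval: 10
  generation_cap: 500
  generations_per_year: 10
initial_mean: 0.0
n_bins: 1001
mean_survival_integrated: false
immediate_withdrawal: false
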