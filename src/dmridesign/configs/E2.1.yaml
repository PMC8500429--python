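# Illustrative simulated task: tissues differ only in perfusion fraction f
# (0.09 vs 0.12).  IVIM is fitted with both segmented (b_threshold 50 s/mm^2)
# and bound-constrained NLLS; ADC by weighted least squares.  Point-mass
# tissue parameters (all SDs zero) isolate the effect of noise + fitting.
name: E2.1
task:
  positive: Chronic
  negative: Healthy
tissues:
  diffusivity_units: 1e-3 mm^2/s
  distributions:
    - label: Chronic
      model: ivim
      means: {f: 0.12, d_slow: 0.35, d_fast: 123}
      sds:   {f: 0.0, d_slow: 0.0, d_fast: 0.0}
    - label: Healthy
      model: ivim
      means: {f: 0.09, d_slow: 0.35, d_fast: 123}
      sds:   {f: 0.0, d_slow: 0.0, d_fast: 0.0}
design:
  b_values: [0, 10, 20, 40, 80, 100, 200, 400, 600]
  snr: 20
  n_per_tissue: 10000
  seed: 1201
  analyses:
    - method: snlls
      b_threshold: 50
      scores: [f, d_slow, d_fast]
    - method: bcnlls
      scores: [f, d_slow, d_fast]
    - method: wls
      scores: [adc]
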