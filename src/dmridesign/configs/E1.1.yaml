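# Chronic vs healthy sacroiliac bone marrow, IVIM generative model,
# acquisition settings matching the external (Zhao) clinical protocol.
name: E1.1
task:
  positive: Chronic
  negative: Healthy
tissues:
  diffusivity_units: 1e-3 mm^2/s
  distributions:
    - label: Chronic
      model: ivim
      means: {f: 0.12, d_slow: 0.35, d_fast: 124.7}
      sds:   {f: 0.02, d_slow: 0.11, d_fast: 13.7}
    - label: Healthy
      model: ivim
      means: {f: 0.09, d_slow: 0.34, d_fast: 122.7}
      sds:   {f: 0.02, d_slow: 0.09, d_fast: 18.3}
design:
  b_values: [0, 10, 20, 30, 50, 80, 100, 200, 400, 800]
  snr: 150.6
  n_per_tissue: 10000
  seed: 1101
  analyses:
    - method: snlls
      b_threshold: 200
      scores: [f, d_slow, d_fast]
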