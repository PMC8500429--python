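# Active vs chronic sacroiliac lesions, IVIM generative model,
# acquisition settings matching the external (Zhao) clinical protocol.
name: E1.2
task:
  positive: Active
  negative: Chronic
tissues:
  diffusivity_units: 1e-3 mm^2/s
  distributions:
    - label: Active
      model: ivim
      means: {f: 0.12, d_slow: 0.99, d_fast: 123.9}
      sds:   {f: 0.03, d_slow: 0.39, d_fast: 19.9}
    - label: Chronic
      model: ivim
      means: {f: 0.12, d_slow: 0.35, d_fast: 124.7}
      sds:   {f: 0.02, d_slow: 0.11, d_fast: 13.7}
design:
  b_values: [0, 10, 20, 30, 50, 80, 100, 200, 400, 800]
  snr: 150.6
  n_per_tissue: 10000
  seed: 1102
  analyses:
    - method: snlls
      b_threshold: 200
      scores: [f, d_slow, d_fast]
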