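# Inflamed vs normal bone marrow, IVIM generative model, acquisition
# settings matching the in-house (Bray) clinical protocol.  Both the IVIM
# model (bcNLLS) and the simpler ADC model (wLS on the log signal) are
# fitted to the same IVIM-synthesised cohort.
name: E1.4
task:
  positive: Inflamed
  negative: Normal
tissues:
  diffusivity_units: 1e-3 mm^2/s
  distributions:
    - label: Inflamed
      model: ivim
      means: {f: 0.07, d_slow: 1.91, d_fast: 24.2}
      sds:   {f: 0.08, d_slow: 0.56, d_fast: 28.5}
    - label: Normal
      model: ivim
      means: {f: 0.05, d_slow: 0.92, d_fast: 44.6}
      sds:   {f: 0.04, d_slow: 0.26, d_fast: 35.2}
design:
  b_values: [0, 50, 100, 300, 600]
  snr: 56.3
  n_per_tissue: 10000
  seed: 1104
  analyses:
    - method: bcnlls
      scores: [f, d_slow, d_fast]
    - method: wls
      scores: [adc]
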