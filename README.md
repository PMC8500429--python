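# dmridesign

Task-driven, in-silico assessment of quantitative diffusion-MRI
experimental designs.

## The problem

When planning a quantitative dMRI study — which b-values to acquire, which
signal model to fit, which fitting algorithm and SNR to aim for — the usual
computational yardsticks are parameter-estimation metrics: bias, variance,
information criteria. But for classification tasks (e.g. calling a tissue
*diseased* or *healthy* from a fitted parameter), what matters is the
*effect size the design delivers at the end of the whole pipeline*, not
microstructural fidelity. A biased, low-variance model can classify better
than the ground-truth model; the best fitting algorithm can differ from task
to task within a single tissue.

`dmridesign` measures task performance directly by simulating the complete
experiment, start to finish, for any candidate design:

1. **Cohort synthesis** — per-subject tissue parameters are drawn from
   Gaussian distributions (truncated to the physical domain) for two tissue
   classes; noise-free signals are generated from the designated model and
   corrupted with Rician noise at the design's effective SNR; each subject's
   signal is normalised by their own noisy b = 0 measurement.
2. **Parameter estimation** — each noisy signal is fitted with the design's
   method: weighted least squares for ADC, or segmented / bound-constrained
   nonlinear least squares for IVIM.
3. **Task evaluation** — the chosen parameter estimate is used as a
   classification score; sweeping the decision threshold yields an empirical
   ROC curve, its trapezoidal AUC, and (optionally) the distribution of AUC
   over sub-samples matching a small clinical cohort's size.

Designs are then compared on predicted AUC rather than on how well they
recover parameters. Intended users: quantitative MRI methodologists and
clinical researchers choosing protocols, models and fitting methods before
committing to data acquisition.

## Models

Signals are normalised to the b = 0 measurement. The intravoxel incoherent
motion (IVIM) model separates perfusing and non-perfusing water:

    S(b)/S0 = f · exp(−b (D_fast + D_slow)) + (1 − f) · exp(−b D_slow)

with perfusion fraction *f* ∈ [0, 1], tissue diffusivity *D_slow* and
pseudo-diffusivity *D_fast* (mm²/s). The apparent diffusion coefficient
(ADC) model is the mono-exponential `S(b)/S0 = exp(−b · ADC)`. Rician noise
is the magnitude of a complex Gaussian perturbation with σ = S0/SNR.

## Worked example

Six fixture configurations ship with the package (`dmridesign fixtures`
lists them): four mirroring published spondyloarthritis classification
settings against two clinical acquisition protocols (E1.1–E1.4), and two
illustrative simulated tasks (E2.1: tissues differing only in perfusion
fraction, 0.09 vs 0.12; E2.2: tissues differing only in tissue diffusivity,
0.60 vs 0.46 × 10⁻³ mm²/s), both at SNR 20 with nine b-values from 0 to
600 s/mm².

```text
$ dmridesign --quiet run E2.1 --n-subjects 2000
E2.1  snlls_ivim:f             AUC = 0.6295  CNR = 0.2331
E2.1  snlls_ivim:d_slow        AUC = 0.5039  CNR = 0.0123
E2.1  snlls_ivim:d_fast        AUC = 0.5252  CNR = 0.0153
E2.1  bcnlls_ivim:f            AUC = 0.6101  CNR = 0.2162
E2.1  bcnlls_ivim:d_slow       AUC = 0.5144  CNR = 0.0398
E2.1  bcnlls_ivim:d_fast       AUC = 0.5214  CNR = 0.0181
E2.1  wls_adc:adc              AUC = 0.5594  CNR = 0.1523
```

Each line is one (fitting method, score parameter) classifier evaluated on
the same simulated cohort of 2 × 2000 subjects. Reading the numbers: the
perfusion-fraction difference between the tissues is best detected by the
IVIM *f* estimate from the segmented fit (AUC 0.63); classifying on ADC — a
model that does not even contain the parameter that differs — still beats
chance (AUC 0.56) because perfusion leaks into the apparent diffusivity;
and classifying on parameters that do not differ between the tissues
(d_slow, d_fast here) sits at chance level, as it should. CNR is the
standardised mean difference between the two groups' estimate
distributions. Adding `--out results/ --plots` writes a summary JSON, ROC
and estimate tables (CSV), and figures; `--seed` and `--n-subjects`
override the fixture's pinned values.

To rank competing designs that share a task, give `compare` one
(method, parameter) evaluation per config:

```bash
dmridesign compare my_design_a.yaml my_design_b.yaml --out comparison/
```

Config file format is documented in `dmridesign/config.py` and by the
bundled fixtures under `src/dmridesign/configs/`.

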