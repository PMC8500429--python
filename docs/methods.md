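# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind `dmridesign`, in the spirit of a model-documentation page:
what is simulated, what is estimated, what the defaults mean, and what the
simulations can and cannot say about real experiments.

## Simulation model

**One subject = one mean-ROI signal.** The pipeline simulates the summary
measurement a clinical reader would classify: the ROI-averaged signal of one
subject at each b-value. No voxel grid or image is simulated; ROI averaging,
repetitions, TE/TR and voxel size are absorbed into a single *effective SNR*
at b = 0, which is a config input. Consequences: spatial heterogeneity,
partial-volume effects and ROI-placement variability are outside the model,
and an effective SNR must be supplied (the package does not derive it from
images).

**Tissue characterisation.** Each of the two tissue classes is described by
independent Gaussians per model parameter (mean ± SD). Draws violating the
physical domain (f outside [0, 1], negative diffusivities) are rejected and
redrawn, so the effective marginals are truncated Gaussians; this choice
keeps every synthetic subject physically valid and keeps the distribution
unimodal, at the cost of shifting the realised mean when the Gaussian places
substantial mass outside the domain (e.g. f = 0.07 ± 0.08 places ~19% of
mass below 0; the truncated mean is ≈ 0.097). Draw batches whose acceptance
rate falls below 0.1% raise a configuration error rather than loop
indefinitely. Parameters within a subject are drawn independently;
correlations between tissue parameters are not modelled.

**Signal synthesis and noise.** Noise-free signals come from the IVIM
bi-exponential (the fast compartment's exponent carries D_fast + D_slow) or
the ADC mono-exponential. Every measurement, including b = 0, is corrupted
independently with Rician noise of width σ = S0/SNR (S0 = 1 after
normalisation): the magnitude of (N(S, σ²), N(0, σ²)). The signal is then
divided by the subject's *measured noisy* b = 0 value, not the true S0 —
mimicking real processing, where S0 is unknown. This makes the normalised
b > 0 samples slightly heavy-tailed (a ratio of Rician variables) and is the
main reason estimates are not simply "truth + Gaussian error". Noise is
independent across b-values; correlated noise, ghosting and motion are not
modelled.

**Randomness.** Each experiment has a single root seed. It is spawned into
independent `numpy` sub-streams (parameter draws and noise per tissue;
sub-sampling per analysis), so results are bit-reproducible and adding an
analysis does not perturb the cohort.

## Estimators

All fits operate on the normalised signal. Defaults follow standard IVIM
practice: bounds f ∈ [0, 1], D_fast ∈ [0, 500]·10⁻³, D_slow ∈ [0, 10]·10⁻³
mm²/s; iterative fits are seeded with the across-tissue mean of the two
generative parameter means (individual diagnoses are unknown a priori in a
real study, so subject-specific seeding would be cheating).

* **wLS ADC** — weighted linear regression of ln S on b with weights S²
  (the variance-stabilising weights for log-transformed data), solved in
  closed form via the weighted normal equations. The intercept is fitted
  and discarded. Non-positive samples, whose log is undefined, are dropped
  sample-wise; if fewer than two remain, the subject is flagged
  non-converged. A negative fitted ADC (increasing signal with b; only
  possible under extreme noise) is clamped to 0 rather than propagated.
  By default the fit uses all protocol b-values including b = 0; an
  optional `b_subset` restricts it to a sub-scheme.
* **sNLLS IVIM** — segmented fit. Step 1 fits A·exp(−b·D_slow) by bounded
  NLLS to the samples at b ≥ b_threshold (the amplitude A is discarded);
  step 2 fixes D_slow and fits (f, D_fast) to *all* samples against the
  bi-exponential. Both steps run in the linear signal domain under the same
  optimiser, rather than using a log-linear step 1 or deriving f from the
  step-1 intercept; this keeps one noise model across both steps and
  matches seeding with population-mean values. The b_threshold is a design
  input (200 s/mm² for the E1 fixtures, replicating the source protocol's
  choice; 50 s/mm² for E2, better matched to D_fast ≈ 123·10⁻³ mm²/s whose
  fast compartment has decayed by >99% at b = 50). When the threshold is
  too low the perfusion tail contaminates step 1 and biases D_slow upward;
  this bias is measured by the noise-free recovery tests, not assumed away.
* **bcNLLS IVIM** — simultaneous bounded NLLS over (f, D_slow, D_fast) on
  all samples.

**Optimiser contract.** Trust-region reflective least squares
(`scipy.optimize.least_squares`, method `trf`) with analytic Jacobians;
stop when the relative cost change falls below 1e-8 or after 200 function
evaluations. Seeds are clipped strictly inside the bounds (trf requires an
interior start). A failed or non-finished fit never raises mid-cohort: the
subject keeps the seed values with `converged=False` and *remains in the
ROC* — excluding failures would bias the curves; a diagnostic count is
reported. Near-degenerate problems (f·D_fast ≈ 0, constant signals) stop on
a cost plateau, so "zero" parameters come back at the 1e-3–1e-4 scale of
the stopping rule rather than exactly 0.

## Task evaluation

The classifier thresholds one estimated parameter. The empirical ROC is
traced through every distinct score; the trapezoidal AUC equals the
Mann-Whitney statistic with half-credit for ties (ties are real here:
bound-clipped and non-converged estimates pile up at common values). By
default the orientation is *auto* (scores are negated if the raw AUC < 0.5,
and this is recorded), matching clinical ROC reporting; *fixed* orientation
is available so that method comparisons cannot reward sign-flipping on
noise.

Sub-sampled AUC distributions draw n_pos/n_neg scores per group *without
replacement* (a small clinical cohort drawn from a population), 1000
repeats by default, with orientation inherited from the full-sample curve.
The contrast-to-noise ratio reported alongside AUC is the standardised mean
difference |μ₁ − μ₂| / √(σ₁² + σ₂²) of the two estimate distributions —
this package's working definition, stated here because usage in the
literature varies. For Gaussian scores, AUC = Φ(CNR), which the tests use
as an analytic cross-check.

## Fixtures and problem sizes

The bundled configs encode two published spondyloarthritis settings
(chronic/active lesions vs healthy sacroiliac marrow at SNR 150.6 with ten
b-values to 800 s/mm²; inflamed vs normal marrow at SNR 56.3 with five
b-values to 600 s/mm²) and two illustrative one-parameter-contrast tasks at
SNR 20. Default cohort size is 10,000 subjects per tissue, which puts the
Monte-Carlo standard error of an AUC near 0.005; the test suite runs most
end-to-end checks at 2,000 per tissue (AUC SE ≈ 0.01), a size chosen so the
documented orderings between designs remain detectable while a full run of
the suite stays in the minutes range. The E1 fixtures carry no clinical
sub-sample sizes because the per-group patient counts of the source
cohorts are not public; sub-sampling is exercised on the simulated tasks.

## What passing tests do and do not show

The test suite verifies internal correctness (estimators recover noise-free
truth; ROC equals exhaustive pair counting; Rician moments match closed
forms; truncated draws match the analytic truncated Gaussian) and the
qualitative design-assessment findings on the illustrative tasks: both ADC
and IVIM classifiers beat chance on both tasks; IVIM-f beats ADC when the
tissues differ in perfusion, while ADC beats IVIM-D_slow when they differ
in diffusivity (the biased model wins through lower estimation variance);
and the better IVIM fitting method differs between the two tasks. These are
statements about the simulation model above — Gaussian tissue classes,
mean-ROI signals, Rician noise at a stated effective SNR. They transfer to
a real experiment only insofar as those inputs describe it; in particular,
an unrealistic tissue characterisation (I2, in pipeline terms) propagates
directly into the AUC predictions.

## Known limitations

* Direction-averaged signals only; no diffusion tensors, no multi-b-shell
  directional schemes.
* Least-squares fitting only; Rician-likelihood, Bayesian and learning
  based estimators are out of scope.
* Two-class tasks with a single scalar score; no multi-parameter or
  multi-class decision rules.
* No automated design optimisation loop: the package assesses designs it is
  given and ranks them; proposing new candidates is up to the user.
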