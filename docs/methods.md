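# Methods

## The measurement and its model

An egg clamped between parallel-plate electrodes is driven with a small AC
signal and its complex impedance Z(f) = R(f) + jX(f) is read at each
frequency of a 2–300 kHz sweep (beta-dispersion range: membrane and
macromolecule polarisation). Four contact positions around the equator are
measured and averaged pointwise; averaging requires identical frequency
grids and never resamples. Polar decomposition |Z|, θ = atan2(X, R) and the
loss factor D = tan δ = R/|X| (δ = π/2 − |θ|) are provided alongside. The
magnitude convention for D keeps the loss factor non-negative for
capacitive samples (X < 0), which is how tan δ is conventionally reported;
the literal signed ratio would be negative for every egg.

### Equivalent circuits

Two fitted circuits summarise the two gel states:

* **Completely gelled** — series L₁ (218 pH) – Warburg (1/Y₀ = 4.786 MΩ·√s)
  – C₁ (81.67 pF). The solid gel blocks ionic drift, leaving a
  diffusion-limited response: an oblique line in the Nyquist plane.
* **Incompletely gelled** — L₁ (583.7 µH) – R₁ (46.25 Ω) in series with
  R₂ (298.3 kΩ) ∥ CPE (Q₀ = 503.5 ps^n·Ω⁻¹, n = 0.8361). Mobile ions in
  the liquid albumen support charge transfer: a depressed semicircular
  arc whose reactance peak sits near 6 kHz.

The Warburg element uses the finite-length ("short") form
Z = tanh(B√(jω))/(Y₀√(jω)); the printed coefficient is read as the
magnitude 1/Y₀ in SI units, and the diffusion time constant B — for which
no fitted value is available — defaults to 1 √s. Over 2–300 kHz with B = 1
the element is deep in its semi-infinite regime (tanh ≈ 1, −45° phase), so
no downstream result depends on B; a `semi_infinite` switch exposes the
1/(Y₀√(jω)) form for sensitivity analysis. CPE powers use the principal
branch; the exponent limits n = 1, 0, −1 reduce exactly to capacitor,
resistor (1/Q₀) and inductor.

### Circuit fitting

Parameters are estimated by minimising Σ_f w_f |Z_model(f) − Z_obs(f)|²
with modulus weighting w_f = 1/|Z_obs(f)|² (|Z| spans decades over the
band; unit weighting would fit only the low-frequency arc and is available
as an option — "proportional" weighting coincides with modulus weighting
for complex residuals and is accepted as an alias). The search runs on
log₁₀-scaled parameters inside finite positive box bounds, because the
values span 10⁻¹² to 10⁶ in SI units, with 8 Latin-hypercube starts
(deterministic per seed) refined by a trust-region-reflective solver.
Non-convergence is returned as data (`converged=False`), not raised, so
cohort-scale fitting can tally failures. Topology selection fits every
candidate and keeps the smallest weighted residual, breaking ties toward
fewer free parameters.

Identifiability note: R₁ (46 Ω) and L₁ contribute ≲1 kΩ to a ~10⁵ Ω
spectrum over this band, so they are recovered exactly only from noiseless
data; under measurement noise the well-determined parameters are the arc
parameters R₂, Q₀ and n.

### Transient decay rate

Treating the egg as a series RLC circuit, the under-damped free response
is i(t) = A·e^(−αt)·cos(ω_d t + θ) with α = R/(2L), ω₀ = 1/√(LC),
ζ = α/ω₀ and ω_d = ω₀√(1 − ζ²). At 6 kHz the net reactance is capacitive,
so the meter-implied inductance L = X/(2πf) is negative; α and ω₀ use |L|
so the decay rate stays real and non-negative (a `signed=True` flag
preserves the literal formula for auditing). Only the under-damped branch
is exposed; over-damped circuits do not oscillate and are rejected. The
absolute decay rates produced by the printed circuit values (≈10³–10⁴ s⁻¹)
are on a different scale from tapping-test oscillation decays; only the
ordering α_gelled < α_non-gelled is meaningful and asserted.

## Classification

Features are taken at 6 kHz — where the non-gelled reactance arc peaks and
the class contrast in (R, X) is near its largest — interpolating R and X
separately, linearly in log₁₀(f), when 6 kHz is not a grid point
(interpolating the Cartesian parts preserves exactly the quantities the
classifier consumes; extrapolation is refused). The feature set is
{|Z|, R, X, α} with (R, X) the default subset.

The classifier is naive Bayes — the Bayesian-network structure with the
class node as sole parent of each feature node. The Gaussian variant
stores per-class sample means and variances (ddof = 1), with variances
floored at 10⁻⁹·(pooled feature range)² to keep densities proper on
degenerate (e.g. noise-free) cohorts. A discretized variant (10
equal-frequency bins over the pooled training data, Laplace-smoothed
class-conditional counts) is included for fidelity checks, since the
original software's discretization policy is not recoverable. Posteriors
accumulate in the log domain; the label is decided on the raw
(unnormalised) log posteriors so that an exact tie deterministically
yields "gelled". Training follows the fixed 60-train / 116-test design —
no cross-validation.

Evaluation: confusion matrix with "gelled" positive; accuracy, precision,
sensitivity; Cohen's κ = (p₀ − p_c)/(1 − p_c); AUC by the Mann–Whitney
rank statistic (ties ½), which equals trapezoidal ROC integration.
Percentages mirror the field's 1-dp convention and κ its 2-dp convention;
raw fractions are always returned too.

## Synthetic cohorts

No raw egg measurements are publicly available, so the study design is
emulated: each egg draws its circuit parameters around its class preset,
simulates four contact positions on a 50-point log grid over 2–300 kHz,
adds independent proportional complex Gaussian noise (sd 0.02·|Z| per
quadrature component, the simplest model of an LCR meter's joint R/X
reading) and averages positions.

* **Magnitude parameters** (R, L, C, Y₀, B, Q₀) are jittered log-normally
  with sd 0.15 dex. The log-normal's median equals the class centre, and
  0.15 dex makes the single-feature |Z| classifier imperfect (≈80–87%)
  while (R, X) stays near-perfect — qualitatively matching the real-egg
  ordering without pretending to reproduce its exact rates.
* **The CPE exponent n** is a shape parameter, not a magnitude: it is
  perturbed additively (sd 0.02, clipped to (0, 1]). Log-normal jitter of
  0.15 dex on an exponent would span n ≈ 0.4–1.2, producing unphysical
  (n > 1) and non-capacitive eggs that contradict the very band behaviour
  the generator is meant to emulate.

With these defaults every generated egg is capacitive (X < 0) across the
band; gelled traces fall monotonically in |X| and the large majority
(≥ 90%) of non-gelled traces keep their arc peak inside the band — heavy
parameter jitter occasionally pushes the peak below 2 kHz, which real
cohorts would also show as between-egg variation.

What the generator does **not** model: shell thickness and geometry,
electrode contact area, temperature/humidity, egg-yolk heterogeneity, or
any correlation between circuit parameters. Passing tests on synthetic
cohorts therefore demonstrate the pipeline's correctness and the
qualitative class structure, not field performance on real eggs.

## Problem sizes and determinism

Default study sizes are the design's own: 60 training and 116 test eggs,
50 frequencies, 4 positions. The multi-seed comparisons (two-feature vs
one-feature classifier) use 25 independent cohort seeds; the noisy
parameter-recovery study uses 20 replicate fits at 1% noise with 4 starts
each. All randomness in the library flows through explicit
`numpy.random.Generator` seeds; the pipeline and the acceptance script are
bit-reproducible given a seed, and reports embed a provenance block
(version, seed, config hash).

## Known limitations

* The fitted circuits are the only anchor for class-conditional
  distributions; real dispersion and noise levels are unknown, so
  synthetic accuracies are not comparable numerically to real-egg
  accuracies.
* The Warburg B and the gelled circuit's exact Nyquist trace are
  under-determined by the available fitted values.
* Binary classification only; partially gelled grades are out of scope.
* No Kramers–Kronig consistency testing of measured spectra.
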