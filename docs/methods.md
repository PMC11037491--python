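# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, the numerical choices, and what the simulations
do and do not establish.

## Circular representation

Orientation is an axial variable with period 180°. All densities are
semicircular von Mises distributions obtained by angle doubling:
`p(θ; μ, κ) = exp(κ cos 2(θ−μ)) / (π I0(κ))` per radian, which is
uniform (1/π) at κ = 0 and integrates to 1 over any half-turn.
Densities are tabulated per radian on a uniform grid over [0°, 180°)
with a 1° default step (configurable down to 0.25°); integrals are
Riemann sums on that grid, which are spectrally accurate for smooth
periodic integrands. The 1° default matches the enumeration used for
the absolute-orientation sweep, and at that resolution the response
probabilities of interest are converged to well below the tolerances
asserted in the tests.

## Efficient encoding

Coding resources are allocated by frequency of occurrence: the
stimulus-to-sensory mapping is `F(θ) = 180° × CDF(θ)` of the generating
frequency distribution. Sensory space is deliberately rescaled to one
half-turn so that sensory and stimulus concentrations live on a common
scale (the baseline uses κ_sens and κ_stim of comparable magnitude, 18–20)
and so that a uniform environment gives the identity mapping exactly.
The CDF is accumulated with the trapezoidal rule: this keeps
`F(0°) = 0`, keeps uniform → identity exact, preserves the total sweep of
180° by periodicity, and agrees with the analytic CDF of the natural
prior to < 1e-3 degrees at a 1° step (a plain cumulative sum carries an
O(step) bias of ~0.4°, which is visible against a Monte-Carlo simulation
of the measurement equation).

A single measurement is `m = F(θ + δ_stim) + δ_sens` with axial von
Mises stimulus noise in stimulus space and sensory noise in the rescaled
sensory space. The likelihood over hypothesized θ is the grid quadrature
of the convolution of the two noise densities through `F`. Likelihoods
are evaluated at the *expected* measurement `m = F(θ_true)` — the model
produces per-trial response probabilities, not sampled measurements —
so the entire trial-level pipeline is deterministic; stochasticity
enters only in sampled-response mode and in the population draw.

## Two-stage observer

Stage 1 (rectangular lattice): the two-peak likelihood mixes the
component likelihoods for the relative 0° and 90° measurements with
weights `1/(1+w_AR)` and `w_AR/(1+w_AR)`, `w_AR = AR^c_stim`. Components
are mixed on the raw measurement-density scale (no per-component
renormalization over θ): this is the literal reading of the mixture
equations; with the uniform prior it coincides with the renormalized
variant for lattice 1 by symmetry, and for lattice 2 it reinforces
repulsion, because components falling in high-resolution regions of
sensory space carry less stimulus-space mass.

Between stages, two summaries are carried forward:

* stimulus frequency `(1−w_stimL1)·prior + w_stimL1·posterior_L1`,
  which regenerates `F` for stage 2 (adaptation route);
* perceptual prior `(1−w_percL1)·prior + w_percL1·vm(r̂1, κ_percL1)`,
  which multiplies the stage-2 likelihood (hysteresis route). The
  complement of the percept bump mixes with the *lattice-1 prior
  density* (the form of the mixture equation), not with a flat density;
  the two coincide for the uniform prior.

Stage 2 (hexagonal lattice): equal-weight three-peak likelihood at the
relative 0°/60°/120° measurements with κ_stimL2/κ_sensL2. Response
probabilities read the posterior *density values at the exact candidate
orientations* (nearest grid point; absolute orientations are constrained
to grid multiples and snapped with a warning otherwise), per the
response rule; no integration window is applied.

Variants: `stimulus_prior` replaces the perceptual prior by the stimulus
frequency distribution (no percept information → hysteresis is exactly
zero). `no_efficient_coding` fixes the identity mapping for both
lattices while keeping the perceptual prior (no mapping asymmetry → the
stage-2 curve is exactly flat in AR). In the `stimulus_prior` variant
the net AR slope of the stage-2 curve is a balance of prior attraction
and likelihood repulsion; under this package's density-reading
convention attraction dominates at the baseline weights, so that
variant's *sign* of the net AR effect is not treated as a model
prediction — only the exact ablation identities are.

## Parameters

| name | meaning | baseline |
|---|---|---|
| c_stim | aspect-ratio sensitivity exponent | 5 |
| κ_stimL1, κ_stimL2 | stimulus precision per lattice (peak width, no asymmetry) | 20, 20 |
| κ_sensL1, κ_sensL2 | sensory precision per lattice (controls likelihood asymmetry) | 20, 18 |
| κ_percL1 | precision of the percept bump in the perceptual prior | 10 |
| w_stimL1 | weight of stage-1 evidence in the stimulus frequency distribution | 0.60 |
| w_percL1 | weight of the stage-1 percept in the perceptual prior | 0.50 |

κ_sensL2 < κ_sensL1 encodes the shorter presentation of the second
lattice (300 vs 800 ms); it is recommended, warned about when violated,
but not enforced. With the uniform prior, κ_stimL1 and κ_sensL1 cancel
from the stage-1 posterior ratio, so the proximity curve is exactly
`p(0°|L1) = 1/(1 + AR^c_stim)` — a useful closed-form check (the GLM
proximity slope equals −c_stim).

With the uniform prior all probabilities are rotation invariant, so a
single representative absolute orientation φ = 0° is computed; with the
natural prior the full 1°-step sweep over φ runs and probabilities are
averaged.

## Experiment and population simulation

The design crosses the seven aspect ratios 1.3⁻¹ … 1.3 (symmetric on
the log scale) with the absolute orientations above. Expected-frequency
mode writes `n·p(r1)·p(r2|r1)` per cell (n = 100 per cell by default — a
declared choice, ample for stable GLM fits; expected-mode point
estimates are invariant to n up to weighting). Sampled mode draws
seeded multinomials and refuses to run without a seed.

The population draws (c_stim, w_stimL1_raw, w_percL1_raw) for 75
individuals from a truncated multivariate normal, means (5, 6.5, 5),
bounds [0, ∞) × [0, 10]², raw weights then divided by 10. The
covariance is diag(25, 9, 9) with covariance 8.95 (correlation ≈ 0.994)
between the two raw weights and none with c_stim. This matrix is an
*interpretation*: the printed source is typographically garbled, and
this reading matches the stated dimensionality and the positively
correlated weight generation. Sampling is by rejection from the
unconstrained normal (exact; acceptance ≈ 0.6 at the default spec, with
a guard that aborts below 1e-4 acceptance).

## Effect estimation

Per individual, binomial GLMs with logit link on counts:
`logit p(r1=0) ~ 1 + centered log AR` (proximity) and
`logit p(r2=0) ~ 1 + centered log AR + contrast(r1)` with ±0.5 coding
(adaptation, hysteresis — the ±0.5 coding makes the hysteresis
coefficient read directly as the full 0°-vs-90° logit difference).
Centered log AR is the natural predictor scale because the printed AR
grid is symmetric on it. Fits are maximum likelihood (IRLS, tolerance
1e-12); complete separation triggers a flagged ridge-penalized fallback
(L2, α = 1e-6) with NaN standard errors. This per-individual GLM +
bootstrap scheme deliberately replaces a Bayesian multilevel regression:
point estimates target the same slopes without partial pooling, which is
sufficient for sign and correlation statements at these simulated sample
sizes (it does not reproduce shrinkage or posterior intervals).

Cross-individual structure is summarized by Pearson correlations among
the three effects with percentile bootstrap CIs (2000 resamples of
individuals, seeded). At the default population the simulation yields a
clear positive hysteresis–adaptation correlation (bootstrap CI excluding
zero), a strong negative adaptation–proximity correlation (both inherit
c_stim), and a near-zero hysteresis–proximity correlation; the exact
values vary with the population seed and are recomputed, not asserted as
constants.

## What the synthetic data does and does not emulate

The generator reproduces the *structure* of the behavioral task (AR
levels, two-then-three alternative responses, percept-conditioned
second-lattice trials) and plausible individual variation in three
parameters. It does not emulate lapses, response bias, the four-choice
response interface, masking/ISI structure, sequential dependencies
beyond one lattice back, or measurement noise in individual effect
estimates beyond binomial sampling. Passing tests therefore establish
internal consistency of the model and pipeline, and qualitative
agreement with the published effect pattern — not quantitative fits to
any individual human dataset.

## Numerical choices and degenerate inputs

* Quadrature: Riemann sums on the uniform grid; FFT-based circular
  correlation for the likelihood convolution (exactly preserves the
  even symmetry of the identity-mapping case).
* All produced densities are renormalized on their grid to 1 within
  1e-9; the natural prior is grid-renormalized (its analytic constant
  1/(2π−2) is accurate to ~5e-5 at 1°).
* κ = 0 is a valid concentration (uniform); negative κ, weights outside
  [0, 1], AR ≤ 0, non-integer 180/step, and unknown prior/variant names
  raise typed errors.
* Expected-mode logit summaries use exact `logit(p)` (falling back to
  the empirical logit only at p ∈ {0, 1}); sampled-mode summaries use
  the empirical logit `log((k+½)/(n−k+½))`.
* Missing seeds in any stochastic mode are an error, never silently
  defaulted, so every pipeline artifact is reproducible byte-for-byte.

## Known limitations

* Only one lattice of history; no long-range serial dependence.
* The `stimulus_prior` variant's net AR-slope sign is
  convention-dependent (see above).
* No fitting to empirical data is provided — the package is a forward
  simulator plus a recovery/analysis pipeline.
* The multilevel-regression replacement ignores estimation uncertainty
  when correlating effects across individuals, which would attenuate
  correlations under sampled (rather than expected) responses at small
  n per cell.
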