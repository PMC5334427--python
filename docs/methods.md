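# Methods

This package re-implements, end to end on synthetic data, an
effective-connectivity analysis of a three-region visual hierarchy (V1,
V5, posterior parietal cortex) under three levels of visual-motion
predictability. It covers the stimulus and session simulator, the nested
experimental inputs, the bilinear DCM generative model with a
balloon–Windkessel observation stage, variational-Laplace inversion,
enumeration of the study's model spaces, fixed-effects Bayesian model
selection (BMS) with Occam's window, and Bayesian parameter averaging
(BPA) with multiplicity-corrected credible intervals.

## Stimulus model

A ball of diameter 2° moves at a constant 6°/s inside a 24° × 16° frame;
its center is confined to the 22° × 14° effective play area. Between
direction changes motion is linear, so event times are computed in closed
form (time to boundary), and trajectories are only discretized (100 Hz)
for export. Direction changes follow the condition:

* **PREDICTABLE** — specular reflection at walls;
* **RANDOM** — at walls, the emergent direction is uniform over the
  inward directions, excluding ±5° grazing angles (our addition, to avoid
  wall-sliding trajectories);
* **ARBITRARY** — as RANDOM, plus midfield direction changes arriving as
  a Poisson process. Corner hits reflect (or redraw) both components as a
  single event.

The midfield hazard rate is a free parameter. Its default (0.2139 events/s)
is set by `calibrate_hazard`, a bisection on simulated sessions with common
random numbers, so that ARBITRARY blocks contain ≈1.6× the direction
changes of PREDICTABLE blocks under the default geometry. The absolute
per-block change counts of the original display are not reconstructible
from the published geometry (our simulator gives ≈9 wall events per
20-s block); only the 1.6 ratio is treated as a calibration target.

A session holds 30 blocks (10 per condition, order pseudo-randomized)
with durations {20, 20.5, 21.5} s, onset jitters {0, 0.5, 1.5} s and
baselines {8.5, 10, 11.5} s (mean exactly 10 s). With 10 blocks per
condition and 3 levels per factor, the remainder is distributed (3, 3, 4)
and cyclically rotated across conditions, so levels are counterbalanced
up to the unavoidable remainder. The nominal session (~940 s) slightly
overruns the 512-scan × 1.8-s acquisition window — the published timing
is internally inconsistent at the tens-of-seconds level — so trailing
blocks are truncated at the scan window with a warning.

## Inputs

Three nested binary predictors on a microtime grid of TR/16 = 0.1125 s:
MOTION (all blocks), UNPREDICTABLE (RANDOM + ARBITRARY), ARBITRARY.
Nesting (`ARBITRARY ≤ UNPREDICTABLE ≤ MOTION` pointwise) makes each
predictor the *additional* effect of one step down in predictability.
Inputs are unit boxcars, not mean-centered; the same u drives and
modulates the dynamics.

## Generative model

Neuronal states follow dx/dt = (A + Σᵢ uᵢ B⁽ⁱ⁾) x + C u. Because u is
piecewise constant on the microtime grid and takes only four distinct
values under the nested coding, the neuronal update over each bin is
computed exactly with the matrix exponential of the affine-augmented bin
dynamics (full- and half-bin operators are precomputed per distinct u).

Each region's activity drives a balloon–Windkessel cascade (vasodilatory
signal, inflow, venous volume, deoxyhemoglobin) with per-region κ = 0.64
1/s (signal decay), γ = 0.32 1/s (feedback), τ = 2 s (transit), α = 0.32
(stiffness), E₀ = 0.4 (resting extraction) and neuronal efficacy ε = 1,
integrated by RK4 on the same grid (the neuronal drive at bin midpoints
is exact, keeping RK4 at full order). BOLD in percent-signal units uses
the standard nonlinear readout with 3 T constants (TE 30 ms, ϑ₀ = 80.6
s⁻¹, r₀ = 110 s⁻¹, intra/extravascular ratio 0.47, V₀ = 4%). The hot
loop is numba-compiled when numba is available (a pure-NumPy fallback
gives identical results, slowly).

Synthetic scan noise is i.i.d. Gaussian per scan and region; `noise_sd_for_snr`
sets the per-region SD to (temporal SD of the noiseless signal)/SNR.
AR(1) noise is deliberately out of scope.

## Inversion (variational Laplace)

Free parameters: self-decays as A_ii = −0.5·exp(θ) (structurally negative);
off-diagonal A, B, C couplings in Hz; per-region log-transit and a shared
log-efficacy; per-region noise log-precision as hyperparameters. Priors
are zero-mean Gaussians. Coupling priors (off-diagonal A, B, C and the
log self-decay scaling) share variance 1/4: the study's own published
winning-model couplings reach ≈1 Hz and self-decays span 0.24–0.69 Hz,
which a 1/16–1/256 shrinkage prior would place 3–12 prior SD from its
mean, producing shrinkage biases larger than the recovery tolerance.
With sd 0.5 those values sit within ~2 prior SD. The cost is that only
~80% of *joint* prior draws yield a stable A (the diagonal alone is
always stable); the integrator rejects unstable draws, and the inversion
treats non-finite predictions via step-halving. Hemodynamic priors stay
tight (variance 1/256) as forward-model nuisance parameters. Noise
log-precision has prior N(0, 1).

Each iteration computes a central finite-difference Jacobian of the
integrator, a ReML-style Newton update of the noise log-precisions
(capped per iteration; the cap halves whenever F dips, which suppresses
E/M limit cycles), and a Gauss–Newton step on the parameters with
step-halving so accepted steps never decrease F. F is the standard
Laplace bound: expected log-likelihood under q minus KL(q‖prior) for
parameters and hyperparameters; on a linear-Gaussian model with fixed
noise it equals the exact log evidence (tested to 1e-3 nats).
Convergence requires |ΔF| < 0.01 nats with the hyperparameters settled,
or 128 iterations.

Known behaviour at the study's noise level (SNR 3): the PPC "gain ridge"
(the ratio of V5→PPC coupling to PPC self-decay is well identified, its
decomposition is not) lets the MAP sit ~0.1 Hz below the generating
V5→PPC coupling; the displacement shrinks with SNR (≈0.06 Hz at SNR 10)
and is not an optimizer artifact (multistart and truth-started ascents
converge to the same mode). Fixed-effects BPA intervals therefore
under-cover this parameter; the recovery tolerance of ±0.15 Hz is met.

## Model spaces

All models share the endogenous skeleton (self-connections, reciprocal
V1↔V5 and V5↔PPC, no V1↔PPC edge) and the MOTION modulation of V1→V5.
The main space crosses three direct-input families (A: MOTION→V1 +
ARBITRARY→PPC; B: +MOTION→V5; C: +UNPREDICTABLE→V5, +ARBITRARY→V5) with
the 2⁸ on/off patterns of UNPREDICTABLE/ARBITRARY modulating the four
inter-node connections, and with three mutually exclusive synaptic-gain
variants (none, UNPREDICTABLE or ARBITRARY on the V5 self-connection):
3 × 256 × 3 = 2304. Mutually exclusive gain variants are the only
reading consistent with that count. Pre-selection spaces: 2⁵ = 32 direct-
input combinations (all modulations on), then the step-1 winner against
adding MOTION→V5 and/or MOTION→PPC (4 models). Models are identified by
a SHA-1 hash of their canonical mask JSON, so results are joinable
across runs. A 16-model demo subspace (family-B inputs, modulations of
the two forward connections) contains the active-run winning model and
keeps end-to-end experiments desk-scale.

## Group inference

Fixed-effects BMS sums free energies over subjects and applies a softmax
under a uniform model prior; family probabilities sum member posteriors.
Occam's window keeps models with posterior probability > 0.01 (the
original report does not define its window; the threshold is a config
knob) and probabilities are reported both on the full space and
renormalized within the window. BPA combines Gaussian posteriors by
precision addition with full covariances. Corrected credible intervals
draw from the averaged Gaussian and take Bonferroni-adjusted empirical
quantiles ((α/k)/2, 1−(α/k)/2) with k = 13 by default — the number of
parameters tested per response mode; zero-exclusion is flagged per
parameter. At the published passive-run means/SDs this reproduces the
three reported non-significant parameters; a fourth (UNPREDICTABLE drive
of V5, 0.11 ± 0.04) sits within rounding error of the corrected bound
and is asserted neither way.

## Synthetic world: what a green test establishes

The generator emulates the study's design dimensions (30 blocks, 3
conditions, 512 scans at TR 1.8 s, 3 regions, 3 nested inputs) and uses
the published active-run winning-model estimates as ground truth at
SNR 3. It does not emulate: subject-to-subject parameter variability
(all subjects share one generating parameter set, matching the
fixed-effects assumption), AR(1)/physiological noise, eigenvariate
extraction from real scans, or session effects. Green recovery tests
therefore establish internal consistency of simulator + estimator at the
stated noise level, not robustness to real-fMRI confounds.

## Numerical choices

Microtime bin 0.1125 s; neuronal updates exact per bin; hemodynamics RK4
at the bin width; finite-difference steps 1e-3 × prior SD per parameter
(one-sided fallback when a perturbation destabilizes the model);
Cholesky with escalating jitter for near-singular posterior precisions;
noise log-precision clipped to ±16; exponential maps clipped at +8 to
avoid overflow during line searches. Corner hits count as one event.
Trajectory export at 100 Hz. All randomness flows through
`numpy.random.Generator` seeds; identical seeds give bitwise-identical
event streams, schedules and noise.

## Known limitations

Single-subject generating parameters (no between-subject variability);
no AR noise; no random-effects BMS; the full 2304-model × cohort
inversion is supported but deliberately gated behind configuration (the
default pipeline uses the 16-model demo subspace); MAP displacement
along weakly identified timescale ridges at low SNR, as described above.
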