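# Methods

## The generative model

Neural activity in the three regions (ordered bottom→top: r-V5, r-pSPL,
r-aSPL) follows the bilinear state equation

    dx/dt = (A + Σⱼ uⱼ(t) Bʲ) x + C u(t)

with four experimental inputs u = (fixation, visual stimulation,
rivalry-switch, replay-switch), all with values in [0, 1]. A (1/s) is the
context-independent coupling: self-connections fixed at −0.5/s (the usual
identifiability convention), reciprocal edges only between adjacent
hierarchy levels (no direct V5↔aSPL edge). Bʲ modulates coupling while input
j is on; only the two switch inputs carry modulation, on the four
connections aSPL→pSPL, pSPL→aSPL, pSPL→V5, V5→pSPL. C routes driving input:
visual stimulation always drives V5; switch events always drive V5 and
optionally pSPL and/or aSPL.

Candidate structures differ in the modulated subset (2⁴, shared by both
switch inputs) and the two free switch-input bits (2²) — 64 models encoded
as a 6-bit `model_id` (bits 0–3 modulation, bits 4–5 inputs), partitioned
into families by the direction class of the modulated connections:
no-modulation (4), bottom-up (12), top-down (12), bidirectional (36).

The observation model is the balloon–Windkessel cascade per region
(vasodilatory signal s, inflow f, venous volume v, deoxyhemoglobin q):

    ds/dt = x − κs − γ(f − 1)
    df/dt = s
    τ dv/dt = f − v^{1/α}
    τ dq/dt = f·E(f, E₀)/E₀ − v^{1/α} q/v,   E(f, E₀) = 1 − (1−E₀)^{1/f}

with BOLD output y = 100·V₀(k₁(1−q) + k₂(1−q/v) + k₃(1−v)) in percent signal
change. Constants default to the canonical values κ = 0.64/s, γ = 0.32/s,
τ = 2.0 s, α = 0.32, E₀ = 0.4, V₀ = 0.04, k₁ = 7E₀, k₂ = 2, k₃ = 2E₀ − 0.2;
all configurable.

### Numerics

Classical RK4 on a uniform grid (default dt = 0.05 s; any dt that divides
the TR is valid). Inputs are zero-order hold — piecewise constant over each
step — so boxcars and pulses aligned to the grid mean the same thing at
every resolution and refinement converges at the integrator's order; the
balloon stage interpolates the continuous neural trajectory linearly at RK4
half-steps. Switch events enter as rectangular pulses of height 1 and
width 1.0 s starting at the (RT-corrected) switch time. The
width is a design choice, not an empirical claim: a one-step pulse would
give the modulatory term u·B·x near-zero support and make B unidentifiable
at any realistic noise level; ~1 s matches the timescale of the neural
transient accompanying a perceptual switch, and the parameter is exposed.
Trajectories are checked for finiteness; divergence raises an error naming
the first bad time (during optimization, a diverged trial step is rejected
rather than raised).

## Synthetic cohorts

The generator emulates the bistable structure-from-motion paradigm:

* dominance durations ~ Gamma with mean 4.50 s, SD 0.99 s (shape/scale
  solved from mean/SD; gamma is the standard duration model for bistable
  perception);
* short mixed-percept epochs at transitions, exponential with mean chosen so
  the expected mixed fraction of stimulus time is 2.23%;
* button presses lag each percept onset by a gamma-distributed reaction time
  (mean 0.90 s, SD 0.43 s); reports are serial (a press never precedes the
  previous one); presses after stimulus offset are lost; replay-trial
  presses carry `response_time` (press − stimulus change), rivalry presses
  do not (no defined stimulus change);
* trials: 31.5 s stimulation + 11 s fixation, TR 2.1 s, runs of 10 trials
  (5 rivalry / 5 replay, pseudo-random order starting with rivalry; each
  replay trial replays the earliest unreplayed rivalry sequence of the same
  run), a 10.5 s fixation lead-in absorbing the five discarded volumes,
  6 runs × 18 subjects by default. The stated trial timing leaves the 11 s
  fixation slightly off the 5-volume grid (5 × 2.1 = 10.5 s); the timing is
  kept as configured and nothing downstream requires alignment.

Ground-truth couplings (population defaults, chosen once for plausible
signal amplitudes and identifiable effects, then frozen): A off-diagonal
0.35/s bottom-up and 0.15/s top-down; C = 0.04 (stimulation→V5) and 0.15
(switch→V5), giving ~2.5% stimulus responses and ~1% switch transients;
per-subject B(replay) ~ N(0.30, 0.08) and ΔB ~ N(0.15, 0.15) per modulated
connection, truncated to [−0.2, 0.75] because couplings outside that range
transiently destabilize the pulse-modulated dynamics; observation noise
white Gaussian with SD 0.3% (ROI-averaged series). Rivalry and replay share
A and C and differ only in B.

The linking rule — a construction of this package, not an empirical claim —
makes the behavioral outcome recoverable: mean duration_i = γ₀ + Σ_c γ_c
ΔB_{i,c} + ε_i, floored at 1 s, with defaults γ₀ = 4.5 s, γ =
(0, −3, 0, +3) s per unit ΔB on (aSPL→pSPL, pSPL→aSPL, pSPL→V5, V5→pSPL)
and ε SD 0.3 s; each subject's duration distribution keeps the default
coefficient of variation. Per-subject random streams derive deterministically
from (master seed, subject index), so a cohort is a pure function of its
config.

What the generator does **not** emulate: scanner drift, autocorrelated or
physiological noise, head motion, hemodynamic variability across regions or
subjects, percept-duration serial correlations, response errors or missed
reports, and eye-dominance/disparity mechanics. Passing recovery tests
therefore show the estimation and selection machinery is correct and
calibrated under the stated assumptions — not that real fMRI would behave
this well.

## First-level GLM

Design: fixation and stimulation boxcars, rivalry- and replay-switch
impulses, all built at microtime resolution (TR/16), convolved with the
canonical double-gamma HRF (delays 6/16 s, dispersions 1/1, undershoot
ratio 6, 32 s kernel) and sampled at volume onsets; optional nuisance
columns; intercept. Switch events are derived from presses (a press whose
exclusive-percept label differs from the previous exclusive press in the
same block; mixed-percept reports never generate switches) and shifted
earlier by the mean RT estimated from replay presses, pooled across
subjects. OLS per region; t statistics with df = rows − rank; the
rivalry > replay contrast is (+1, −1) on the two switch columns; group
inference is a one-sample t-test over subjects. The run loader drops the
first five volumes by default and shifts the event clock accordingly.
Because synthetic data are generated per ROI, "extraction" is the identity;
the voxelwise peak/sphere/eigenvariate step of real studies has no synthetic
counterpart.

## DCM inversion and evidence

Per subject and candidate model, the free parameters θ (A off-diagonal, B on
the model's modulated set for both switch inputs, C on its input set; p
between 7 and 19) are estimated by Levenberg–Marquardt on

    O(θ) = ‖y − g(θ)‖²/(2σ²) + ½(θ−μ)ᵀΠ(θ−μ)

where g integrates the forward model with the same RK4 scheme and step used
for simulation (no discretization bias between generation and inversion) and
samples at the TR grid; runs are concatenated with state resets. Priors are
zero-mean with variance 0.25 per free parameter; hemodynamic constants are
fixed. σ² is the pooled ML estimate updated each accepted step (floored at
1e-8), or fixed when supplied. The Jacobian is forward finite differences
(relative step 1e-4), evaluated as one batched pass through a fused
numba kernel. Steps that increase the objective or diverge are rejected with
increased damping; convergence is a relative step below `tol` (default
1e-4) or damping exhaustion; non-convergence is flagged, never silent.

Approximate log evidence is the Laplace free energy at the optimum:

    F = −N/2 log(2πσ²) − RSS/(2σ²) − ½eᵀΠe + ½(log|Σ| + log|Π|),

with Σ = (JᵀJ/σ² + Π)⁻¹, i.e. accuracy minus a complexity term that is zero
when the posterior equals the prior. This is a simplified
variational-Laplace: deterministic and adequate for model ranking on
synthetic data; numerical equality with SPM's DCM implementation is not
claimed, and SPM prior settings, drift terms and input mean-centering are
not reconstructed.

## Random-effects model selection

Model frequencies r ~ Dirichlet(α); the posterior follows the standard
fixed-point variational update (subject-wise model probabilities ∝
exp(log evidence + ψ(α_k) − ψ(Σα)), α = α₀ + expected assignments), iterated
to 1e-6 with flat prior α₀ = 1. Exceedance probabilities are Monte-Carlo
argmax frequencies over 10⁶ Dirichlet draws (chunked; seed recorded in the
output). Family-level inference scores each family as a composite model —
subject-wise family evidence = logsumexp over members − log(family size),
the marginal likelihood under a uniform within-family prior — and runs the
symmetric four-way update. This implements equal prior mass per family
exactly; rescaling the model-level concentrations by 1/size instead is
badly biased through the variational update at small counts, because the
geometric-mean weighting exp(ψ(α)) misrepresents concentrations far from 1
(ψ(1/36) ≈ −37 where the intended prior log-odds are log(1/36) ≈ −3.6).
The winner is chosen in two stages: the family with the highest exceedance,
then the member with the highest model-level exceedance; exact ties break to
the lower model_id with a warning.

## Individual differences

ΔB = B(rivalry) − B(replay) on the winning model's modulated connections
(both conditions sit in one joint fit, so the difference needs no
cross-fit alignment). The outcome is the observed mean exclusive-percept
duration over all rivalry trials: intervals between consecutive presses
starting at each exclusive press, censored final epochs excluded, mixed
epochs excluded. OLS with intercept; Cook's distance D_i =
(standardized residual²/p)·h_i/(1−h_i) computed once on the full sample;
subjects with D > 1 (strict) are dropped in a single pass and the model is
refit — an iterative mode exists behind a flag but is off, matching the
single-pass reading of the exclusion rule. Standardized β are computed on
the retained sample (z-scored predictors and outcome). Adjusted R² is
asserted against its hand formula on every report. Two-sided coefficient
tests, no multiplicity correction across the four predictors.

## Problem sizes in tests and the acceptance script

Heavy simulations are scaled down, keeping the trial structure and noise
model fixed: recovery tests use single runs of 4–6 trials at dt = 0.15–0.3 s
(both generation and inversion on the same grid), five-subject cohorts for
the 20-replicate family-recovery check (inversion tol 5e-4, max 20
iterations there), and a 12-subject cohort for the end-to-end regression in
`scripts/acceptance.py`. The full 18-subject × 6-run default remains the
package default for real use.

## Known limitations

* The evidence approximation is a curvature-based Laplace at a local
  optimum; multistart optimization is not attempted.
* Family selection with very weak data follows the prior (all families
  equiprobable); the winner is then near-arbitrary, which the modest
  exceedance values make visible.
* The bottom-up modulation V5→pSPL and a direct switch input to pSPL are
  nearly collinear explanations of pulse-locked pSPL responses; with little
  data this can shift single-subject winners within the bidirectional
  family.
* Reaction-time jitter is the dominant source of ΔB estimation error in the
  realistic pipeline: the mean-RT correction recovers switch times only up
  to the per-event RT spread (SD 0.43 s), and with a single short run per
  subject this jitter — not observation noise — limits the ΔB–truth
  correlation. With exact switch timings and zero noise the inversion
  recovers ΔB essentially perfectly (a test asserts correlation > 0.9);
  more runs per subject average the jitter out.
* AR(1)/physiological noise, slice timing, two-state and nonlinear (D
  matrix) DCM variants, stochastic/spectral DCM and parametric empirical
  Bayes are out of scope.
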