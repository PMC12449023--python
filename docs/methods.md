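# Methods

## Models

Four delta-rule learners over outcomes normalised to [0, 1].  The belief
update is always `p(t+1) = p(t) + η·(O(t) − p(t))`, clamped to [0, 1];
the models differ in the origin of η.

* **Rescorla-Wagner (RW).**  η = η₀, constant, η₀ ∈ [0, 1].
* **Hybrid Pearce-Hall (PH).**  An associability is updated from the
  unsigned PE, `η(t+1) = ω·η(t) + (1−ω)·|PE(t)|` with ω ∈ [0, 1], and
  the belief update applies `γ·η(t)` (γ ≥ 0, effective rate clamped to
  [0, 1]).  The order is fixed as *belief update with the current
  associability, then associability update*: the two equations as
  written, with Eq-style η(t) in the belief rule.  Because all the other
  models' learning rates are instantaneous functions of the current
  trial's PE, trace summaries record for PH the *PE-aligned*
  associability `ω·η(t) + (1−ω)·|PE(t)|`, i.e. the learning-rate
  estimate the trial's PE triggers.  Without this alignment, correlating
  the PH learning-rate sequence with the cubic/exp-log sequences mostly
  measures the lag-1 autocorrelation of |PE| and collapses to ~0.2.
* **Cubic.**  η = PE²/(4κ), κ > 0.  The division by 4 places the focus
  of the parabola at height κ, so κ is directly interpretable as the
  focal point of the PE→rate transfer.  For κ < 0.25 the raw transfer
  exceeds 1 at large |PE|; the applied rate is clamped at 1.
* **Exponential-logarithmic (exp-log).**  η = exp(−δ·(−log|PE|)^λ),
  δ, λ ≥ 0.  At λ = 0 the transfer is the constant e^{−δ} — the model
  reduces *exactly* to RW with η₀ = e^{−δ} (verified to machine
  precision).  For λ > 0 it passes through η = 1 at |PE| = 1 and is
  defined by continuity as 0 at |PE| = 0.  A numerical floor of 1e−12
  on |PE| guards log(0).

A `NoiseLink` implements κ = a·e^{βσ} + ε (a ≠ 0, resulting κ > 0),
expressing the idea that expected uncertainty (noise σ) should flatten
the PE→rate transfer.  σ is meaningful in (0, 0.4] for normalised
outcomes.  Defaults everywhere: initial belief p₀ = 0.5 (maximum
uncertainty), initial PH associability 0.5; both configurable.

## Task environments

All generators are seeded (`numpy.random.default_rng`) and bit-identical
per seed.  Out-of-range Gaussian draws are clipped to [0, 1], not
resampled; the clipped-trial count is stored because clipping biases the
realized mean when means sit near the boundary.

**Factorial tracking environment (1500 trials).**  Five spans crossing
volatility (mean switches) with noise (generative SD): 300 volatile
trials (mean jump every 100) at SD 0.05; 200 stable at SD 0.10; 300
volatile at SD 0.10; 200 stable at SD 0.05; and a final noisier span of
500 trials at SD 0.15 containing both a volatile stretch (300 trials,
jumps every 100) and a stable stretch (200 trials), which obscures the
regime transition.  Volatile means alternate between the ends of the
mean range (0.2 ↔ 0.8 by default) — large, clearly discriminable level
changes, the same regime the magnitude task uses for its volatile
blocks; stable segments carry the preceding mean forward, since a jump
at a segment boundary would itself be volatility.  With small uniform
jumps instead, the post-switch PE transients drown in noise and every
fitted quantity drifts far below the values the environment is designed
to elicit (constant rate ≈ 0.19 instead of ≈ 0.3; cross-model η
correlations ≈ 0.25 instead of ≈ 0.75).

**Random short environments (60 trials).**  Piecewise-constant means
with `n_switches` jumps at uniformly drawn trials, means drawn uniformly
from [0.2, 0.8], Gaussian noise with per-environment SD.  Used by the
model competition with n_switches ~ U{0..5} and SD ~ U[0.02, 0.25].

**Binary probabilistic schedule.**  Stable (120 trials at 0.75) and
volatile (170 trials, contingency flipping 0.75 ↔ 0.25 after run lengths
of 30–40 trials) blocks; exactly one of the two anti-correlated options
is rewarded each trial; per-option reward magnitudes are uniform [0, 1].

**Magnitude task (4 × 60 trials, 2 × 2 design).**  Two options split 100
points per trial (magnitudes sum to 1 exactly).  Stable blocks use a
mean of 0.5 for option A; volatile blocks alternate 0.2 ↔ 0.8 every 20
trials; low/high noise is SD 0.05/0.15.

## Choice model and estimation

Reward magnitudes pass through a power utility m^ρ; the EV difference
between options enters a logistic sigmoid with slope β (inverse
temperature).  For binary tasks EV = p·m^ρ (probability × utility) with
the unchosen option's probability taken as the complement; for the
magnitude task EV is the utility of the predicted magnitude.  The
learner updates the chosen option's belief from the realized outcome;
the other belief is its complement.

`fit_mle` maximises the choice likelihood with L-BFGS-B from `n_starts`
random initialisations within bounds (η₀, ω ∈ [0, 1]; γ ∈ [0, 5];
κ ∈ (1e−3, 10]; δ, λ ∈ [0, 20]; ρ ∈ (0, 2]; β ∈ [0, 50]; convergence
tolerance 1e−8 on the objective).  Starts for scale-like parameters
(κ, δ, λ, β) are drawn log-uniformly: uniform draws over [0, 20] pile
onto the flat large-λ plateau, where the exp-log transfer degenerates to
a step function with zero numerical gradient and the optimiser stalls.
Zero-probability observed choices are floored at 1e−12 with a warning.

`fit_tracking` is an exhaustive grid search minimising the mean absolute
deviation between the belief trajectory and a target — realized
outcomes (mean-|PE| minimisation), the generative mean, or an observed
placement sequence.  Default grids: η₀ at 0.01 resolution; κ on an
81-point log grid over [1e−3, 10]; ω × γ on 0.02 × 0.1 grids; δ × λ on
0.05 × 0.1 grids with λ ≥ 0.1, because the λ = 0 slice *is* the RW model
and competes as such.  Ties break toward smaller parameter values
(slower learning under equivalence).

**Model comparison.**  AIC = 2k + 2·NLL, summed over subjects for group
comparisons.  `bms` implements variational Dirichlet random-effects
model selection: per-subject model evidences (−AIC/2 by convention here)
enter a variational update of Dirichlet weights; exceedance
probabilities come from a seeded Monte-Carlo sample of the posterior;
the Bayes Omnibus Risk is 1/(1+exp(F1−F0)), the posterior probability of
the null that all model frequencies are equal.  Equal evidences give
xp = 1/K and BOR → 1; a model 20 log-units ahead per subject gives
xp > 0.99 and BOR ≈ 0 (both verified against a Dirichlet sampling
oracle).

## In-silico experiments

**Factorial fits.**  Each model is fitted to a factorial-environment
realization by mean-|PE| minimisation over all 1500 trials at once.
Averaged over 30 seeds the optima are ≈ η₀ 0.30, κ 0.077, δ 0.87,
λ 1.41, with a PH mean learning rate ≈ 0.087, cross-model learning-rate
correlations ≥ ~0.74 and signed-PE/rate correlations indistinguishable
from zero.  The PH objective is nearly flat over a broad (ω, γ) ridge —
combinations from (0.1, 1.1) to (0.5, 1.6) differ by under 1% in
mean |PE| — so the *location* of the PH optimum is weakly identified and
its seed-to-seed spread is large (SD ≈ 0.13 on ω); any ω in that band
should be read as equivalent.

**Environment competition.**  The default protocol characterises the
four models once on a factorial environment and then runs the fixed
agents across 1000 random 60-trial environments; the winner per
environment is the lowest mean |belief − generative mean|.  A `refit`
mode re-fits every model per environment instead; note that the PH and
exp-log families can mimic near-constant learning rates (ω = 1 freezes
the associability; small λ flattens the transfer), so per-environment
refitting against the oracle mean systematically hands the flexible
families the win and the constant-rate learner almost never comes first
under that protocol.  Under either protocol the environments won by
trial-wise-rate models have significantly lower noise SD than those won
by the constant-rate learner — low expected uncertainty is where
PE-scaled learning pays.

**Generate-recover.**  Agents are simulated on the 240-trial magnitude
task and refitted by MLE (ρ fixed at 1).  δ recovers well (r ≈ 0.8–0.98
across seeds at β = 8).  λ is weakly identified on this task: the δ–λ
likelihood surface has a ridge, the realized |PE| support concentrates
at small values, and on single realizations the global optimum can sit
far from the generating λ with a *better* likelihood, so λ recovery
correlations fluctuate around 0.4–0.75 and should not be relied on at
this trial count.  This is a property of the model-task pairing, not of
the optimiser (verified with more starts, fixed β, and a binary task,
which is worse).

## Pupillometry

500 Hz sessions.  Preprocessing: linear interpolation across flagged
blink gaps; zero-phase (forward-backward) order-3 Butterworth low-pass
at 3.75 Hz; z-transform over the session (error on zero-variance
traces).  Epoching: outcome-locked 0–6000 ms windows, baseline = mean of
the 200 ms before onset; a trial is excluded when strictly more than 50%
of its window was interpolated, a session flagged when strictly more
than 50% of trials are excluded; windows truncated by the end of the
recording are flagged, not fatal.  Regression: regressors (intercept,
trial number, chosen outcome, signed PE, learning rate, black-pixel
luminance covariate) are z-scored per session; OLS runs at every time
point across included trials, returning coefficients and t statistics,
plus per-1000-ms-bin two-sided t tests of dilation against baseline.

The synthetic-session generator shapes per-trial amplitudes
(design × known coefficients) with a slow ramp kernel (rise to 1 by
1.5 s, plateau to 5 s, decay by 6.5 s), adds Gaussian sample noise and
Poisson-placed 100–400 ms blink gaps.  It emulates the *statistical*
structure the regression assumes — linear, time-locked, additive
effects — not real pupil physiology (no luminance reflex dynamics, no
arousal drift, no gaze artefacts), so passing recovery tests certify the
pipeline's correctness, not the physiological model.  With zero noise
the regression recovers the injected coefficients exactly at the kernel
plateau; after full preprocessing the z-transform rescales all
coefficients by the session SD, which tests undo before comparing.

## Problem sizes

Default analysis sizes were chosen so a complete run stays desk-scale:
30 factorial realizations for fitted-parameter summaries, 1000
environments in the competition, ~50 generate-recover fits, 10–40-trial
synthetic pupil sessions.  All randomness flows from explicit seeds.
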