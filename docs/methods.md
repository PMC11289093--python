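# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `qflytrack`.  Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and angle conventions

Positions are local planar meters, x east, y north.  All internal
angles are math-convention radians (counter-clockwise from +x), wrapped
to (−π, π]; a reversal is +π, and a left turn is positive.  Compass
bearings (degrees clockwise from north) exist only in the `polar` CSV
dialect, mirroring tape-and-compass field records; conversions are
tested at the I/O boundary.  Fixes closer than `min_step` (default
0.05 m) are merged into the earlier fix: positions were read at ground
level, so sub-5-cm "moves" are measurement noise, and zero-length steps
leave headings undefined (gamma densities can also diverge at zero).
The first step of a path has no turning angle; it is represented as
absent, never as zero, and contributes only its length to every
likelihood.

## Movement models and likelihood

Step lengths are gamma with moment parameterization shape = μ²/σ²,
rate = μ/σ², so published "mean ± SD" values are usable directly as
distribution parameters.  Turning angles are von Mises (mean μₜ,
concentration κ) for the CRW and for each HMM state, and fixed uniform
for the RW — the RW estimates no angular parameter, giving parameter
counts k = 2 (RW), 4 (CRW), 10 (two-state HMM: 2×4 emissions + 2
transition).  All three likelihoods share the same structure (every
step contributes a length density; every step but a path's first
contributes a turning density), so AIC = −2ℓ + 2k is comparable across
models.

The HMM likelihood is the scaled forward algorithm (per-step max-log
shifting plus normalization; the recursion is JIT-compiled with numba).
One transition matrix Γ is shared across flies and each path restarts
in the stationary distribution δ of Γ, reflecting a single pooled model
for the cohort.  Fitting maximizes ℓ directly with L-BFGS-B over
unconstrained transforms — log(μ), log(σ), log(κ), a sine/cosine pair
for mean angles, and per-row softmax logits for Γ — from `n_starts`
(default 25) initializations: the first is a data-moment seed (step
lengths split at quantiles; pooled turning moments), the rest are
Gaussian perturbations of it.  Convergence uses ftol 1e-10-scale
tolerances so refitting from a fitted model moves ℓ by < 1e-6.  Fitted
states are always reported sorted by ascending step mean; degenerate
fits (e.g. all step lengths equal) raise instead of returning infinite
AICs.  Correctness anchors: the forward value equals exhaustive
enumeration over all state sequences for short series (≤ 1e-10), and
with two identical states it collapses to the CRW likelihood exactly.

Parameter recovery at the study's scale (30 tracks × 200 steps,
self-transition 0.8) is the package's primary self-check.  ML on
finite-separation state mixtures has a small finite-sample bias —
most visibly ~−0.04 rad in the short-step state's turn mean — which
vanishes at 10× the data; the recovery tests therefore compare the
across-seed mean to truth within twice the across-seed SD of a single
seeded estimate.

## Circular statistics

κ̂ solves A(κ) = R̄ by bracketed Brent root finding on exponentially
scaled Bessel ratios; κ̂ = 0 at R̄ = 0 and +∞ (with a warning) at R̄ = 1.
The Rayleigh p-value uses the standard fourth-order series
approximation, which the tests check against a 1e5-replicate Monte-
Carlo null.  The Hermans–Rasson statistic is the recommended second
form, T = (1/n)ΣᵢΣⱼ[|‖θᵢ−θⱼ‖−π| − π/2 − 2.895(|sin(θᵢ−θⱼ)| − 2/π)],
with p-values from a seeded Monte-Carlo uniform null (default 9,999
replicates; p ≥ 1/(reps+1) by construction) rather than asymptotics.
Watson–Williams uses the classical F with the 1 + 3/(8κ̂) correction
(κ̂ from the weighted mean resultant) and warns when κ̂ < 1, where the
test's assumptions are shaky.  The quadrant χ² tests are asymptotic
with no continuity correction; angles lying exactly on a class boundary
(0, ±π/2, π) are excluded from the binary tests and reported in an
`n_excluded` field.

## Displacement

MSD origins are each path's first recorded fix.  The CRW prediction
consumes pooled moments: m₁, m₂ from all step lengths, c as the mean
cosine of all turning angles.  Near the ballistic limit the bracket
n − (1−cⁿ)/(1−c) is evaluated as (n(1−c) − (1−cⁿ))/(1−c) with
expm1/log1p for c > 0.5; the naive form loses three digits at
c = 1−1e-8.  The deviation test is a seeded parametric Monte-Carlo
envelope (2.5/97.5 percentiles of cohorts simulated from the fitted
CRW with the observed path-count/length structure), standing in for the
original analysis program's unpublished internal test.

## Fractal scale analysis

`divider_length` walks the classical forward dividers: each endpoint is
the first point along the polyline at chord distance δ from the
previous endpoint (circle–segment intersection solved per segment), and
the straight-line remainder to the path end is added.  Only the forward
walk is used; no reverse walk or direction averaging.  Measured length
shrinking with δ is a *trend*, not a strict monotonicity: the remainder
term produces wiggles of a few percent at fine scales and ~10–15% where
only a handful of dividers fit, and the tests assert exactly that.

The profile uses a log-spaced δ grid (defaults 1–50 m, 100 divisions)
and a local regression of log L on log δ within a sliding window of
width 0.35 in log₁₀ units (the width reading of the original program's
"window range" convention; a ratio-based window could be swapped behind
the same interface).  D = 1 − slope.  Paths shorter than a configurable
gross-length cutoff are dropped (the original analysis excluded two
short paths without printing its rule), and only scales measurable for
every retained path enter the profile.

The changepoint fit scans candidate thresholds at observed x between
the 10th and 90th percentiles, requiring ≥ 3 points per phase;
max LR = N·log(RSS₀/RSS₁) against the single-line fit, for either a
hinge (continuous) or two free lines split at e (discontinuous).
Because the threshold vanishes under the null, p-values come from a
parametric bootstrap of the single-line fit with Gaussian residuals,
not from asymptotics.

## Step summaries

Step frequencies are binned into (k−1, k] meter intervals and fitted by
OLS of log₁₀ proportion on log₁₀ k over nonzero bins — spreadsheet
"power trendline" behavior, which makes fitting an exact power table an
identity.  The abscissa convention (integer bin index vs midpoint
k − 0.5) is an explicit option, `index` by default; the source equation
is reproducible only under some such declared convention.  Tag-load
percentages round half-up to one decimal.

## Dispersal simulation

"Movements" for the 50%/95% radii are all visited step endpoints
(origin excluded), matching circles drawn around all steps rather than
final positions; percentiles are nearest-rank.  Per-fly randomness is
spawned from a single SeedSequence, so ensembles are reproducible given
(model, seed).  ANOVA and Tukey HSD come from scipy
(`f_oneway`, `tukey_hsd`); a textbook sums-of-squares oracle in the
tests provides the independent route.

## Synthetic data

The Experiment-1 generator defaults are the study's structure: 20
flies, 10–12 steps each, reference two-state model (0.8 ± 0.3 m,
turn mean −0.82, κ 0.46 / 4 ± 3 m, turn mean 0.05, κ 0.77), Gaussian
position jitter 0.1 m (tape-and-compass precision; off in oracle
tests).  The transition matrix is *not* published for this system;
symmetric self-transition 0.8 (stationary occupancy 50/50) is this
package's declared choice, serialized with every fixture.  The
Experiment-2 generator subsamples a latent fine-scale walk at
twice-daily sweeps (0, 6, 22, 26 h); its latent rate of 2 steps/h was
calibrated once, by the diffusive scaling of the reference model, so
the default cohort reproduces the reported mean movement rate of
≈1.7 ± 0.5 m/h.  An optional drift (speed, direction) exists for
studying directional bias but defaults to off, since no mechanism for
the observed field bias is established.

What the generators do *not* emulate: planting geometry or attraction
to trees, observation dropout correlated with distance, and — notably —
sub-step-scale tortuosity.  Simulated tracks are piecewise straight
below the step length, so their fractal dimension *rises* with spatial
scale (D → 1 at δ ≪ 0.8 m, Brownian-like D → 2 above the persistence
length), whereas real tracks are tortuous at fine scales and were
reported to straighten at large scales.  Passing fractal tests
therefore validate the estimator's geometry, not the field-scale
direction of the effect.  Similarly, with the declared symmetric
transition matrix the fitted-HMM ensembles disperse *further* than the
fitted CRW (long steps arrive in forward-persistent runs), so the
reported CRW-first ordering of maximum dispersal distances is not
reproduced by the synthetic conditions; the package asserts the parts
that are parameter-derivable (CRW > RW; super-diffusive MSD under
state switching).

## Problem sizes

Defaults used by the shipped analyses and tests: recovery at 30 × 200
steps (20 seeds for SE estimation); Monte-Carlo nulls of 999–9,999
replicates; bootstrap 499–999; dispersal comparisons of 20 replicates
of 100 flies × 100 steps.  These sizes make every Monte-Carlo SE small
relative to the tolerances asserted and run in minutes on one CPU.

## Known limitations

* Two states only are fitted by default; state-count selection,
  covariates on Γ, and biased (BCRW) walks are out of scope.
* The Hermans–Rasson implementation could not be cross-validated
  against the original R implementation in this environment; its null
  calibration is instead verified by simulation (type-I error ≈ 5%).
* Signal-only detections carry a `confirmed=False` flag but are never
  down-weighted.
* The changepoint test's statistic form (N·log(RSS₀/RSS₁)) is one
  reasonable choice among several; the bootstrap calibration makes the
  p-value self-consistent regardless of that choice.
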