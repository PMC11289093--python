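# qflytrack

Movement analysis for harmonic-radar tracks of Queensland fruit flies
(*Bactrocera tryoni*) — and for any small-insect telemetry data with the
same shape: a handful of flies, each observed as an ordered sequence of
landing positions in a field.

The package is aimed at movement ecologists and pest-surveillance
modelers who want to go from raw landing coordinates to (i) descriptive
flight statistics, (ii) fitted movement models, and (iii) forward
simulations of dispersal, without stitching together half a dozen
single-purpose tools.

## What it computes

**Track geometry** (`track_io`): step lengths, absolute headings, and
signed turning angles (wrapped to (−π, π], counter-clockwise positive)
from x/y or tape-and-compass records; movement rates in m/h.

**Circular statistics** (`circular_stats`): mean direction and resultant
length R̄, ML von Mises concentration κ̂ (the root of A(κ) = I₁(κ)/I₀(κ)
= R̄), the Rayleigh and Hermans–Rasson tests of uniformity (the latter
with a seeded Monte-Carlo null), the Watson–Williams F test across
flies, and χ² bias tests on turning angles in 45° quadrants.

**Movement models** (`movement_models`): three nested descriptions of a
fly's flight sequence, sharing one likelihood structure so AICs are
comparable —

* RW: gamma step lengths, uniform turning angles (k = 2);
* CRW: gamma step lengths, von Mises turning angles (k = 4);
* two-state HMM: a hidden Markov chain (within-tree vs between-tree
  behavior) selecting per-state gamma + von Mises emissions (k = 10),
  fitted by direct multi-start maximization of the scaled forward
  log-likelihood and decoded with Viterbi.

**Displacement** (`displacement`): empirical mean squared displacement
per step count against the RW prediction MSD(n) = n·E[L²] and the
Kareiva–Shigesada CRW prediction
MSD(n) = n·m₂ + 2m₁²c·(n − (1−cⁿ)/(1−c))/(1−c), with a Monte-Carlo
envelope test for deviations.

**Fractal scale analysis** (`fractal_scale`): dividers-method fractal
dimension D (L(δ) ∝ δ^(1−D)) as a function of spatial scale, and
two-phase (continuous/discontinuous) threshold regression of D against
log₁₀ scale with a bootstrap-calibrated maximal-LR changepoint test.

**Dispersal simulation** (`dispersal_sim`): replicate ensembles under
fitted models, max distance from origin and nearest-rank 50%/95%
radii, compared by one-way ANOVA + Tukey HSD.

**Synthetic data** (`synthetic_data`): seeded generators reproducing the
study's data structure (20 continuously tracked flies of 10–12 flights;
intermittent twice-daily fixes over ≤26 h), built on a reference
two-state model (short within-tree steps 0.8 ± 0.3 m with diffuse
turning, κ = 0.46; longer between-tree steps 4 ± 3 m with forward
persistence, κ = 0.77).

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on a
synthetic cohort (every step is importable from `qflytrack` directly):

```sh
python analysis/01_make_fixtures.py --seed 1
python analysis/03_fit_movement_models.py --seed 1
```

which prints (seed 1):

```
  rw: loglik=  -810.25  k= 2  AIC=  1624.50
 crw: loglik=  -799.59  k= 4  AIC=  1607.19
 hmm: loglik=  -732.62  k=10  AIC=  1485.25
best model by AIC: hmm
state 1: step 0.83 +- 0.36 m, turn mean -1.56 rad, kappa 0.37
state 2: step 4.66 +- 2.95 m, turn mean -0.25 rad, kappa 0.85
```

Read: on a 20-fly, 222-step cohort the two-state HMM beats the pooled
CRW by ~122 AIC points, and the fitted states recover the generator's
short-step/diffuse and long-step/persistent behaviors (ML estimates
from only ~100 steps per state, hence the spread around the generating
values).  `02` prints the circular tests and the step-frequency power
fit, `04` the MSD table (observed spread exceeds both RW and CRW
predictions from ~5 steps on), `05` the fractal changepoint, `06` the
dispersal ANOVA/Tukey comparison, `07` the intermittent-observation
cohort (movement rate ≈ 1.7 m/h by construction).

A thin CLI wraps the same functions: `qflytrack synth|stats|fit|msd|
fractal|simulate --help`.

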