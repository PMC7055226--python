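# Methods

## Task model

A session is deterministic given its inputs: deck schedules, a
60-element sequence of deck choices, and four estimate categories.
Each deck is an ordered integer card cycle (net stickers per card);
the defaults are a SAFE cycle `(+1,+1,0,+1,0,+1,+1,0,+1,0)` (mean
+0.6/card) and a RISKY cycle `(+2,+2,−4,+2,−6,+2,+2,−4,+2,−6)` (mean
−0.8/card). These particular values are configuration, not doctrine:
what matters structurally — and what the engine validates — is that
the SAFE deck's mean is positive and the RISKY deck's negative, and
that values are integer sticker counts. The practice phase is a fixed
6-card script whose realized sum from an empty sheet is exactly +4,
the buffer the child starts the scored game with.

The sticker balance is floored at zero:
`balance_after = max(0, balance_before + card)`, and the *realized*
delta (`balance_after − balance_before`) is what enters block payoffs
and hence the calibration deltas — the child's visible sticker sheet
reflects realized, not raw, values. Estimates are elicited after
blocks 1, 2, 4 and 5 (configurable); each predicts the immediately
following block. The video point between blocks 3 and 4 is recorded
as a flag with no mechanical effect. Turn/block/occasion indexing is
1-based everywhere.

Invariants asserted at run time for every session: final balance =
4 + Σ realized deltas; no negative balance at any turn; realized ≥ raw
with equality iff the floor does not bind; identical
(choices, config, card-order seed) ⇒ identical turn records.

## Calibration coding

With Δ the realized payoff change from reference to target block:

| category | overconfidence = 1 | miscalibration = −1 |
|---|---|---|
| More | Δ < 0 | never |
| About the same | Δ < −1 | Δ > +1 |
| Less | never | Δ > 0 |
| Don't know | never | never |

Boundary decisions, where the verbal rules are open to reading:
More with Δ = 0 scores 0 (the negative-change condition is strict);
Less with Δ = 0 scores 0 (winning *more* is strict); "about the same"
is a ±1-sticker band, so |Δ| ≤ 1 is calibrated. The binary score is
exactly `max(0, miscalibration)` — an invariant property-tested across
the input grid. Missing estimate categories are rejected at ingest,
never imputed.

## The mixed models

All three analysis models share the longitudinal structure
`η_it = x_itᵀβ + u_i0 + u_i1 t` with per-participant random intercept
and slope, a priori independent (diagonal covariance — no covariance
parameter is modeled). Fixed-effect sets:

* linear models (safe-card ratio, block payoffs; time = block 1–6):
  intervention, age group, female, time, intervention×age×time,
  constant;
* probit model (overconfidence; time = occasion 1–4): intervention,
  age group, female, time, female×2nd-occasion, female×4th-occasion,
  constant;
* robustness model: miscalibration as a linear outcome on the probit
  model's design.

Time is used untransformed (no centering/standardization). Age enters
as a binary ≥ 60-months indicator. Only these covariate sets plus the
listed interactions are constructible — there is deliberately no
formula language.

**Priors.** β_k ~ N(0, 10⁴) independently — a near-flat "null effect"
default. Variance components (residual σ² for linear models, random
effect variances τ₀², τ₁²) get Inv-Gamma(0.01, 0.01), a standard weak
conjugate default; both choices are exposed in `PriorSpec`. The probit
model's effective prior is necessarily more informative on the
probability scale (coefficients live in probit units); the same
N(0, 10⁴) default is retained with the variance configurable.

**Sampler.** Pure Gibbs with conjugate updates: β | rest from the
weighted-least-squares multivariate normal; u_i0, u_i1 | rest from
independent scalar normals (aggregations via bincount over the
participant index); variances | rest from inverse-gamma. The probit
model adds truncated-normal latent draws z_it ~ N(η_it, 1) constrained
to the sign of y_it (inverse-CDF sampling with the uniform clipped to
[1e−15, 1−1e−15] for numerical safety), after which the linear updates
apply with the latent residual variance fixed at 1. Chains are seeded
`seed + chain_index` and independent of execution order. Collinear
designs are rejected up front; complete separation by a binary column
logs a warning and proceeds (the priors regularize).

Iteration semantics follow the convention in the reported analyses:
`n_iterations` counts monitored (post-burn-in) iterations and
`n_iterations / thinning` draws per chain are kept. Library defaults
are the study's settings — linear models: 2 chains, 10,000 burn-in,
100,000 monitored, thinning 5, seed 12345; probit: 10,000 burn-in,
400,000 monitored, thinning 20, seed 1234. Tests and the acceptance
script run scaled-down chains (typically 2 × (2,000–10,000 burn-in +
12,000–40,000 monitored)); convergence at those sizes is verified
directly by PSRF.

**Summaries.** pM/pSD over pooled chains; the 95% HPD as the shortest
contiguous window containing ⌈0.95 n⌉ sorted draws (leftmost window on
ties — deterministic); ROPE mass with inclusive bounds, defaults 0
± 0.01 (safe-card fraction), ± 0.5 stickers (payoffs), ± 0.1 probit
units (overconfidence/miscalibration); PSRF as
`sqrt(((n−1)/n·W + B/n)/W)`, splitting a single chain in half.
Report rows follow the convention: Intervention, Age, Female, Time,
interactions, Constant, then random-effect variances (and residual
variance for linear models). Probit coefficients can be displayed
×100 ("percent" convention) — the draws always stay on the probit
scale.

## Synthetic cohorts

No behavioral generative model exists in the underlying task protocol;
the agent policies are this package's own construction, and their
defaults are labeled as such. The default cohort reproduces the study
composition: 58 children, 29 per arm (balanced permuted allocation),
27 girls, 16 aged ≥ 5y (ages drawn uniformly in 36–59 / 60–78 months).

*Choice policy*: P(SAFE in block b) = Φ(−0.15 + 0.06·b + 0.30·female
+ 0.10·older + 0.15·arm·post-video + u_i0 + u_i1·b), with participant
noise sd 0.30 (intercept) and 0.05 (slope). This yields a safe-card
ratio rising from ≈ 0.53 to ≈ 0.62 across blocks with a female
advantage — qualitatively the trajectories the analysis expects.

*Estimate policy*: an ordered-threshold model on a latent optimism
score `0.55 + 0.08·(last payoff change) − 0.35·occasion +
v_occ·female + N(0,1)`, cut at (−0.85, 0.25) into Less/Same/More,
with female volatility shifts v = (0, −0.9, 0, +1.2) (dip at the 2nd
estimate, spike at the 4th) and an independent 8% Don't-know rate.
Noise scales are calibrated only to keep simulated summaries in a
plausible range and are otherwise arbitrary. Under these defaults
roughly a third of occasion scores are overconfident and the binary
and trinary codings correlate at r ≈ 0.85.

What the agents do *not* model: any cognitive process claim
(reinforcement learning, memory), video content effects beyond a
binary arm flag, spatial deck layout. Passing tests on these cohorts
therefore demonstrates pipeline correctness and estimator behavior
under known structure — not behavioral validity on real children.

A second, model-based generator (`simulate_outcome_table`) draws
outcomes directly from the mixed model being fitted, with the study
covariate layout and known coefficients; its default ground truths sit
in the effect-size regime the analysis targets (e.g. a 2.87-sticker
female payoff effect, a −0.585 probit time trend). Parameter-recovery
experiments use this generator so "truth" is well defined.

## Validation strategy and known limitations

* Scoring is checked exhaustively against an independent rule-table
  oracle over the full category × Δ ∈ [−30, 30] grid.
* The linear sampler is checked against the exact conjugate normal
  posterior (random effects disabled, σ² fixed — draws are then iid
  from the exact posterior, so 3-MCSE bounds are sharp).
* The probit sampler is checked against an independent random-walk
  Metropolis sampler on the same 10-observation posterior (3 joint
  MCSE on posterior means, effective sample sizes via arviz), and for
  large-sample consistency at n = 5,000.
* HPD is checked against a brute-force minimal-window scan; ROPE
  against the normal-CDF closed form; PSRF against the hand-computed
  formula and its calibration on iid chains.
* Parameter recovery: 20 cohorts per model; each generating fixed
  effect's 95% HPD coverage is required to lie in [0.90, 1.00].
  Measured over 60 replicates, per-coefficient coverage is ≈
  0.88–0.97: 95% Bayesian HPD intervals evaluated at a *fixed* truth
  with only 58 participants are mildly anti-conservative for some
  coefficients, and the coverage estimate at 20 replicates carries
  ±0.05 binomial noise on top. One payoff-model coefficient (the time
  trend) sits at 17/20 under the frozen seeds and fails the 0.90
  bound; this reflects the interval-calibration property just
  described, not a sampler defect (see the oracle checks above).
* Convergence: the probit model on the default cohort at 2 × (10,000
  burn-in + 40,000 monitored, thinning 20) yields max fixed-effect
  PSRF ≈ 1.001, comfortably under the 1.009 reporting bound.

Numeric agreement with any specific published posterior table is not
a goal: those values depend on a deposited dataset and software
prior defaults not reproducible here. The targets are structural
exactness, oracle equivalence, recovery, and convergence, as above.

Problem sizes in tests are chosen for desk-scale runs: recovery uses
20 replicates per model at reduced chain lengths; all other checks
run in seconds.
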