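# cgtcal

Simulation and Bayesian analysis of confidence calibration in the
Children's Gambling Task (CGT).

## The scientific problem

The CGT is a two-deck adaptation of the Iowa Gambling Task for
preschoolers: a SAFE deck with a superior average sticker payoff and a
RISKY deck with larger single-card gains but net losses. A child plays
6 practice trials (netting a 4-sticker buffer), then 60 scored turns
in 6 blocks of 10, with a video break between blocks 3 and 4
(intervention vs. control clip). After blocks 1, 2, 4 and 5 the child
predicts whether the next 10 cards will pay **More**, **About the
same**, or **Less** than the previous block (or **Don't know**). The
sticker balance is floored at zero throughout.

Comparing each prediction to the realized payoff change
`Δ = payoff(block t) − payoff(block t−1)` yields two per-occasion
calibration measures:

* **overconfidence** (binary): 1 iff (More ∧ Δ < 0) or (Same ∧ Δ < −1);
  Don't-know is always 0 (conservative coding);
* **miscalibration** (trinary −1/0/+1): +1 under the same conditions,
  −1 iff (Less ∧ Δ > 0) or (Same ∧ Δ > 1).

This package simulates full cohorts of task sessions, applies the
coding rules, and fits three Bayesian random-intercept +
random-slope mixed models by Gibbs sampling, written from scratch:

```
y_it = x_itᵀβ + u_i0 + u_i1·t + ε_it            (linear: safe-card ratio, payoffs)
P(y_it = 1) = Φ(x_itᵀβ + u_i0 + u_i1·t)          (probit: overconfidence)
```

with priors β_k ~ N(0, 10⁴), σ², τ₀², τ₁² ~ Inv-Gamma(0.01, 0.01).
The probit model uses latent-variable (truncated-normal) augmentation
so every conditional is conjugate. Posteriors are summarized by
posterior mean (pM), SD (pSD), 95% highest-posterior-density (HPD)
interval, mass in a region of practical equivalence (ROPE), and the
Gelman–Rubin potential scale reduction factor (PSRF).

Intended users: behavioral/developmental researchers who want a
tested, reproducible reference pipeline for calibration scoring and
small-sample Bayesian mixed modeling of repeated-measures task data.

## Worked example

```python
import cgtcal as c

cohort, truth = c.simulate_cohort(c.CohortConfig(seed=1))   # 58 children, 29/29 arms
tables = c.build_model_tables(cohort)                       # 348/348/232-row long tables
print(len(cohort), len(tables["overconfidence"]))

r = c.correlate_measures(tables["overconfidence"].overconfidence,
                         tables["overconfidence"].miscalibration)
print(round(r, 3))

mcmc = c.MCMCConfig(n_chains=2, burn_in=10_000, n_iterations=40_000,
                    thinning=20, seed=1234)
draws = c.fit_probit_glmm(tables["overconfidence"], c.overconfidence_spec(),
                          mcmc=mcmc)
print(c.render_summary(c.summarize(draws, rope_half_width=0.1)))
```

prints (seed 1):

```
58 232
0.854
Parameter                           pM       pSD               95% HPD    ROPE    PSRF
--------------------------------------------------------------------------------------
Intervention                     0.080     0.206       [-0.342; 0.472]  0.3515  0.9998
Age                             -0.203     0.236       [-0.656; 0.269]  0.2362  1.0005
Female                           0.001     0.249       [-0.482; 0.481]  0.3165  0.9998
Time                            -0.447     0.101      [-0.646; -0.251]  0.0000  1.0005
Female, 2nd Estimate            -0.497     0.346       [-1.213; 0.147]  0.0813  1.0002
Female, 4th Estimate             1.313     0.385        [0.617; 2.127]  0.0003  1.0008
Constant                         0.478     0.289       [-0.096; 1.026]  0.0727  1.0008
Random Intercept                 0.044     0.047        [0.002; 0.134]          0.9998
Random Slope                     0.014     0.010        [0.002; 0.033]          0.9998
```

Reading the table: each row is one model parameter on the probit
scale; the two calibration codings correlate at r = 0.854 on this
cohort. The `Time` row says the cohort's overconfidence probability
falls with each successive estimate occasion (pM −0.45, 95% HPD
excluding 0, no posterior mass inside the ROPE of ±0.1), and the
`Female, 4th Estimate` row captures the simulated girls' rebound in
overconfidence at the 4th estimate. PSRF ≈ 1.00 for every parameter
indicates the two chains mixed well.

A command-line interface wraps the same pipeline:

```bash
cgtcal simulate --out cohort_dir          # write turns/estimates/covariates CSVs
cgtcal fit --config pipeline.yaml         # simulate → score → fit → report
cgtcal report --out results_dir          # print the plain-text summary report
```

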