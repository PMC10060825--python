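# driftchoice

Computational modelling of impulsive intertemporal choice under smartphone
separation: a multi-attribute drift diffusion model (simulation, fitting,
posterior-predictive checking), delay-discounting task scoring, and the
group / correlation / bootstrap-mediation statistics — all exercisable on
fully synthetic, study-shaped cohorts with known ground truth.

## The problem

When people choose between a smaller-sooner reward (SS, "¥17 today") and a
larger-later one (LL, "¥38 in 30 days"), the traditional delay-discounting
account summarizes impulsivity in a single rate `k` (hyperbolic value
`V = A/(1 + kD)`). That says *how* impulsive someone is, but not *why*. A
drift diffusion model (DDM) opens the decision up: noisy evidence `x(t)`
accumulates from a starting point `z·a` toward an upper boundary `a`
(choose LL) or a lower boundary 0 (choose SS), at a drift rate that weighs
the options' attribute differences,

    v = d_c + W_m · MoneyDiff + W_d · DelayDiff,

with `MoneyDiff = A_LL − A_SS` and `DelayDiff = D_LL − D_SS`. Reaction time
is the boundary-crossing time plus a non-decision time `t0`. The decision
weights `W_m` (on reward) and `W_d` (on delay) are the quantities of
scientific interest: experimentally induced anxiety (being separated from
one's smartphone) has been reported to lower `W_m`, making the diffusion
less likely to reach the delayed-reward boundary — a mechanistic account of
increased impulsivity. This package implements that full analysis chain for
anyone who wants to simulate it, fit it, or stress-test it: the Wiener
first-passage-time likelihood, per-participant maximum-likelihood (or
ensemble-MCMC) estimation, the titration and purchase-scenario task scores,
one-way/covariate-adjusted ANOVA with η², Cronbach's α, and PROCESS-style
percentile-bootstrap mediation (simple, serial, and parallel).

Because the original raw data are unreleased, the package ships a seeded
synthetic-cohort generator that emulates the four study designs (group
sizes, questionnaire scales and reliabilities, group-specific correlations,
diffusion-weight distributions) so every stage is testable end to end; see
`docs/methods.md` for exactly what it does and does not emulate.

## Worked example

```python
from driftchoice import (ChoicePair, DDMParams, choice_probability,
                         drift_rate, fit_individual, simulate_trials)
from driftchoice.cohort import generate_choice_menu

pair = ChoicePair(amount_ss=17, delay_ss=0, amount_ll=38, delay_ll=30)
control   = DDMParams(z=0.5, a=2.0, t0=0.3, dc=0.0, wm=0.047, wd=-0.009)
separated = DDMParams(z=0.5, a=2.0, t0=0.3, dc=0.0, wm=0.023, wd=-0.010)
for name, p in [("control", control), ("separated", separated)]:
    v = drift_rate(p, pair)
    print(f"{name}: v = {v:.3f}, P(delayed) = {choice_probability(v, p.a, p.z):.3f}")

menu = generate_choice_menu()                     # 80 option pairs
trials = simulate_trials(control, menu * 3, rng=0)  # 240 simulated trials
fit = fit_individual(trials, rng_seed=0)
print(f"recovered wm = {fit.params.wm:.4f} (true 0.047), "
      f"a = {fit.params.a:.2f}, t0 = {fit.params.t0:.2f}")
```

prints

```
control: v = 0.717, P(delayed) = 0.808
separated: v = 0.183, P(delayed) = 0.590
recovered wm = 0.0503 (true 0.047), a = 1.93, t0 = 0.30
```

The two groups share the same option pair, but the lower money weight of
the separated group cuts the drift from 0.717 to 0.183 evidence/s, dropping
the probability of waiting for the larger reward from 81% to 59% — and the
latent money weight is recoverable from a few hundred simulated trials.

A command-line interface wraps the pipeline:

```
driftchoice run-study 3 --seed 1 --out out/          # full study replica
driftchoice generate --design separation --out out/  # cohort CSVs
driftchoice fit --trials out/trials.csv --out fits.csv
driftchoice reproduce-printed                        # printed-statistics check
```

`run-study {1|2|3|4}` generates a study-shaped cohort, scores the tasks,
fits the diffusion model where the design has trials, and writes group
contrasts, correlations, weight contrasts and mediation tables as CSV plus
a plain-text summary.

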