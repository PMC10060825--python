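# Methods

## The model

`driftchoice` models a binary intertemporal choice — a smaller-sooner (SS)
amount now versus a larger-later (LL) amount after a delay — as a
two-boundary drift diffusion process. Relative evidence `x(t)` starts at
`z·a` (a fraction `z` of the boundary separation `a`), accumulates with
drift `v` and Gaussian noise of scale `s`, and is absorbed at `a` (choose
LL) or `0` (choose SS). Observed reaction time is the absorption time plus
a non-decision component `t0`. The drift is a linear function of the two
attribute differences between the options:

    v = dc + wm · MoneyDiff + wd · DelayDiff

where `MoneyDiff = amount_LL − amount_SS` (currency units) and
`DelayDiff = delay_LL − delay_SS` (days). `wm` (evidence/s per currency
unit, typically positive) and `wd` (evidence/s per day, typically negative)
are the decision weights on reward and delay; `dc` absorbs any
attribute-independent bias toward the delayed option. Together with `z`,
`a` and `t0` that makes six estimated parameters per participant.

Assumptions: constant boundaries, no across-trial variability in drift,
start or non-decision time, and a drift that is linear in raw attribute
differences (no normalization of MoneyDiff/DelayDiff — they enter in task
units). The noise scale `s` is not identifiable jointly with `(a, dc, wm,
wd)`: scaling `(v, a, s) → (c·v, c·a, c·s)` leaves all choice probabilities
and passage-time densities unchanged (asserted numerically in the tests).
`s` is therefore fixed at 1; estimates on the 0.1 convention used by some
packages are the deterministic rescaling with `c = 0.1`.

## Likelihood and its evaluation

The trial likelihood is the Wiener first-passage-time density at the
boundary matching the recorded choice, evaluated at `rt − t0`. The density
is computed by the standard dual series expansion: a small-time expansion
in image terms and a large-time eigenfunction expansion, switching to
whichever needs fewer terms for a truncation error below 1e−10. Upper-
boundary passage is evaluated as lower-boundary passage of the mirrored
process (`v → −v`, `z → 1 − z`). The analytic absorption probability

    P(LL) = (1 − exp(−2·v·z·a/s²)) / (1 − exp(−2·v·a/s²)),  P(LL)|v=0 = z

is evaluated with `expm1` and saturates boundedly for |2va/s²| > 500.
Trials with `rt ≤ t0` would have zero density; they contribute a floored
density of 1e−12 so the objective stays finite during optimization.

## Simulation

Trials are simulated by Euler–Maruyama steps `Δx = v·dt + s·√dt·N(0,1)`
with `dt = 1 ms` and a 20 s censoring cap (censored trials are flagged and
assigned the boundary nearer the final position). Discrete monitoring
misses excursions that cross a boundary and return within one step, which
biases both absorption probabilities and passage times by O(√dt); the
Broadie–Glasserman continuity correction (crossings registered against
boundaries inset by `0.5826·s·√dt`) removes this bias. With the correction,
simulated choice fractions match the closed-form absorption probability
within Monte-Carlo error at n = 10⁵ across a grid spanning `a ∈ [0.5, 3]`,
`v ∈ [−2, 2]`, `z ∈ [0.2, 0.8]`.

## Estimation

Default estimation is per-participant bounded maximum likelihood
(L-BFGS-B) with multi-starts: one informed start plus up to seven
Latin-hypercube draws over the box `z ∈ (0.05, 0.95)`, `a ∈ (0.1, 5)`,
`t0 ∈ (0, min rt − 1 ms)`, `dc ∈ (−5, 5)`, `wm, wd ∈ (−1, 1)`. Starts stop
early once two of them independently replicate the best objective within
1e−3 — the surface is unimodal for typical data, and genuinely multimodal
cases still receive all starts. Data with a single represented choice
category, or fewer than 20 trials, are flagged unconverged with a warning;
the boundary-pinned estimate is still returned.

An optional non-hierarchical Bayesian mode runs an affine-invariant
ensemble sampler (emcee) with weak priors — `a ~ half-normal(2)`,
`z ~ Beta(2, 2)`, `t0 ~ U(0, min rt)`, `dc, wm, wd ~ N(0, 10)` — and
reports the posterior mean, keeping the draws so predictive summaries can
propagate parameter uncertainty. A full hierarchical model (group-level
nodes shrinking individual estimates) is deliberately out of scope: the
quantities of interest here are individual weights and their group
contrasts, which per-participant estimation recovers (rank correlation
between true and recovered money weights ≈ 0.87 at 200 trials per
participant).

Model fit is assessed by simulating replicate datasets from the fitted
model over the participant's own option pairs (default 500) and comparing
the probability of choosing the delayed reward and the mean RTs per choice
category with the observed values.

## Task scoring

* **Titration indifference point**: the midpoint between the grid amounts
  bracketing the first delayed→immediate switch. All-immediate series are
  censored low (grid min − half step, floored at 0), all-delayed censored
  high (grid max + half step). Non-monotone series use the first switch and
  carry a multi-switch flag — deterministic and auditable rather than
  model-based.
* **Discount rate**: hyperbolic `V = A/(1 + kD)` (the standard
  delay-discounting form), so `k = (A/V − 1)/D` per day with "2 months"
  taken as 60 days; an exponential variant sits behind a flag.
* **Impulsive decisions**: the count of immediate (SS) choices.
* **Purchase scenarios**: restaurant wait (5–60 min) reverse-coded as
  `65 − wait`, movie timing (1–100, high = after the deadline = patient)
  reverse-coded as `101 − timing`, gift compensation (1–50) kept as-is;
  all z-scored against the cohort with the sample SD (n−1), so higher
  always means more impulsive.

## Statistics

Two-group contrasts are one-way ANOVAs (F = squared pooled t, df = (1,
n₁+n₂−2)) with `η² = F·df₁/(F·df₁ + df₂)`; covariate-adjusted contrasts fit
OLS with dummy-coded categorical covariates, where the single-df group term
makes the Type III F equal the squared coefficient t. Mediation follows
the PROCESS conventions: OLS path models on variables standardized upstream
(sample SD), indirect effects as products of path coefficients (`a·b` for
one mediator; `a1·d21·b2` for the serial chain, with the two single-mediator
routes reported alongside; one `aⱼ·bⱼ` per mediator in the parallel model),
and 95% percentile intervals from 5,000 case-resampled bootstrap replicates
(percentile, not BCa — the PROCESS default). Bootstrap replicates are
solved in one batched normal-equations pass, so full-size bootstraps cost
~0.2 s. All p-values are two-sided. The binary treatment is coded
0 = control, 1 = separated; median splits assign ties to the low group.

## The synthetic cohort generator

The generator emulates the four study shapes with the reported group
parameters as defaults: money weights 0.047 (SD 0.029) control vs 0.023
(SD 0.026) separated; delay weights −0.009/−0.010 (SD 0.002); state
anxiety 29.11 (4.23) vs 37.50 (7.25); trait anxiety with only the printed
trivial difference; SAS totals near 34 (SD ≈ 2.8) on the 11–55 scale;
scenario responses at the printed group means. Where the studies are
silent the defaults are: 36 participants per group, 80 trials per
participant over a deterministic 80-pair menu (immediate amounts {10, 14,
17, 20, 25} × money differences {6, 11, 16, 21} × delays {10, 20, 30, 60}
days, which contains the worked-example pair $17 now vs $38 in 30 days),
`a ~ 1.8 (0.3)`, `t0 ~ 0.35 (0.08)`, `z ~ 0.5 (0.05)`, `dc ~ 0.05 (0.10)`
— values that give RT distributions and choice rates in the range typical
of laboratory intertemporal choice.

SAS totals are built from item-level responses under a parallel-items
model: items are `c·(θ + ε)` shifted to the item mean, with `var(ε)` set
from the target Cronbach α (0.80) via the mean inter-item correlation
`r̄ = α/(k − (k−1)α)` and `c` scaling the total to the configured SD. The
latent trait θ is drawn jointly with state anxiety at a latent correlation
`r/√α` (the Spearman–Brown attenuation), so the *total*-score correlation
hits the configured 0.414 in the separation group; an infeasible target
(latent r outside [−1, 1]) raises rather than being silently repaired.
Gaussian draws onto bounded scales are truncated by resampling, not
clipping, to avoid boundary spikes.

The titration cohort draws latent `k` lognormally (median 0.01/day,
log-SD 0.7 — indifference points centred near the grid's upper-middle) and
answers each grid amount X by a logistic comparison with the present value
(temperature 8 currency units; 0 = deterministic). SAS is generated
independently of `k`, emulating the null questionnaire findings. The
mediation harness generates a linear-Gaussian serial chain with
configurable paths (defaults a1 = 0.6, d21 = 0.5, b2 = 0.4 → serial
indirect 0.12, direct effect 0.2, unit residual SDs).

What the generator does *not* emulate: item content and response styles,
missing data, RT contaminants (fast guesses, lapses), demographic structure
(the ANCOVA covariates are pure noise, so the covariate-adjusted path is
exercised mechanically, not matched numerically), and any joint structure
among scenario responses beyond the printed pairwise constraints. Passing
tests therefore show that the estimators recover the structure this
generator encodes — not that the original effects would replicate on new
human data.

## Problem sizes in the standing checks

The validation experiments run at the emulated studies' scale: 20
replicate cohorts of 36 + 36 participants × 200 trials for weight
recovery; 10⁵ simulated passages per grid cell for the simulator oracle;
50 recovery and 200 coverage datasets of n = 72 with 5,000 bootstrap
resamples for mediation calibration. The unit-test suite uses smaller
cohorts (8 per group, 40 trials) for the end-to-end paths.

## Known limitations

* No hierarchical shrinkage: individual estimates at 80 trials are noisy
  (the group-level SD of fitted weights overstates the latent SD).
* `dc` and `wd` are weakly identified on menus with limited delay
  variation; their single-participant estimates scatter widely even when
  `wm`, `a`, `t0` recover well. Group means remain unbiased.
* The exact trial menu of the original task is unpublished; the default
  menu is a documented configuration, and absolute impulsive-choice counts
  depend on it.
* The original studies' raw data are unreleased, so their fitted weights,
  correlations and mediation coefficients cannot be reproduced exactly —
  only the printed summary statistics (F, η²) and the qualitative structure
  are recomputable, and the package checks those.
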