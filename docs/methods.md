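# Methods

## The model

`motorddm` analyses two-alternative forced-choice data from a 2 (spring
pressure: soft vs stiff) x 2 (set size: 3 vs 5) within-participant design
with the drift diffusion model (DDM). Evidence accumulates from a starting
point `z*a` with drift `v` and unit diffusion coefficient until it hits one
of two absorbing boundaries separated by `a`; the response time is the
first-passage time plus a non-decision time `ter` covering encoding and
motor execution. Responses are accuracy-coded: the upper boundary is the
correct response, so `z` is a bias toward correct responding.

The full model adds across-trial variability: drift ~ Normal(v, sv),
relative start ~ Uniform(z ± sz/2), non-decision time ~ Uniform(ter ± st/2).
A fixed 5% of trials are treated as contaminants from a uniform outlier
distribution over (0, 5 s] (the response window), split evenly over the two
responses, so each trial's likelihood is
`(1 - p_outlier) f(rt, response) + p_outlier / (2 * 5.0)`. The contaminant
fraction is fixed, not estimated.

The scientific question is dissociation: a motor-load manipulation (stiffer
response springs) should move non-decision time (and possibly boundary
separation, via response caution) but not the drift rate, while a
cognitive-load manipulation (longer strings) should move the drift rate.
The nine-model space enumerates which of v/a/ter vary by which factors;
model 1 lets all three vary by both factors, model 4 restricts the drift to
a set-size effect only, model 9 frees only the drift.

## Likelihood

The Wiener first-passage density is evaluated by the standard dual series
representation, switching per evaluation between the small-time
(image/reflection) and large-time (Fourier sine) expansions according to
which needs fewer terms for the requested absolute truncation error
(default `series_tolerance = 1e-7`).

Across-trial drift variability is integrated analytically: the density's
drift dependence factorises as `exp(-a z v - v^2 t / 2)`, which is Gaussian
in `v`, so mixing over Normal(v, sv) multiplies the zero-drift density by
`(1 + sv^2 t)^{-1/2} exp[(a^2 z^2 sv^2 - 2 a z v - v^2 t) / (2 (1 + sv^2 t))]`.
This is exact (it is the closed form of the quadrature the variability
integral would otherwise need) and is verified against a Monte-Carlo
mixture oracle in the tests. The st and sz integrals have no closed form
and use Gauss–Legendre quadrature with `quadrature_points` nodes per active
dimension (default 11; dimensions with zero range are skipped exactly).
Density normalization over both boundaries holds to 1e-3 across the
parameter ranges the analysis visits (tested).

Units and conventions: unit diffusion coefficient (v and a are identified
relative to it); times in seconds; `z` and `sz` are fractions of `a`.

## Simulator

Trials are simulated by Euler–Maruyama paths (default `dt = 1e-4 s`) with
within-step Brownian-bridge crossing detection: after each step the
probability `exp(-2 d0 d1 / dt)` that the bridge between the endpoint
distances `d0, d1` to a boundary touched that boundary is applied. The
bridge correction removes nearly all of the first-passage discretisation
bias of naive Euler checks; at `dt = 1e-4` the simulated RT distribution
matches the numerically integrated density with Kolmogorov–Smirnov distance
about 0.003 at 10^5 trials (tested against < 0.01, and halving dt leaves
the comparison unchanged well within that bound). Trials that do not cross
before `response_window - ter` are emitted as no-responses (essentially
absent at realistic parameters).

## Synthetic-data generator

The generator emulates the study design: 2 counterbalanced blocks (one
spring condition each), 24 practice + 300 experimental trials per block,
150 experimental trials per condition cell, match/no-match balanced within
every (set size, practice) stratum, 5 s response window. Practice trials
use the same parameters as experimental trials. Block randomization imposes
exact balance (equal set-size counts per block, 12/12 in practice).

Subjects are drawn Normal(group mean, between-subject SD) per parameter
node, truncated to the parameter constraints; contaminant trials are
replaced by Uniform(0, 5 s) response times with fair-coin responses and are
flagged in a ground-truth ledger that inference never sees.

Reference group parameters (`reference_group_parameters()`) are the fitted
group posterior means for the letter-comparison task under model 4 —
drift 2.57/1.78 (set size 3/5); boundary 1.78/2.01 (soft, by set size) and
2.14/2.20 (stiff); non-decision time 0.58/0.70 s (soft) and 0.62/0.80 s
(stiff). The group-only values are not constrained by that study's tables
and are set once to field-realistic values: `z = 0.5` (no bias),
`sv = 0.5`, `st = 0.15 s`, `sz = 0.1`, `p_outlier = 0.05`. Between-subject
SDs default to 0.3 (v), 0.25 (a) and 0.05 s (ter).

What the generator does **not** emulate: sequence effects (fatigue,
practice-driven drift changes, post-error slowing), perceptual encoding of
the actual letter/symbol strings, response-box physics beyond the parameter
differences, attentional lapses other than the uniform contaminant, and
any between-block non-stationarity. Passing recovery tests therefore shows
the estimation machinery is faithful to the assumed data-generating
process, not that real data satisfy those assumptions.

## Preprocessing

Order of operations: discard practice trials; exclude participants
(accuracy at or below 0.5 in any single cell; overall accuracy at or below
the group mean minus 2 group SD; overall mean RT outside the group mean ± 2
group SD; group statistics computed once over all participants before any
exclusion); then trim response times below 0.2 s or above the participant's
mean + 3 SD, with thresholds computed once (single pass) on all of that
participant's experimental trials pooled across conditions. Trials without
a response are dropped in the trimming step. "Chance" is 0.5 for this
two-alternative task. With fewer than 3 participants the group-level rules
are skipped with a warning.

A note on trimmed fractions: the first-passage distribution is right-skewed
enough that roughly 1.5–2% of uncontaminated trials exceed mean + 3 SD, so
the trimmed fraction on simulated data is larger than the sub-1% figures
typical of empirical datasets. The trimming also removes exactly the slow
tail that identifies `sv`, which is why recovery studies here (and
elsewhere) underestimate `sv` and, mildly, `a`.

## Priors

Proper, weakly informative: group means v ~ Normal(2, 3), a ~ Normal(1.5, 1)
truncated positive, ter ~ Normal(0.4, 0.3) truncated nonnegative; group SDs
Half-Normal(1) for v and a, Half-Normal(0.2) for ter; z ~ Beta(5, 5);
sv ~ Half-Normal(2); st ~ Half-Normal(0.3) with the joint constraint
`ter - st/2 >= 0` enforced during sampling; sz | z ~ Uniform(0,
min(2z, 2(1-z))). These are explicit choices, not a reconstruction of any
toolbox's internal defaults. Prior-predictive simulation puts most prior
draws' median RT inside the response window (tested).

## Sampler

Adaptive Metropolis-within-Gibbs in a **centered** parameterization:

- Subject-level nodes (v, a, ter per induced condition cell) are updated
  single-site with Gaussian random-walk proposals, simultaneously across
  subjects — valid because subjects are conditionally independent given the
  group nodes — so each parameter's sweep costs one vectorized pass over
  the affected trials.
- Group means and SDs have likelihood-free conditional updates (the
  centered hierarchy makes their conditionals depend only on the subject
  values), at negligible cost.
- The four group-only nuisance nodes (z, sv, st, sz) are updated as one
  joint Metropolis block whose proposal covariance is estimated from the
  burn-in history (Haario-style adaptive Metropolis); these parameters are
  strongly correlated in the posterior and a diagonal proposal mixes them
  poorly.

Proposal scales adapt during burn-in only (Robbins–Monro toward 0.44
acceptance for scalar updates, 0.25 for the block), so retained draws come
from a fixed kernel. Chains are initialised from EZ-style moment estimates
(logit-accuracy and RT mean/variance per subject and cell) with small
jitter, and re-initialised up to 10 times if the starting likelihood is not
finite. Per-draw total deviance (-2 log mixture likelihood) is recorded for
model comparison. The centered parameterization was chosen over a
non-centered one because each subject contributes 150–300 trials — a
strong-data regime where centered chains mix better — and because it makes
group-node updates free of full-data likelihood passes, which is what holds
a 2-chain x 5000-iteration fit to minutes rather than hours.

Sampler correctness is verified with a conjugate harness: a unit-variance
Gaussian likelihood swapped in for the Wiener likelihood turns the model
into a normal hierarchy whose posterior is known in closed form, and the
sampler must match it within Monte-Carlo error.

Weak identification: with accuracy near ceiling and tails trimmed, `z`,
`sz` and especially `sv` carry little information; their chains move slowly
(low effective sample size) and `sv` is systematically underestimated on
trimmed data. The condition-level targets (v, a, ter) recover within the
stated tolerances regardless; treat nuisance posteriors as nuisance.

## Model comparison

`pD = Dbar - D(posterior means)` (Spiegelhalter plug-in), `DIC = Dbar + pD`,
`BPIC = Dbar + 2 pD` (doubled penalty; lower is better). The plug-in
deviance evaluates subject-level nodes at their own posterior means by
default (hierarchical practice focusing on the subject-level likelihood); a
group-level plug-in is available via `plugin_level="group"`. The
independence check reports mutual mean-in-95%-interval containment for
soft-vs-stiff drift nodes wherever the fitted model has them, and says "not
applicable" when it does not.

## Behavioral statistics

Bayes factors for the four ANOVA-style effect models (spring, set size,
both, both + interaction) against a subject-only null use the BIC
approximation `BF = exp((BIC_null - BIC_model) / 2)` over repeated-measures
linear models on subject-cell means. This is a documented stand-in that is
monotone in evidence and scale-invariant in the dependent variable; it
approximates, and does not replicate, default-Cauchy ANOVA Bayes factors.
Inclusion Bayes factors compare the best model with and without each
effect. Cell RT means include correct and error responses by default
(switchable). Correlation matrices between subject-level posterior means
and assessment scores (SDMT oral/written, NHPT) use pairwise-complete
Pearson correlations and carry an explicit caveat: hierarchical shrinkage
biases such correlations, so they are descriptive.

## Problem sizes and numerical defaults

- Likelihood: `series_tolerance 1e-7`; `quadrature_points 11` (default);
  fits use 7 nodes per dimension — at 7 nodes the st/sz quadrature error is
  far below posterior uncertainty, and likelihood evaluation is the entire
  fit cost.
- Simulator: `dt 1e-4 s` for datasets, `1e-3 s` for posterior-predictive
  replicates.
- Recovery studies: 12 subjects x 300 experimental trials, 2 chains x 5000
  iterations (1000 burn-in) in the acceptance script; the test suite runs
  the same data with 2000/700 iterations (model 4) and single-chain
  1500/500 fits (models 1 and 9). Recovery tolerances at this size:
  ±0.2 (v, a), ±0.07 s (ter).
- Tie-breaks and degenerate inputs: empty trial tables yield zero log
  likelihood and empty reports; cells without error trials report absent
  (NaN) quantiles, not zeros; participants with fewer than 2 responded
  trials have no RT SD, so only the 0.2 s floor applies.

## Known limitations

- `sv` (and with it, mildly, `a`) is underestimated when the analysis
  pipeline trims slow responses; this is a property of trimming plus the
  DDM, not of the sampler, and it mirrors what any such pipeline does to
  real data.
- The BIC-approximate Bayes factors are not comparable in absolute value
  to default-prior ANOVA Bayes factors; only their ordering and order of
  magnitude are meaningful.
- Single-site random-walk sampling needs thousands of iterations; gradient
  samplers would be more efficient but are out of scope.
- The credible-interval overlap check is a descriptive criterion, not a
  formal test of parameter equality.
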