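# Methods

## Model

Let `D` be the unobserved true status with prevalence `π = P(D=1)`, and
let three binary tests have sensitivities `Se_i` and specificities `Sp_i`.
Tests 1 and 2 (the two standardized scales) are conditionally dependent
given `D`; their dependence is parameterized additively by the conditional
covariances `C+ = cov(T1,T2 | D=1)` and `C− = cov(T1,T2 | D=0)`:

    P(T1=t1, T2=t2 | D=1) = Π_i Se_i^{t_i}(1−Se_i)^{1−t_i} + (−1)^{t1+t2} C+

and analogously for `D=0` with specificities and `C−`. Test 3 (the expert)
is conditionally independent of the scales. Marginalizing over `D` gives
the eight cell probabilities `p_{t1 t2 t3}`, and the observed counts `Y`
are multinomial(n, p). The log-likelihood is the multinomial kernel
`Σ Y_t log p_t`; a zero cell probability with a positive count evaluates
to −∞ rather than raising, so samplers treat such states as rejected.

Keeping all four conditional joint probabilities per stratum inside [0, 1]
requires `(a1−1)(1−a2) ≤ C ≤ min(a1,a2) − a1·a2` for the relevant accuracy
pair. For tests at least as good as chance (`a1 + a2 ≥ 1`, the regime of
every analysis here) these bounds are exactly the admissibility condition;
below that the lower bound additionally needs `C ≥ −a1·a2`, and the
parameter validator enforces cell admissibility directly so both checks
always hold for accepted parameter vectors.

The model has 9 parameters but the multinomial has 7 degrees of freedom,
and the likelihood is exactly invariant under the label swap
`π → 1−π, Se_i ↔ 1−Sp_i, C+ ↔ C−` (verified as a property test). The
inference is therefore prior-driven in two ways: informative accuracy
priors both localize the 2-dimensional null ridge and suppress the mirror
mode. The sampler reports the fraction of retained draws in the mirror
region (`Se_i + Sp_i < 1` for all i) as a diagnostic; it is 0 in all
packaged analyses.

## Priors and elicitation

Accuracy priors are Beta(α, β), elicited from "most probable value m,
95% sure the quantity is at least q" statements using the mode-preserving
parameterization `α = 1 + m·k`, `β = 1 + (1−m)·k`, which has mode exactly
m for every `k > 0`. `k` is solved so that the beta CDF at q equals the
stated lower-tail probability (0.05 for "95% sure at least"), by Brent's
method on `k ∈ [1e−6, 1e6]`; the CDF at fixed `q < m` is monotone
decreasing in `k`, so the root is unique when it exists. Statements whose
tail mass exceeds the uniform limit (lower-tail mass above q itself) are
rejected as infeasible. The packaged elicitations are:

| parameter          | statement                | resulting prior      |
|--------------------|--------------------------|----------------------|
| Se1, Se2 (scales)  | mode 0.70, ≥ 0.50 @ 95%  | Beta(13.322, 6.281)  |
| Sp1, Sp2 (scales)  | mode 0.80, ≥ 0.50 @ 95%  | Beta(7.549, 2.637)   |
| Se3 (expert)       | mode 0.80, ≥ 0.70 @ 95%  | Beta(48.283, 12.821) |
| Sp3 (expert)       | mode 0.85, ≥ 0.60 @ 95%  | Beta(10.657, 2.704)  |

Prevalence takes a uniform prior on [0, 1]. The covariances take uniform
priors on their admissible ranges, which depend on the current
accuracies, so the joint prior is hierarchical:
`f(θ) = f(Se, Sp, π) · f(C+ | Se1, Se2) · f(C− | Sp1, Sp2)`. The
`−log(range)` normalizers of the conditional uniforms are part of the
prior log-density — omitting them would tilt the posterior of the
accuracies that control the ranges.

## Posterior sampling

The posterior is sampled by single-site random-walk Metropolis-within-Gibbs
over the nine components (the additive covariance terms destroy
beta-multinomial conjugacy, so no Gibbs conditionals exist in closed
form). Numerical choices:

* **Accuracies and prevalence** are proposed on the logit scale (normal
  increments; the `x(1−x)` change-of-variables Jacobian enters the
  acceptance ratio), keeping them strictly interior.
* **Covariances** are proposed by a reflected random walk on their current
  admissible interval (symmetric, no Jacobian).
* **Accuracy–covariance coupling:** an update of Se1/Se2 (Sp1/Sp2) moves
  the admissible interval of C+ (C−). The proposal is joint: the
  covariance is linearly rescaled to preserve its relative position in the
  interval, and the rescaling Jacobian (new range / old range) enters the
  acceptance ratio. Every emitted draw is therefore valid without silent
  truncation.
* **Tuning:** proposal scales start at 0.3 (logit components) and 0.05
  (covariances) and are adapted every 100 burn-in iterations toward a
  20–40% acceptance rate, then frozen, so the post-burn-in chain is a
  genuine Markov chain.
* **Defaults:** 3 chains × 60,000 iterations, 10,000 burn-in, thinning 5
  (30,000 retained draws). On the packaged 204-patient table this takes
  roughly half a minute on one CPU and yields effective sample sizes above
  10,000 and split-R̂ below 1.001 for every parameter. These lengths are
  comfortable overkill for this posterior; the test suite uses shorter
  chains where the assertion tolerance permits.
* **Initialization:** chain 0 starts at the naive accuracy estimates of
  the packaged data (rounded to 3 decimals) with covariances at 0;
  additional chains get deterministic overdispersed jitter (SD 0.5 on the
  logit scale). Per-chain random streams are spawned from one master seed
  via `numpy.random.SeedSequence`, and all randomness is consumed in a
  fixed order, so results are bit-reproducible given (data, prior,
  config).

Summaries are pooled posterior medians and equal-tailed 2.5%/97.5%
quantiles (the interval type is equal-tailed percentile; HDIs are out of
scope). Convergence diagnostics (rank-normalized split-R̂, bulk ESS,
MCSE of the median) come from ArviZ; with a single chain the split-chain
variant is used and noted. The convergence report flags parameters with
R̂ above 1.05 by default.

## Naive comparison estimator

The naive method conditions on one test as if it were a gold standard:
`Se_i = #(T_i=1, ref=1)/#(ref=1)`, `Sp_i = #(T_i=0, ref=0)/#(ref=0)`,
prevalence = proportion reference-positive, each with a Wald interval
`p ± 1.959964·sqrt(p(1−p)/m)` clipped to [0, 1]. Wald was chosen because
it reproduces the published comparison table: all five point estimates
match exactly at 3 decimals and 8 of 10 interval endpoints match exactly,
with the remaining two (Se1 lower, Sp1 upper) one unit off in the third
decimal — a discrepancy no consistent interval method or rounding rule
removes, so agreement for endpoints is asserted to within one unit in the
last printed digit. Display rounding is half-up to 3 decimals; full
precision is retained internally.

## Synthetic data

`simulate_subject_level` draws, per subject, `D ~ Bernoulli(π)`, then
`(T1, T2)` by inverse-CDF over the four-cell conditional table in fixed
order (1,1), (1,0), (0,1), (0,0) — this is where the covariance enters —
then `T3` independently given `D`. `simulate_counts` is defined as the
pattern aggregation of the subject-level draw under the same seed, which
is distributionally one multinomial(n, p) draw and makes the two
generators exactly consistent. The generator emulates the multinomial
sampling structure the model assumes — and only that: no covariates,
missingness, verification bias, or drift in expert behaviour. Passing
recovery tests therefore show the inference machinery is correct under
the model's own assumptions, not that the model describes any particular
real population.

Recovery is asserted only at generating values consistent with the prior
modes (Se = (0.7, 0.7, 0.8), Sp = (0.8, 0.8, 0.85), covariances 0, with
prevalence 0.648 — the posterior estimate for the packaged cohort, since
the flat prevalence prior has no mode of its own) at n = 5,000: with 9
parameters and 7 degrees of freedom, prior-discordant truths are not
recoverable and are not asserted.

## Known limitations

* Exactly three tests, exactly one dependent pair, binary outcomes,
  homogeneous accuracies (no covariates) — by design.
* The constrained-uniform covariance priors make the prior of `C±`
  depend on the accuracies; this is the standard construction but means
  "uniform" is conditional, not marginal.
* Wald intervals in the naive estimator are known to undercover near 0
  and 1; they are kept because the naive method is a faithful comparison
  baseline, not a recommended analysis.
* With weak (all-uniform) priors the posterior is bimodal by the mirror
  symmetry; the mirror-mode fraction diagnostic should be checked before
  trusting any fit with non-informative priors.
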