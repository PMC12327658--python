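# Methods

## The maximum-difference model

A Case-1 best-worst scaling task presents a choice set *T* of *k* items
and records which item the respondent marks best and which worst.  Under
random utility theory each item *i* has a latent utility γᵢ; the model
fitted here assigns the ordered pair (*a* best, *b* worst), *a* ≠ *b*,
the probability

P(a, b | T) = exp(γ_a − γ_b) / Σ_{(u,v) ∈ T, u≠v} exp(γ_u − γ_v).

Two standard single-choice models are implied by the same scale: the
best-choice logit Q_T(i) = exp(γᵢ)/Σ_r exp(γ_r) and the worst-choice
logit R_T(i) = exp(−γᵢ)/Σ_r exp(−γ_r).  Representing the worst scale as
the negated best scale makes the two-item reversal identity
Q_{a,b}(a) = R_{a,b}(b) hold exactly; the package stores a single utility
vector and derives everything else from it.

Assumptions worth keeping in mind: one utility vector for the whole
sample (no respondent heterogeneity), independence across tasks and
respondents, forced choice (every shown task is answered with one best
and one worst), and no position or order effects.

## Estimation

The log-likelihood is a sum of pair-multinomial terms over answered
tasks, concave in γ.  Utilities are only identified up to a constant, so
the fit is parameterised by the first v−1 utilities under effects
(sum-to-zero) coding; the omitted baseline's utility is minus their sum.
This coding was chosen over reference-at-zero because the post-estimation
quantities (marginal probabilities, contrasts against the baseline) are
then read directly off the completed utility vector.

Records are aggregated to per-block pair counts before optimisation, so
one likelihood evaluation costs O(b·k²·v) independent of the number of
respondents.  The optimiser is a trust-region Newton method
(`scipy.optimize.minimize(method="trust-exact")`) with analytic gradient
and Hessian, started at zero utilities — harmless, since the objective is
concave.  Convergence is declared when the score's infinity norm falls
below the `tolerance` option (default 1e-8); failure to reach it is
flagged on the results object rather than raised.

The covariance of the free parameters is the inverse observed information
at the optimum, mapped to all v items through the sum-to-zero contrast
(the resulting v×v matrix has rank v−1, as it must).  Confidence
intervals are Wald intervals at z = 1.959964; p-values are two-sided
Wald.  No multiplicity correction is applied to the pairwise contrast
table — the table reports raw p-values, and users who need familywise
control should adjust downstream.

Degenerate inputs: an item never chosen best or worst, or chosen
best (worst) in every task that shows it, makes its MLE diverge; the
model constructor detects this separation and raises an error naming the
offending items instead of returning a spurious fit.

### Fit statistics

The likelihood-ratio statistic is 2(ℓ̂ − ℓ₀) against the equal-utilities
null (uniform pair probabilities), with df = v−1.  Information criteria
use AIC = −2ℓ̂ + 2(v−1) and BIC = −2ℓ̂ + (v−1)·ln n with effective sample
size n = number of answered tasks; AICc adds the usual small-sample
correction.  Other software may count n differently (respondents, or
expanded pairs), so information criteria are comparable only within one
convention; the package documents its own and does not attempt to match
any particular program's output.

## Design construction

Estimating all utilities with equal precision calls for a balanced
incomplete block design: v items in b blocks of size k with common
replication r and pair co-occurrence λ.  The package builds symmetric
cyclic designs: an exhaustive, deterministic search finds the
lexicographically smallest (v, k, λ) difference set containing 0 (for the
15-item, 7-option layout there are only C(14, 6) = 3003 candidates), and
its v cyclic shifts form the blocks.  This yields r = k and
λ = k(k−1)/(v−1) — for (15, 7) the (15, 15, 7, 7, 3) design in which
every item appears 7 times and every pair co-occurs 3 times.  The
necessary counting identities λ(v−1) = k(k−1), bk = vr and
r(k−1) = λ(v−1) are enforced and re-verified by enumeration in
`check_balance`, which also validates externally supplied design CSVs.
Within-block order is the cyclic-shift order; the CLI can shuffle
presentation order with a seeded flag, off by default, since no
position-balancing guarantee is claimed.

## Post-estimation conventions

- **Marginal probability**: the logit share exp(γᵢ)/Σⱼ exp(γⱼ) over all
  v items, baseline included.  It is translation-invariant and sums
  to 1.  This transform, applied to the reference study's printed
  estimates after completing the baseline at minus their sum, reproduces
  all ten of that study's quoted MP values to four decimals, which is
  how the convention was fixed.
- **Contrasts**: DUE(i, j) = γᵢ − γⱼ with SE = √(varᵢ + varⱼ − 2covᵢⱼ);
  the table is antisymmetric and satisfies the triangle identity
  exactly.  Contrasts recomputed from 3-decimal printed inputs match
  quoted values to ±0.01, the slack induced by input rounding.
- **GUD** is computed over all items including the baseline.
- **Significance**: a utility (or contrast) is flagged significant when
  its 95% CI excludes zero, with strict inequalities — an interval
  touching zero is not significant.
- **Count scores**: best and worst frequencies per item, their
  difference, and a standardised score dividing by replication ×
  respondents, which lies in [−1, 1].  These are model-free and serve as
  a sanity cross-check on the model ranking.

## Synthetic data

The generator emulates the reference study layout: one shared design,
every respondent answering every block, 300 respondents by default.  The
default choice rule draws the (best, worst) pair in a single categorical
draw from the maximum-difference distribution — the same family the
estimator fits, so recovery studies measure the estimator, not model
mismatch.  A `sequential_best_worst` rule (best from the best logit, then
worst from the worst logit over the remaining k−1 items) is provided as
a robustness probe, since the cognitive process generating real
responses is unobserved; the two rules coincide when all utilities are
equal.  Randomness comes from NumPy's PCG64; the draw order is fixed
(respondents outer, blocks inner, one uniform per categorical draw via
inverse CDF), so a seed pins the dataset exactly.

What the generator does *not* emulate — respondent heterogeneity,
inattention and straight-lining, order and fatigue effects, missing
tasks — bounds what passing tests show: they demonstrate correct
recovery under the model's own assumptions, not robustness of real
surveys to their violation.

## Problem sizes used in the checks

Deterministic worked-example checks run on the printed reference
estimates (instant).  The Monte-Carlo calibration uses 200 replicates of
the full study layout (300 respondents × 15 tasks) for bias, coverage
and null LR calibration; distributional checks on the generator use up
to 10⁵ draws on a single block.  These sizes give binomial/Monte-Carlo
noise comfortably inside the asserted bands (e.g. coverage pooled over
15 items × 200 replicates has a standard error of ~0.4 percentage
points).

## Known limitations

- Single utility vector: no mixed logit, latent-class or hierarchical
  Bayes extensions, and no anchored/dual-response BWS.
- The difference-set constructor covers symmetric designs (b = v); other
  block counts must be supplied externally and validated with
  `check_balance`.
- Information criteria depend on the effective-n convention (above) and
  should not be compared across software.
- A respondent-consistency statistic for repeated scenarios is not
  implemented.
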