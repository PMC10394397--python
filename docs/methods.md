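# Methods

## Model and assumptions

Responses are normal with common known variance σ² (default 1): control
observations are N(μ₀, σ²) and an observation on experimental arm k is
N(μₖ, σ²). Hypotheses are one-sided, Hₖ: μₖ = μ₀ against μₖ > μ₀ (larger
response better). The trial structure is a burn-in block (block 0) with a
fixed, equal allocation of b patients per arm including the control,
followed by B adaptive blocks; in block j the scheme allocates a fixed
total of experimental patients across arms, while the control receives a
per-block sample size fixed by design. Adaptation uses only data from
blocks 0..j−1: allocation probabilities and the error-inflator state are
evaluated once per block boundary. Every adaptive block places at least
one patient on every experimental arm; allocators enforce this by
reassigning the last drawn patients of a block to any arms left empty, and
the auxiliary-design generator applies the same guard so that weight
denominators are always positive.

## The adjusted statistic

The auxiliary design is a randomization list fixed before the trial
(uniform draws over arms, redrawn per simulated replicate). The weight
recursion is derived by matching, at every block boundary, the conditional
variance of the remaining weighted statistic to the value it would have
under the auxiliary design:

    (ñ_{j,k} + m_{j+1,k}) / w_j² = m_{j,k} / w_{j-1}²,  w_0 = n_k,

giving the square-root update `w_j = w_{j-1}·sqrt((ñ+m)/(n+m))` and the
final-block rule `w_B = w_{B-1}·sqrt(ñ_B/n_B)`. The per-block identity
telescopes pathwise, so the weighted sum Ũ always has conditional total
variance σ²/n_k; positivity of every w_j is automatic because each update
is a ratio of positive counts. A linear (un-rooted) update would not
satisfy the variance identity; it is kept behind an internal switch purely
so the tests can demonstrate the failure. Agreement of the closed form
with a per-block numeric root-finder is asserted to 1e−10.

Since the control arm never adapts, μ₀ is estimated by the overall control
mean and subtracted post hoc: Ũ* = Ũ − (Σvⱼ)X̄₀(n₀), standardized by
σ·sqrt(1/n_k + (Σvⱼ)²/n₀). With μ₀ known, the resulting statistic is
exactly N(0,1) under Hₖ for any adaptation rule (the increments form a
martingale with conditionally Gaussian terms whose variances are
predictable and sum pathwise to a constant); we verify this empirically to
Monte-Carlo precision. Substituting X̄₀ introduces a slight dependence
between the multiplier Σvⱼ and the experimental data, so the statistic is
then standard normal only to a good approximation: under the designs
studied here the true variance of T̃ is within about 0.01 of 1 and the 5%
one-sided rejection rate within about 0.3 percentage points of nominal,
conservative or anti-conservative depending on how the scheme couples
allocation to responses. The operating-characteristic tests bound this at
the resolution of their replicate counts.

When σ² must be estimated, per-block pooled estimators (degrees of freedom
Σₖ ñ_{j,k} − K − 1) are combined with equal weights; the standardized
statistic is then only asymptotically normal, and the implementation flags
this mode accordingly.

## Multiple testing and interim looks

Closed testing over the 2^K − 1 intersections is explicit for K ≤ 10
(K ≤ 3 in the shipped study): the pooled closed z-test sums burn-in,
auxiliary and realized counts of the intersection's arms block by block,
pools their responses, and runs the same weighting algorithm on the
pseudo-arm — the only construction under which the single-arm algorithm
applies unchanged. The max-statistic test uses Φ⁻¹(1 − α/|𝒦|) per
intersection; its closure coincides with Holm's step-down shortcut, and
the suite checks the two never disagree (with statsmodels' Holm as an
independent oracle). Interim analyses truncate the algorithm's horizon at
a pre-specified block S (final-block rule applied at S, control mean over
blocks 0..S) and spend α over looks additively; the monitor refuses
statistics at unplanned looks because a data-chosen analysis time would
invalidate the calibration. No improvement over Bonferroni spending is
attempted: the correlation between interim and final statistics depends on
future contribution coefficients unavailable at the interim.

## Allocation schemes

*Bayesian adaptive randomization.* Allocation probabilities are tempered
posterior probabilities πₖ ∝ P(μₖ > μ₀ | data)^γ with γ = 0.5 by default.
The posterior model is conjugate normal with known σ² and flat priors, so
P(μₖ > μ₀ | data) = Φ((x̄ₖ − x̄₀)/sqrt(σ²/ñₖ + σ²/n₀)) on all data
accumulated through the previous block, control included. γ = 0 reduces
exactly to equal randomization.

*Error inflator.* An adversarial rule: the favored arm (arm 1) receives
all experimental patients of a block except one per other arm while its
running mean (all its observations, burn-in included) stays below a fixed
threshold of 0.5; once the mean is ≥ 0.5 the state flips — absorbing — and
the favored arm gets exactly one patient per block, the rest randomized
equally over the other arms. The crossing state is evaluated at block
boundaries. Published results for this scheme could also be consistent
with monitoring the favored arm's running mean after every patient within
a block; that variant raises the probability of ever crossing from ~0.14
to ~0.20 under a null favored arm and would shift the unfavored arms'
power up by a few percentage points while pushing all familywise error
rates slightly higher. We implement the boundary-checked reading, which
matches the published global-null error rates most closely; the residual
few-percent gap on unfavored-arm power under the alternative is a known
consequence of this reading and is the first place to look if tighter
agreement is needed.

*Fixed.* Equal-probability draws with the same ≥1-per-arm guard.

## Simulation engine and numerics

Every statistic the package computes is a function of per-arm, per-block
response sums and counts, so the Monte-Carlo engine simulates replicates
in count/sum space: given the counts, a block's response sum is exactly
N(cμ, cσ²). This is distribution-identical to per-patient simulation and
keeps 10⁵-replicate scenarios to a couple of seconds on one CPU, which is
what makes the full-study reproduction (twelve scenarios at 4×10⁵
replicates) a ~1-minute run. Replicates within a batch share one seeded
generator; the per-patient object path (`simulate_trial`) remains
reproducible from its own seed and is used for single-trial analysis, the
case study and the CLI. Batches are processed in chunks of 2×10⁵
replicates to bound memory. All computation is in double precision with
no rounding of intermediate weights; one-sided p-values use the normal
survival function directly.

Default study conditions follow the shipped design: burn-in 5 per arm,
three adaptive blocks of 40 experimental and 20 control patients, α =
0.05 one-sided, σ² = 1, true control mean 0. The case-study configuration
uses two dose arms (burn-in 8 + 8, three blocks of 15) against 31 controls
with standardized true means 17.3/3.5, 66.2/3.5 and 72.3/3.5; only the
control total is fixed by its source, so the per-block control split
(7 burn-in + 8 + 8 + 8) is a package choice that the final statistic is
invariant to.

## What the generator does and does not emulate

The generator draws idealized normal responses, observed immediately and
completely at each block boundary, with a known common variance and no
covariates, dropout, or delayed outcomes. Passing tests therefore
demonstrate the calibration and power properties of the testing procedures
under the stated model — not robustness to non-normal outcomes, response
delay (which blunts block adaptation in practice), or variance
misspecification. The estimated-variance mode is provided but its
calibration is asymptotic only.

## Known limitations

- Exactness of the adjusted statistic holds for known μ₀; the control-mean
  substitution makes the shipped statistic approximately calibrated (see
  above). The closed z-test can exceed the nominal level by a few tenths
  of a percentage point under adversarial schemes.
- The method requires block-wise adaptation with a fixed control
  allocation; fully sequential RAR and adaptive control allocation are out
  of scope, as are post-testing confidence intervals and a Dunnett-type
  parametric closure (the statistics' correlation depends on the
  adaptation and is not available).
- Single-run weight exhibits are seed-dependent illustrations, not
  reproducible targets; reports print weights rounded for display only.
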