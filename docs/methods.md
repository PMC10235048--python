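# Methods

This note documents the models, estimators, and simulation conventions the
package implements, the design decisions taken where several choices were
defensible, and what the synthetic-data studies do and do not establish.

## Task model

A trial presents two independent two-prize lotteries. The high-variance
(hiVar) lottery has prizes EV ± 60 (range 120); the low-variance (loVar)
lottery has prizes EV ± 15 (range 30). The EVs sum to 500 points exactly;
their difference ΔEV = EV(hiVar) − EV(loVar) is drawn uniformly from the
21-value design set {−110, −90, −80, …, −10, 0, 10, …, 90, 110} (note ±100
is absent). One prize per lottery is drawn with probability 1/2,
independently, so the realized sum is always one of {425, 455, 545, 575} —
never the 500-point criterion. Sessions are four 126-trial blocks:
Observe, the two instrumental blocks (Estimate, Intervene) in
counterbalanced order, and a closing Observe block. Payoffs follow the
block rule (sum of draws; sum-or-zero for the above/below-500 guess;
unrevealed draw plus the kept-or-swapped revealed amount). Bonuses take
one uniformly chosen trial per block at 2000 points per dollar. Prizes are
stored as floats even though every design-set ΔEV yields integral prizes;
a `permissive` flag admits off-design ΔEV values (used for the classic
−100 illustration) without relaxing the default validation.

### Normative quantities

All normative values are exact enumerations (21 ΔEV values × 4 draw
combinations), not simulations. After any reveal the possible sums are the
observed prize plus the other lottery's two prizes, so the residual range
equals the unrevealed lottery's range; the optimal above/below-500 guess
is certain after a hiVar reveal and indifferent (accuracy 1/2) after a
loVar reveal, for every ΔEV in the set. **Tie convention:** an indifferent
guess is scored by averaging the two guesses' payoffs, making expected
earnings equal 0.5 × E[sum] = 250 points/trial for an always-loVar
Estimate policy. A payoff-greedy tie-break is not equivalent — always
guessing "above" earns 280, because the straddling sums are asymmetric
around the observed prize — and is available via `tie_break="above"`. The
accuracy-indifferent convention is the default because it makes guess
accuracy policy-independent at ties.

## Choice models and estimation

Reveal choices are modeled per participant-block as Bernoulli with

- bivariate: p(reveal hiVar) = σ(b (a + x)), x = ΔEV / 110 ∈ [−1, 1];
  `a` is uncertainty sensitivity (horizontal offset), `b` EV sensitivity;
- univariate: p(reveal hiVar) = σ(c), a constant rate.

Only trials with reaction times inside the 0.5–10 s window enter the fits;
trials are aggregated by ΔEV level (the likelihood is exchangeable within
level), which makes the cost of a fit independent of trial count.

**Priors.** Independent Normal(0, SD 5) on each parameter. The notation
N(0, 5) is read as a standard deviation of 5 (the convention of the usual
normal-density parameterization in the original tooling); recovery results
are insensitive to reading it as variance 5, and `prior_sd` is exposed.

**Optimization.** The MAP is found by L-BFGS-B with analytic gradients
from five starts — the origin and ±2 on each axis — because the posterior
has a flat ridge at b = 0 (there p = 1/2 for every `a`, so the likelihood
cannot distinguish intercepts) and a near-symmetry (a, b) ↔ (−a, −b) for
weak-slope data. Gradient tolerance 1e−8; the univariate problem is solved
by bounded scalar minimization on c ∈ [−30, 30] (xatol 1e−10). Tests
verify the MAP against a brute-force lattice search refined to 0.001
resolution, including the property that the optimizer never falls below
the dense-grid optimum.

**Confidence intervals.** 95% Wald intervals from the observed information
of the log posterior (central-difference Hessian at the MAP, step 1e−4).
The rate-scale interval for the univariate model is σ applied to the
endpoints of the c interval. When the Hessian is singular (pathological
data) the fit is flagged rather than silently reported.

**Model comparison.** BIC(H) = −2 log L + k log n with k = 2 or 1 and
n the number of valid trials. log L is the *log posterior density at the
MAP* (likelihood plus prior density, normalization included); a
`penalized=False` flag gives the conventional pure-likelihood BIC.
A participant-block is EV-sensitive by default and labeled EV-insensitive
only when the univariate model is favored by more than 4.6 BIC units
(Bayes factor 10). EV-insensitive fits split by the rate CI: Random when
it covers 1/2, Uncertainty-only when entirely above, and LoVar-preferring
when entirely below — the last case is counted separately rather than
merged into Random, since a credible loVar preference is not random
sampling. The `robust` flag records whether the EV-sensitivity verdict
survives reversing the burden of proof (criterion −4.6), which is
equivalent to |ΔBIC| ≥ 4.6.

**Sign-flip regime.** For near-flat slopes the likelihood constrains
roughly the product a·b, so the sign of `a` follows residual noise in `b`.
MAP fits of strict uncertainty samplers (c = 3) land at |b̂| ≈ 0.6–1.6
with a·b ≈ 3 and negative â in a large minority of runs; the diagnosis
therefore flags |b̂| < 2 (below the slope range of clearly EV-sensitive
samplers) together with |â| > 2, both configurable, and verifies that the
model comparison reassigns flagged fits with positive ĉ.

**Identifiability at saturated design points.** When the choice curve
saturates over the design (e.g. a = 2, b = 5 gives ~99.8% reveals), the
Fisher information for the marginal parameters collapses (CRLB SDs ≈ 0.36
for a and 1.48 for b at 12,600 uniform trials, correlation −0.98): single
fits cannot recover such parameters tightly, although the cohort-mean
estimate and the product a·b do. Recovery studies in the test suite state
their design points accordingly; mid-range agents (a = 0.5, b = 5) recover
to ±0.1 at the same sample size.

## Dip statistic and unimodality test

The dip of a sample is the minimal sup-norm distance between its empirical
cdf and any unimodal cdf (convex up to the mode, concave after, an atom
permitted at the mode). The implementation works on the unique-value ecdf:
band constraints at the data points reduce the problem, per mode position,
to maximum gaps between the ecdf and convex hulls of its left limits —
gaps that are independent of the distance d — plus a monotonicity link
between the convex and concave pieces. The hull gaps give a lower bound
that is usually exact; when the cross-piece link binds, a binary search on
d with an exact feasibility test (minimal/maximal achievable piece
endpoints via tangent-line envelopes) closes the gap. Atom-at-mode
placements, which matter for heavily tied samples, are enumerated
separately with the left-limit band retained. The statistic equals an
independent linear-programming formulation of the definition on hundreds
of random, tied, and adversarial small samples (see the test suite); a
constant sample returns 0 (a point mass is unimodal), an evenly spaced one
the floor 1/(2n), and a balanced two-point sample the maximum 1/4.

The test bootstraps the null from the uniform distribution — the least
favorable unimodal null — at the observed sample size; p is the fraction
of null dips at or above the observed dip. Constant input is degenerate
and returns p = 1 with a warning.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, with
all parameters exposed in `CohortConfig`:

- **Classes and parameters** (defaults): 65% EV-sensitive with
  a ~ N(0.5, 0.4) and b ~ N(5, 1) truncated at ≥ 3; 15% Random with
  c ~ N(0, 0.15); 20% Uncertainty-only with c ~ N(3, 0.4) truncated at
  ≥ 2.5. The truncations keep the classes identifiable at 126 trials per
  block, which is what the classification-recovery guarantees require; the
  resulting %reveal-hiVar distribution is trimodal like the behavioral
  taxonomy it emulates.
- **Instrumentality**: uncertainty sensitivity (a or c) is shifted by
  +0.4 in the Estimate and Intervene blocks — the order of magnitude of
  the observed task effects — so task-comparison analyses have signal to
  detect. It is a constant additive shift, not a learned adjustment.
- **Instrumental decisions**: Estimate guesses follow the valence of the
  observed prize with probability `obey_prob` (0.95 for engaged classes,
  0.6 for Random — emulating the disengagement that low instrumental
  accuracy indicates); Intervene actions follow switch-iff-below-mean with
  lapse 0.05 (0.4 for Random).
- **Reaction times** are a configurable log-normal placeholder that exists
  so the 0.5–10 s validity filter has something to filter; no RT model is
  claimed, and RT-based analyses beyond pass-through are out of scope.
- **Personality**: 15 questionnaire scores and 3 demographic codes per
  participant, generated standardized. Planted scores are
  λ·z + √(1−λ²)·ε with z the standardized *expected* long-run
  %reveal hiVar of the agent (a noiseless function of its parameters) and
  λ the loading: extraversion −0.5, need for cognition +0.4, thrill
  seeking −0.3, stress tolerance +0.3 by default; every loading on EV
  sensitivity is zero. Demographics are independent of behavior.

Reproducibility: one master seed per cohort, spawned into independent
child streams per participant plus streams for class assignment and
personality, so cohorts are bit-identical across runs and single
participants can be regenerated in isolation.

What passing tests on these cohorts show — and what they do not: they
establish that the estimators, classifiers, and test wrappers recover
known structure and stay calibrated under the null *when the generative
assumptions hold* (stationary logistic policies, independent trials,
Gaussian trait noise). They do not certify behavior on real data with
sequential dependencies, non-logistic policies, item-level questionnaire
noise, or attrition.

## Personality decoding

Targets are continuous per-participant summaries median-split into
high/low (strictly-above-median → high; ties go low and the class balance
is reported). Per bootstrap iteration: a fresh random 50:50 train/test
split; predictors standardized on the training half only; a linear-kernel
SVM (C = 1, coefficients interpretable) or logistic classifier fit on the
true labels and, with the same split, on shuffled training labels; excess
accuracy is the difference of the two test accuracies in percentage
points. Coefficients and excess accuracy are summarized by means and 95%
percentile intervals over 100 iterations.

**Interpretation caveat.** The iteration CI measures split-to-split
variability around *this cohort's* association, not a population-level
test: chance associations in a finite cohort can yield an unplanted trait
with a CI excluding zero. Null calibration of the decoder is therefore
asserted on the mean excess accuracy across independent null cohorts,
where it is unbiased.

**Selectivity target.** With loadings planted on uncertainty sensitivity
only, decoding %reveal hiVar must succeed and decoding EV sensitivity must
stay at chance. The EV-sensitivity target used for that null check is the
fitted slope b̂ (median split), which is independent of the planted
summary by construction. The %reveal-hiEV measure is also provided, but it
is *not* a clean null: the logistic curve geometry couples it to the
uncertainty intercept (a higher intercept depresses hiEV choice on
negative-ΔEV trials), so a small genuine decodability of hiEV is expected
even with zero loadings on b — consistent with reference findings of
small-but-significant hiEV decoding. Decoding and selectivity studies use
a dedicated single-class cohort (all EV-sensitive, a ~ N(0.8, 0.8),
b ~ N(5, 1.5), independent) because in a mixed cohort any median split is
confounded with class membership.

Variance attribution is leave-one-score-out ΔR² from in-sample linear
regressions on all 18 predictors; exactly collinear scores correctly show
ΔR² ≈ 0 (shared variance). Parameter pooling for these analyses uses `a`
for EV-sensitive participants, `c` otherwise, and sets b = 0 for
EV-insensitive participants.

## Cohort analyses

- Task comparisons are paired within participants classified EV-sensitive
  in all three tasks: means ± SEM and two-sided Wilcoxon signed-rank tests
  for Δa and Δb against the first Observe block, the Intervene−Estimate
  slope contrast, the Spearman correlation between the task effects on a
  and b, and a two-way ANOVA (task order × instrumental task) on a.
  All-zero difference vectors return p = 1 by convention.
- Strategy consistency groups participants by the 2³ patterns of
  Uncertainty-only labels over (first Observe, first instrumental, second
  instrumental); the second Observe block is reported separately. The
  repetition analysis conditions on the first instrumental block's
  strategy and tests the two repetition proportions with a df = 1
  chi-square on the 2 × 2 repeat/non-repeat table (no continuity
  correction) and Cramér's V = √(χ²/n). A one-way chi-square on the repeat
  counts alone was considered and rejected: it discards the non-repeat
  cells and is severely conservative under the null (0/200 null cohorts
  rejected at α = 0.05), while the 2 × 2 form is calibrated and preserves
  the df and effect-size conventions.
- The sequential effect is P(repeat the previous reveal | high prize
  observed) − P(repeat | low prize), over consecutive valid trials within
  blocks; participants with fewer than 20 transitions are flagged.
  Within-block learning uses the second-minus-first-half %reveal
  difference as the primary statistic (robust at 126 trials) with a
  logistic slope on trial index as a secondary descriptor.
- The obey-rate analysis correlates, across participants, %inspect loVar
  in the Estimate block with the probability of guessing in accordance
  with the observed prize's valence after loVar reveals; participants with
  no loVar reveals are excluded.

## Problem sizes and numerical conventions

Recovery and calibration studies use sizes chosen to make the guarantees
sharp while keeping the full suite quick on a laptop: 300 agents for
classification recovery, 100–200 seeds for recovery and sign-flip rates,
100 null cohorts per calibration check (dip at n = 200 with 200 bootstrap
draws; decoding at n = 120 with 40 iterations), and 500-participant
cohorts for decoding demonstrations. Degenerate inputs are handled
explicitly rather than silently: empty blocks, constant targets, empty
conditioning cells, missing ΔEV = 0 trials, and non-converged fits all
raise or flag. All randomness flows from numpy `SeedSequence` spawning.

## Known limitations

- No generative model of reaction times or of learning; the generator is
  stationary within blocks unless a drift is injected by the caller.
- The Wald CIs rely on local quadratic behavior of the log posterior; near
  the b = 0 ridge the `a` interval is honest about its width but a profile
  or bootstrap interval would differ (a bootstrap cross-check hook exists
  in the test oracles rather than the API).
- The dip test's uniform null is the canonical least-favorable choice, but
  for strongly discrete data the bootstrap null (continuous uniform) and
  the tied-data statistic are not perfectly matched; the package's own
  usage (percentages over 126 trials) has at most mild ties.
- Real questionnaire scoring, recruitment filters, and payment mechanics
  are out of scope; personality profiles are standardized abstractions.
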