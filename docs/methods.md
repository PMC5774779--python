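# Methods

This note documents the statistical machinery the package implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## Tasks and scores

Three comparative-judgment tasks are modelled. The IMPRES presents every
unordered pair of *n* primes exactly once (n(n−1)/2 trials; 190 for the
reference set of 20), with left/right placement decided by an independent
fair coin per trial and trial order randomly permuted — the counterbalancing
scheme is the package's choice, as a pairwise design admits several. The AMP
presents each prime a fixed number of times (6 by default, 120 trials). The
EXPRES reuses the all-pairs structure with no deadline. Presentation timings
(75 ms AMP primes, 150 ms simultaneous IMPRES primes, 500 ms fixation, 1500
ms deadline) travel with schedules as metadata only; no computation consumes
them.

Category preference scores are proportions over *cross-category* trials
(pairs whose primes differ on the feature); same-category pairs are
uninformative for the category contrast and are excluded from these scores
but retained in the preference-count matrix, where they sharpen
stimulus-level resolution. With 10 primes per level, 100 of the 190 pairs
cross race and 100 cross age. Non-responses are kept in trial logs and
dropped at scoring time, so the exclusion policy lives in one place.
Unscoreable participants get missing (NaN) scores, never an imputed 0.5
or 0.

The latency filter keeps trials with a recorded response and latency in
[150, 1500] ms, bounds inclusive (the exclusion rule drops latencies
strictly below 150 or strictly above 1500 ms). Trials with a response but no
recorded latency are dropped, since their speed cannot be vetted. By
default the pipeline filters AMP trials only; IMPRES/EXPRES scoring uses
all responded trials. Both choices are flags, not hard-wired policy.

Questionnaire sum scores reverse negatively keyed items as
(scale_max + 1 − score) before summing; a 10-item, 5-point instrument has
range [10, 50] with midpoint 30.

## Split-half reliability

The estimator partitions each participant's *relevant* trial set (e.g. only
cross-race pairs for the race score) into two random halves, sizes
differing by at most one; the split is a simple unstratified random
partition, with no balancing by prime identity. Half-scores are correlated
(Pearson) across participants; runs with an undefined correlation — fewer
than three complete pairs, or zero variance in a half — are dropped and
counted rather than zero-filled. The mean of the remaining correlations is
Spearman–Brown corrected once, at the end: corrected = 2r̄/(1 + r̄). The
reference analysis protocol uses 10,000 runs; the estimate at 500 runs is
already within ±0.02 of a 5,000-run rerun on the simulated designs used in
the tests, so the test suite and acceptance script use 500–2,000 runs.

## Metric unfolding

Counts become dissimilarities by linear reverse scoring δ = K − count,
where K is the number of times each stimulus could have been chosen (n − 1
in a complete all-pairs design). Linear reversal is the minimal metric
transform; it is a configurable choice, not a claim that preference counts
are interval-scale distances.

The loss is normalized stress-1 over the rectangular (participant,
stimulus) pairs only,

σ₁ = √( Σᵢⱼ wᵢⱼ (δᵢⱼ − dᵢⱼ)² / Σᵢⱼ wᵢⱼ dᵢⱼ² ),

so the reported value lies on the 0–1 scale. One transformation applies to
the whole matrix (unconditional fitting); row-conditional variants are out
of scope. Weights default to 1.

**Solver.** The joint configuration is updated by the Guttman transform
with a weight matrix whose within-set blocks are zero (SMACOF specialized
to unfolding), followed each iteration by the optimal scaling of the
configuration, b\* = Σwδd / Σwd². The rescale matters: after it, σ₁ is a
strictly decreasing function of the scale-optimal raw stress that the
Guttman step majorizes, so σ₁ is provably non-increasing across iterations
— a property the solver asserts at every step. Plain Guttman iteration
does not guarantee this, because σ₁'s denominator moves with the
configuration.

Guttman fixed points are stationary for the *raw* stress but not for σ₁
(the two objectives share global optima over shape and scale but differ
locally). The solver therefore finishes with a quasi-Newton descent on σ₁
itself (analytic gradient, L-BFGS), accepted only when it strictly lowers
the stress; on small benchmark instances this closes the gap to a
multi-start general-purpose minimizer to well under 1e-3. An `n_init`
option adds seeded random restarts for rugged small instances.

**Initialization** defaults to a classical-scaling start: the square
dissimilarity matrix is completed by imputing within-set values as the
midpoint of the average triangle-inequality lower bound mean|δᵢₖ − δⱼₖ| and
upper bound mean(δᵢₖ + δⱼₖ) over the opposite set, then double-centered and
eigendecomposed. A seeded random start is available. Convergence is
declared when the per-iteration drop in σ₁ falls below `tol` (default 1e-6)
or after `max_iter` (default 5000) iterations.

**Degeneracy** is surfaced, not silently corrected: no penalty term is
added, and each solution carries the ratio var(fitted distances)/var(δ) as
a collapse diagnostic; an all-zero δ raises an error outright.

Dimensionality is compared by refitting at each d under a shared seed
policy; stress is non-increasing in d. Solutions are rotated so the
principal axes of the centered stimulus cloud become the coordinate axes —
an isometry applied identically to both point sets, leaving stress
unchanged to machine precision. Reflection signs are resolved only here,
optionally orienting each axis so a designated feature level has the larger
mean coordinate.

## Feature axes

Categorical axes come from bias-reduced logistic regression of the feature
labels on the stimulus coordinates. The estimator maximizes the
Jeffreys-prior-penalized log-likelihood ℓ(β) + ½ log det I(β) by Fisher
scoring with the hat-diagonal score adjustment X′(y − p + h(½ − p)) and
step-halving; estimates stay finite under complete separation, the typical
case when a feature is well represented in the map. Convergence is ‖Δβ‖ <
1e-8 within 1000 iterations — small separated instances can crawl along a
flat ridge of the penalized likelihood, so the cap is generous. A
rank-deficient design (e.g. a constant coordinate) is handled by
pseudo-inverse steps, leaving redundant directions at zero.

The axis direction is the normalized slope vector, oriented toward the
configured positive level to pin down the sign across runs; the intercept
is retained for the decision boundary but never used in projection, so
projections depend on direction alone. Axis goodness is side-of-boundary
accuracy for categorical features and R² for continuous ones (fitted by
OLS). The cosine of the angle between two axes measures the correlation of
the corresponding preference dimensions. Projection scores are
⟨point − participant centroid, direction⟩; centering at the participant
centroid fixes the arbitrary origin of the map.

Extreme points are flagged by a robust distance screen: distance from the
spatial (geometric) median of the point set, flagged when it exceeds the
median distance by more than k (default 3) median absolute deviations. The
deviation-from-median form is used because raw distance and its MAD both
scale with the cloud's spread, which would otherwise flag a constant
fraction of any well-behaved cloud. Flagging is a prompt for inspection,
not exclusion.

## Simulator

The generative model formalizes the misattribution hypothesis as a
Bradley–Terry-style choice law. Attitudes are
a(p,s) = Σ_f β_f(p)·x_f(s) + γ(p,s) with features coded x_f ∈ {−½, +½}, so
β_f(p) is participant p's full between-level attitude gap. Defaults mirror
the reference design and a plausible population for it:

| parameter | default | meaning |
|---|---|---|
| n_participants | 53 | reference sample size |
| β̄_race, σ_race | 0.0, 1.0 | no mean racial preference, real individual differences |
| β̄_age, σ_age | 0.3, 1.0 | mild mean preference for young faces |
| σ_γ | 0.5 | stimulus-level idiosyncrasy within categories |
| outlier fraction / multiplier | 0.04 / 4 | ~2 of 53 extreme responders |
| λ (IMPRES) | 2.0 | misattribution strength |
| κ, b (AMP) | 2.0, 0.0 | judgment scale and response bias |
| λₑ (EXPRES) | 6.0 | explicit judgments discriminate more sharply |
| ε | 0.02 | lapse rate (uniform guessing) |
| latency log-mean, log-sd | 6.4, 0.3 | median ≈ 600 ms |
| fast-guess / slow-tail rates | 0.02 / 0.03 | contamination the latency filter must catch |

Choice probabilities are ε/2 + (1−ε)·logistic(·) with a probit link as a
config alternative; ratings are clip(round(5 + 1.5·a + N(0,1)), 1, 9);
questionnaire items are noisy linear functions of β_race (sufficient to
exercise sum-scoring, with no claim of psychometric realism). One seed
deterministically spawns all per-stage seeds, so a study bundle is
byte-reproducible.

Problem sizes in the test suite and acceptance script are the reference
design itself (53 × 20) or modest reductions (12–50 participants) chosen
to keep the full pipeline checks comfortably fast while leaving every
statistical property detectable.

**What the simulator does not emulate:** ideograph-specific effects,
sequential and order effects, deadline truncation of the response process,
response-strategy heterogeneity beyond the outlier multiplier, and any
dependence between latency and choice difficulty. Passing recovery tests on
these data therefore shows the pipeline is correct and self-consistent
under the stated model — not that real task data satisfy that model. In
particular, simulated reliabilities at the default λ are higher than those
typically observed with real participants, and observed stress values
depend on the dissimilarity transform and fitting choices above, so
real-data stress levels are expected to differ in detail.

## Known limitations

- Nonmetric (ordinal) unfolding, row-conditional transformations, and
  three-way models are out of scope.
- The δ = K − count transform is linear by design; count data with strong
  ceiling effects may warrant alternatives, which can be supplied via a
  custom `DissimilarityMatrix`.
- Firth regression is implemented for the two-level case used by feature
  axes; multinomial features are not supported.
- Inferential statistics on scores (t-tests, regressions on outcome
  behavior) are deliberately not included.
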