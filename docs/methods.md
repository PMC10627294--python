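# Methods

## Task and generative model

A stimulus is a sequence S of n = 20 binary tokens (1 = blue,
0 = yellow). Two generators are equiprobable a priori:

* **Random**: i.i.d. Bernoulli(0.5) tokens.
* **DMS** (disrupted Markov sequence): a latent Markov chain h with a
  fair first token and P(h_t = h_{t−1}) = p_r, after which each token is
  independently flipped with probability p_d. The study conditions fix
  p_r = 0.9 and p_d = 0.1 (LD), 0.2 (MD), 0.3 (HD).

The observer's task is generator identification, framed as YES–NO
signal detection with the DMS generator as the signal class.

## Ideal observer

The likelihood of a sequence under the DMS generator marginalizes the
hidden chain:

    P[S | DMS] = Σ_h P(h) P(S | h),
    P(h) = 0.5 · p_r^{R(h)} (1 − p_r)^{n−1−R(h)},
    P(S | h) = p_d^{d(S,h)} (1 − p_d)^{n−d(S,h)},

with R(h) the repetition count of h and d(S,h) the Hamming distance.
This sum over 2^n hidden sequences collapses to a two-state forward
recursion (the standard HMM filter): cost O(n) per sequence. The
scalar implementation runs in log space (safe at p_d ∈ {0, 1}, where
impossible sequences correctly return log 0 = −∞); the batch
implementation runs a scaled linear-space pass over whole arrays of
sequences and is what makes exact enumeration cheap. Both are certified
in the tests against a literal brute-force hidden-sequence sum at
n ≤ 12, at relative error below 1e−10 (observed: ~1e−15).

Posterior odds λ = P[S|DMS]/P[S|RANDOM] with prior odds 1; the
accuracy-maximizing rule answers DMS iff λ > 1. **Tie-break**: λ
exactly at threshold answers RANDOM. Ties occur with probability ~0
except at p_d = 0.5, where λ ≡ 1, the rule always answers RANDOM, and
hit rate = false-alarm rate = 0; d′ is 0 by the equal-rates convention
and the criterion c is reported as NaN.

**Exact performance.** All 2^n sequences are enumerated (cap n ≤ 24;
n = 20 takes ~1 s and ~30 MB); the hit rate sums P[S|DMS] and the
false-alarm rate sums 2^{−n} over the λ > 1 region. **Monte-Carlo
performance** simulates fresh sequences per generator (default 5,000
replications) and estimates the same rates empirically.

Useful exact symmetries, asserted in the tests: the likelihood is
invariant under colour complement (bitwise-exact, since the recursion
is symmetric in the two states) and under sequence reversal (the
stationary symmetric chain is reversible; numerically equal to ~1e−15
relative error because summation order differs).

## Pattern features

Four integer features, each invariant to complement and reversal:

| id | definition | range at n = 20 |
|----|------------|------------------|
| F1 | longest contiguous monochromatic block (tokens) | 1..20 |
| F2 | longest contiguous strictly alternating block (tokens) | 1..20 |
| F3 | number of adjacent equal pairs | 0..19 |
| F4 | absolute colour-count difference | 0..20, parity of n |

"Block" is contiguous and measured in tokens; a single token is a
length-1 block of either kind. Larger F2 is evidence *for* randomness,
so the stored feature is −F2; all stored features then point
"larger = more DMS-like". F3 and the alternation count are perfectly
negatively correlated (they sum to n − 1), so only F3 is kept. F4 is
defined as |n₁ − n₀| rather than max(n₁, n₀); the two are affinely
equivalent, so classifiers and regression fits differ only in
intercept/scale.

**Ideal single-feature observers.** The exact distribution of a feature
under each generator is computed by full enumeration; the observer
answers DMS iff P[φ(S)=v | DMS] > P[φ(S)=v | RANDOM]. Probabilities
equal within relative tolerance 1e−9 count as ties and go to RANDOM —
the masses are sums of ~10^6 floating-point terms, and a strict
comparison would turn round-off into decisions in the degenerate
p_d = 0.5 case. All four features have monotone likelihood ratios at
the study conditions, so each rule reduces to a threshold on the
feature value.

Exact d′ values (full enumeration, this package): full model
2.400 / 1.451 / 0.723 at LD/MD/HD; F3 comes closest to the ceiling at
LD (2.236, efficiency 0.93) and MD (1.236), while at HD the longest-run
feature F1 is marginally the best single feature (0.619 vs 0.551 for
F3). The tests assert these orderings as computed.

## Feature-combination GLMs

Responses are regressed on any non-empty subset of the signed features
with a logistic link, E[P(DMS | S)] = ψ(β₀ + Σ βₖ φₖ(S)), fitted by
maximum likelihood (statsmodels Logit, Newton). The logistic location
parameter is absorbed into β₀ (they are not separately identifiable).

**Separation.** Complete separation (the fitted predictor perfectly
splits the response classes) makes unbounded ML diverge. It is detected
— by the fitter's own error/warning or by the strict-split check on the
fitted predictor — and the model is refitted with coefficients bounded
at ±15 on the z-scored-feature scale (L-BFGS-B), then flagged. This
keeps AICc comparisons on an ML footing without penalization; a bound
of 15 standardized logits is far beyond any behaviourally meaningful
weight.

**Standardized weights.** Menard's fully standardized form is

    β*ₖ = βₖ · sₖ · R / s_logit(ŷ),

with sₖ the sample SD of feature k, s_logit(ŷ) the sample SD of the
fitted linear predictor, and R the correlation between fitted
probabilities and observed responses. A fit with all-zero slopes has
s_logit(ŷ) = 0 and is assigned all-zero standardized weights.

**Dominant feature** = signed argmax of β*ₖ over the four-feature fit
(−F2 is pre-applied, so all expected signs are positive). Exact ties
resolve to the lowest feature index and are flagged. A call whose
largest |β*| is below 0.1 is flagged unreliable: at 100-trial sessions
such an observer is statistically indistinguishable from guessing.

## Model selection

All 15 non-empty subsets of four features are fitted per observer
(4/6/4/1 by size, named by concatenated indices, e.g. "124").
Comparison uses AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k = |subset|+1
parameters and n = 100 trials per observer-session (fits are per
observer; no pooling). Evidence ratio between two fitted models is
exp(ΔAICc/2); the support set keeps models with evidence ratio
strictly below the cutoff (default 10, "strong evidence"; 3/30/100
selectable). The parsimony summary reports the evidence ratio between
the best k-feature and best (k+1)-feature models. An averaged-AICc
table across observers is available for cohort-level reporting.

## SDT metrics

Equal-variance Gaussian model: d′ = z(H) − z(F),
c = −(z(H)+z(F))/2 (positive = conservative, biased toward "random").
Empirical rates of exactly 0 or 1 are corrected to 1/(2N) and
1 − 1/(2N) before the z-transform and the estimate is flagged, so
analyses can exclude corrected cells. Efficiency divides an observer's
d′ by the exact full-model d′ of the same condition (cached
enumeration); it is undefined when the full-model d′ is ≤ 0 (only the
p_d = 0.5 collapse), where the pipeline reports null.

## Synthetic observers

The generative response model deliberately mirrors the GLM so recovery
is well-posed: P(respond DMS) = lapse/2 + (1 − lapse)·ψ(β₀ + Σ βₖφₖ(S) + ε),
ε ~ N(0, noise_sd²). Defaults: lapse 0, noise 0; the
`single_feature_spec` helper builds an observer who consults one
feature, parameterized scale-free as *strength* = logits per pooled-SD
of the feature (intercept centred on the pooled mean, computed from the
exact feature distributions). Strength 2.0 is the default "committed
but imperfect" observer; the dominance-recovery regression tests use
strength 4.0, a near-saturated committed feature user (response
probability 0.98 one pooled-SD above the rule's centre). Very large
strengths reduce to a deterministic threshold rule on the feature.
Heterogeneous cohorts draw random strengths (0.3–2.5), random feature
subsets with Dirichlet-split weights, and lapses 0–0.15; cohort sizes
default to 33/19/40 for LD/MD/HD.

What the generator does *not* emulate: learning or sequential
dependencies across trials, asymmetric response biases beyond the
intercept, non-logistic (e.g. step or lexicographic) decision rules,
and any feature outside F1–F4. Recovery successes therefore certify
the estimation machinery under the assumed response family, not that
human observers follow it.

## Numerical and design choices

* Sequences are uint8 arrays; files use '0'/'1' strings read left to
  right, with 1-based positions in messages.
* One master seed per session; per-trial substreams come from spawned
  `SeedSequence` children, so any single trial is reproducible alone.
  Sessions enforce the exact 50/50 design by default; per-trial
  Bernoulli labelling is available as an option.
* Enumeration cap n ≤ 24 with an explicit error beyond.
* Normalization of exact distributions is checked at 1e−10; likelihood
  oracle agreement at 1e−10 relative; reversal invariance at 1e−12.
* Test and acceptance problem sizes: brute-force oracle checks run at
  n ≤ 12; Monte-Carlo cross-checks use 10^5–4×10^5 draws; recovery
  regressions use 100-trial sessions with 200–500 replicates and one
  10,000-trial session for weight recovery. These sizes make the full
  suite run in well under a minute while keeping every statistical
  check at ≥ 4-SE resolution.

## Known limitations

* The ideal-observer analysis is exact only up to the enumeration cap;
  longer sequences would need importance sampling or analytic bounds.
* The separation-capped fits report finite but boundary-flavoured
  weights; their AICc values are comparable in practice but the
  likelihood is evaluated at a capped, not unbounded, maximizer.
* Menard's standardization exists in several variants; the fully
  standardized form implemented here is the one defined above, exposed
  so it can be audited against any alternative.
* Efficiency and dominance for near-guessing observers are intrinsically
  noisy at 100 trials; the unreliable flag is a coarse guard, not a
  significance test.
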