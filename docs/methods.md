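# Methods

## Model

`iccpool` synthesises externally reported intracluster correlation
coefficients (ICCs) in a weighted hierarchical logit-normal model. For
outcome *l* of study *m*, with reported estimate `ρ̂_ml` from a trial of
`N_ml` participants in `k_ml` clusters:

    ρ̂_ml       ~ N(ρ_ml, V(ρ_ml, N_ml, k_ml))
    logit ρ_ml  ~ N(μ_m, σ_w² / w_ml)
    μ_m         ~ N(μ, σ_b² / w_m)
    μ ~ N(0, 10 000),   σ_w ~ U[0, 5],   σ_b ~ U[0, 5]

`V` is the Swiger asymptotic variance

    V(ρ, N, k) = 2 (N−1) (1−ρ)² (1 + (m̄−1)ρ)² / (m̄² (N−k)(k−1)),  m̄ = N/k

kept as a function of the *latent* ρ by default (`variance_at="latent"`),
since the observation equation states its variance at ρ_ml; an
`"observed"` mode fixing V at ρ̂_ml is provided because published
statements of the formula carry hats and the two conventions differ
slightly for imprecise estimates. m̄ is used as a real number — no
rounding — because source trials rarely have N divisible by k.

Assumptions: exchangeability of study means around μ and of outcome-level
logit-ICCs within a study; Gaussian sampling error for ρ̂ on the raw
scale (so reported estimates of exactly 0 are legal data; only the latent
ρ_ml is constrained to (0,1) by the logit link); relevance expressible as
variance inflation — a weight w in (0,1] divides the level's precision,
so fully relevant sources (w=1) borrow full strength and less relevant
ones proportionally less. Weights of exactly 0 are rejected at ingest
(infinite variance), and pooled elicitation weights are floored at 0.01
for the same reason, with a warning.

The **target ICC** `ρ*` is the posterior *predictive* ICC for a new,
fully relevant study and outcome: per retained draw, `μ* ~ N(μ, σ_b²)`,
`x ~ N(μ*, σ_w²)`, `ρ* = expit(x)`. A plausible alternative functional is
`expit` of a new study mean alone; the predictive quantity was chosen
because it is the model's answer to "what ICC should the planned trial
expect?", integrating both between- and within-study heterogeneity, and
its pronounced right skew matches how synthesised ICC posteriors behave
(posterior mean well above the median, long upper tail). Both can be
computed from the returned draws.

## Sampler

A bespoke Metropolis-within-Gibbs sampler (`bayes.fit_model`):

* `μ` and each `μ_m`: exact conjugate normal Gibbs updates given the
  latent logit-ICCs (vectorised over studies).
* `σ_b`, `σ_w`: slice sampling on the SD scale within the bounded prior
  support (0, 5], by uniform shrinkage from the full interval. Sampling
  the SD directly avoids any reparameterisation mismatch with the
  uniform-on-SD prior.
* each `logit ρ_ml`: random-walk Metropolis (non-conjugate because V
  depends on ρ_ml), vectorised over records. Per-record proposal scales
  start at 0.5 and are adapted only during burn-in, multiplying by
  0.7 / 1.4 whenever the windowed acceptance rate leaves [0.2, 0.5].
* a joint translation move shifts `μ`, every `μ_m` and every
  `logit ρ_ml` by a common normal offset. All within-hierarchy terms
  depend only on differences, so the acceptance ratio involves just the
  μ prior and the observation likelihood. With informative data the move
  is a cheap no-op-scale refinement; with weak data it is essential —
  pure within-level updates mix across the very wide N(0, 10 000) μ
  prior by a random walk with O(σ_b + σ_w) steps, which takes of order
  (100/5)² iterations per effective draw. The translation scale is
  adapted during burn-in like the other proposals.

Chains are seeded from a single `SeedSequence` spawn, so runs are
bit-reproducible given (table, config). Defaults are 4 chains × 30 000
iterations with 10 000 burn-in; the examples and tests use shorter runs
(stated alongside each) chosen so that Monte-Carlo error is small
relative to the tolerances they assert.

Numerical details: `expit` overflow at extreme logits is clipped into the
open unit interval before draws are stored; a proposal that drives V to 0
(ρ → 1) has observation density −∞ and is rejected; non-finite chain
states raise with the iteration index. `log_posterior` evaluates the same
joint density (latent ICCs parameterised on the logit scale) and returns
−∞ outside the support by contract.

Summaries (`summarize_posterior`) report mean, SD (n−1 denominator),
batch-means Monte-Carlo error with ⌊√n⌋ batches, and linearly
interpolated percentiles at 2.5/25/50/75/97.5%. Convergence diagnostics
use an own split-R̂ (floored at 1, so identical stationary chains report
exactly 1 and separated constant chains report ∞) and arviz effective
sample sizes; a run is flagged if any R̂ exceeds 1.05. Model comparison
across sensitivity refits uses DIC = D̄ + p_D with deviance −2·(observation
log-likelihood) and p_D = D̄ − D(posterior mean of the latent ICCs).

## Elicitation aggregation

Experts rate the relevance of each study and outcome on [0, 1]. Ranks
(1 = most reliable, ties allowed) give Rank-Sum importance weights
π_j = (J − Rank_j + 1)/Σ_i (J − Rank_i + 1); pooled item weights are the
linear opinion pool Σ_j π_j · rating_{j,item}, renormalising π over the
experts who rated the item. Down-ranking a rater is a human decision:
the package supplies the diagnostics (Cronbach's alpha with experts as
items, inter-rater correlations, per-item five-number spreads) but never
reclassifies raters automatically, because rater reliability judgements
depend on context the data alone cannot supply.

## Trial design

Two-arm design with k equal clusters of m per arm: the design effect
`1 + (m−1)ρ` shrinks each arm to an effective size `n_eff = km/DEff`, and
two-sided power is `Φ(ncp − c) + Φ(−ncp − c)` with
`ncp = |δ|/(σ√(2/n_eff))`. The critical value c is normal by default;
central-t variants at 2k−2 (cluster) or 2km−2 (subject) degrees of
freedom are provided because sample-size software differs in convention —
for the bundled worked example the normal and subject-df conventions give
82% power where cluster-df gives ≈80.5%, and normal is the default.
Since `n_eff → k/ρ` as m → ∞, a target power can be unreachable for
fixed k and ρ > 0; `min_cluster_size` detects this from the asymptote
(feasible iff the power ceiling at `n_eff = k/ρ` exceeds the target) and
otherwise inverts the power curve for the required n_eff, converts it to
a candidate m in closed form, and adjusts locally so minimality holds
exactly under whichever critical-value convention is configured.
Infeasibility is a result (`feasible=False`), not an exception.

## Synthetic data

The generators exist so that every stage can be tested against known
truth:

* `simulate_cluster_trial`: one-way random-effects Gaussian outcomes —
  cluster effects with variance ρσ², residuals (1−ρ)σ² — with n split
  over k clusters as evenly as possible; `anova_icc` is the standard
  one-way ANOVA estimator with the unbalanced-size correction
  m₀ = (N − Σnᵢ²/N)/(k−1), truncated at 0 to mirror how small trials
  report "0.00".
* `simulate_study_table`: the hierarchical model run forwards at known
  (μ, σ_b, σ_w). Defaults — μ = −3, σ_b = 0.5, σ_w = 0.3, 30 studies × 3
  outcomes, source trials of 1 000–5 000 participants in 20–50 clusters —
  put the latent ICCs in the low range typical of cluster trials
  (expit(−3) ≈ 0.047) with moderate heterogeneity, at source-trial sizes
  spanning the bundled table. Observation noise is either direct
  Swiger-variance Gaussian noise or a full simulated trial per record;
  the two modes agree in distribution at large N.
* `simulate_reviewer_panel`: ratings a·s_i + (1−a)·e_ji mixing a shared
  uniform item signal with independent uniform expert noise, so expected
  inter-rater correlation is a²/(a² + (1−a)²); optional biased experts
  are shifted down and clipped.

What the synthetic data do **not** emulate: non-Gaussian outcomes, binary
ICCs, informatively missing estimates, publication bias in which ICCs get
reported, or correlated outcomes within a study beyond the exchangeable
hierarchy. Passing recovery tests therefore demonstrate internal
consistency of model + sampler under the model's own assumptions, not
robustness to their violation.

## Verification strategy and chosen problem sizes

* Parameter recovery: 50 tables from the default truth, each fitted with
  1 chain × 6 000 iterations (2 000 burn-in) — enough that credible-
  interval coverage of μ is limited by the statistics, not the chain
  length. Observed coverage ≈ 0.92 against the ≥ 0.90 requirement.
* Prior recovery: one record with observation variance inflated ×10⁶ in
  `"observed"` variance mode reproduces the prior predictive of ρ*
  (a near-symmetric two-point mixture at the ends of (0,1)) within
  ESS-based Monte-Carlo error. The `"latent"` mode is *not* used here:
  because V(ρ) → 0 as ρ → 1, a latent-mode likelihood stays informative
  about the upper tail no matter how much it is inflated.
* Calibration of the Swiger formula against the empirical variance of
  5 000 ANOVA estimates at (ρ = 0.05, N = 2 000, k = 40): within 15%.
* The minimum-cluster-size search is checked against brute force over
  200 random specs.

## Known limitations

* The bundled table carries unit relevance weights; the pooled expert
  weights used in the original application were not published, so
  weighted results depend on a user-supplied weight file
  (`iccpool.with_weights` / `--weights`).
* DIC on a non-linear deviance can in principle give small negative p_D
  for very skewed posteriors; it is intended for comparing refits of the
  same data, not as an absolute fit measure.
* Assurance (expected power over the full ICC posterior) is not
  implemented; the posterior-quantile grid is the supported way to
  propagate ICC uncertainty into the design.
* Equal cluster sizes and equal arms are assumed throughout; no
  coefficient-of-variation adjustment for unequal clusters.
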