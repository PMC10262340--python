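# iccpool

Bayesian synthesis of external intracluster correlation coefficient (ICC)
estimates for cluster-randomised trial design.

## The problem

Sample size for a cluster-randomised trial is driven by the design effect
`DEff = 1 + (m − 1)ρ`, where `m` is the average cluster size and `ρ` the
ICC. A robust `ρ` for a new trial is rarely available: published estimates
come from trials of varying relevance, often with few clusters and hence
large sampling error, and naive summaries (median, mean, maximum of the
collected estimates) ignore both the imprecision and the relevance of each
source. `iccpool` is for trial statisticians who have collected external
ICC estimates and want to turn them — and expert judgement about their
relevance — into a posterior distribution for the ICC of the planned
trial, and then into defensible sample sizes.

## The model

Each external estimate `ρ̂_ml` (outcome *l* of study *m*, from a trial of
`N_ml` participants in `k_ml` clusters) enters a weighted hierarchical
logit-normal model:

    ρ̂_ml      ~ N(ρ_ml, V(ρ_ml, N_ml, k_ml))
    logit ρ_ml ~ N(μ_m, σ_w² / w_ml)
    μ_m        ~ N(μ, σ_b² / w_m)
    μ ~ N(0, 10 000),   σ_w, σ_b ~ U[0, 5]

where `V` is the Swiger closed-form asymptotic variance of an ANOVA-type
ICC estimate and `w_ml`, `w_m` are outcome- and study-level relevance
weights in (0, 1]: down-weighting inflates that level's variance so a less
relevant estimate borrows less strength. Weights are aggregated from an
expert panel by Rank-Sum importance weighting plus linear opinion pooling,
with Cronbach's-alpha and inter-rater-correlation diagnostics to support
down-ranking unreliable raters. The model is fitted by a bespoke
Metropolis-within-Gibbs sampler, and the target ICC `ρ*` is the posterior
*predictive* ICC of a new, fully relevant study and outcome. Posterior
quantiles of `ρ*` feed a design-effect-adjusted two-sample power
calculation and a minimum-cluster-size search.

## Worked example

A 34-record table of ICC estimates from 16 published stroke trials is
bundled (`iccpool.load_table1()`); all relevance weights in the bundled
file are 1, and pooled expert weights can be attached with
`iccpool.with_weights`.

```python
import iccpool as ip

table = ip.load_table1()
s = ip.classical_summaries(table)
print(f"classical: median={s.median:.3f} mean={s.mean:.3f} max={s.maximum:.3f}")

cfg = ip.ModelConfig(n_chains=4, n_iter=12000, n_burnin=4000, seed=1)
draws = ip.fit_model(table, cfg)
icc = ip.summarize_posterior(draws)["icc"]
print(f"posterior ICC: mean={icc.mean:.4f} sd={icc.sd:.4f} "
      f"median={icc.percentiles[50.0]:.4f} "
      f"95% CrI=({icc.percentiles[2.5]:.5f}, {icc.percentiles[97.5]:.3f})")
for k in (20, 25):
    r = ip.min_cluster_size(ip.DesignSpec(delta=2.52, sd=8.32,
                                          icc=icc.percentiles[50.0], k_per_arm=k))
    print(f"k={k}: m={r.m} N={r.n_total} power={r.achieved_power:.3f}")
```

prints

```
classical: median=0.050 mean=0.098 max=0.400
posterior ICC: mean=0.0973 sd=0.1661 median=0.0297 95% CrI=(0.00036, 0.655)
k=20: m=12 N=480 power=0.821
k=25: m=9 N=450 power=0.823
```

The classical comparators are right-skewed (median 0.05 well below mean
0.098) and the maximum 0.4 would be a very conservative design value. The
Bayesian posterior median ICC of about 0.03 reflects where the bulk of
the synthesised evidence sits once each estimate's sampling error is
accounted for; using it, a trial detecting a 2.52-point difference (SD
8.32, two-sided α = 0.05) with 20 clusters per arm needs clusters of
m = 12, i.e. N = 480 participants in total (82% power), or N = 450 with
25 clusters per arm. The same search over other posterior quantiles
(`ip.sample_size_over_quantiles`) shows the plausible sample-size range,
including infeasible cells where the `k/ρ` effective-size ceiling makes
the target power unreachable for any cluster size.

The same pipeline is available from a shell:

```sh
iccpool classical --input bundled
iccpool fit --input bundled --seed 1 --out-dir out/
iccpool samplesize --delta 2.52 --sd 8.32 --draws out/draws.csv --k 10,15,20,25,30
```

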