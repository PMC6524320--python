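# clusterbias

Detects post-randomisation **recruitment (selection) bias** in cluster
randomised trials from baseline covariate tests.

## The problem

In an individually randomised trial every baseline null hypothesis is true
by construction, which is why baseline significance testing there is widely
discouraged: on average one in twenty tests comes out below 0.05 by chance
alone. Cluster randomised trials are different. Clusters (schools, clinics)
are usually randomised *before* participants are recruited, so the people
doing the recruiting — and sometimes the participants — already know each
cluster's arm. Recruitment can then differ systematically between arms, and
the recruited groups are no longer exchangeable even though the
randomisation itself was sound. Baseline p-values in this setting test the
*recruitment* mechanism, not the randomisation, and a table with far more
significant covariates than K/20 — or any covariate at p < 0.0001 — is a
red flag for a deficient cluster trial.

`clusterbias` turns that argument into a tool for two users: the reader
auditing a published baseline table (aggregate per-arm summaries), and the
trial statistician with individual participant data (IPD).

## The method

**Design effect.** With intraclass correlation ρ (as assumed in the
sample-size calculation), k clusters randomised and N participants
consenting, the variance-inflation factor of cluster sampling is

    DEFF = 1 + (N/k − 1)·ρ.

**Aggregate tables.** Each continuous covariate (per-arm n, mean, SD) gets
a two-sample t-test (pooled by default, Welch by flag); each categorical
covariate (per-arm level counts) gets a Pearson χ² test. Clustering is then
taken into account under either of two conventions:

* `paper` (`statistic_division`) — divide the t statistic by DEFF (df
  unchanged) and divide every χ² cell count by DEFF, which divides the χ²
  statistic by DEFF exactly. This is the literal published rule for
  auditing a cluster trial's table; dividing t by DEFF rather than √DEFF
  makes it conservative.
* `ess` (`effective_sample_size`) — replace each arm's n by n/DEFF and
  recompute statistic and df. This is the standard design-effect usage; its
  null p-values are approximately uniform and it is the convention used for
  calibration claims.

**IPD.** The recommended analysis fits, per continuous covariate, the
random-intercept model

    y_ij = μ + β·arm_j + u_j + e_ij,   u_j ~ N(0, σ²_u),  e_ij ~ N(0, σ²_e),

by maximum likelihood (deterministic one-dimensional profile likelihood
over σ²_u/σ²_e) and tests β with a Wald z. Binary covariates get a χ² test
adjusted by a DEFF built from the ANOVA ICC estimate of the 0/1 values.

**Verdict.** Given K usable tests, the summary counts the adjusted
p-values below α (default 0.05) and below a stringent threshold (default
10⁻⁴), computes the exact binomial tail P(X ≥ n_significant) for
X ~ Binomial(K, α), and reports `strong_evidence_of_bias`, `caution` or
`consistent_with_null` under a documented rule printed in every report.

**Simulator.** A built-in generator produces two-arm cluster trials with
clustered covariates and logistic, covariate-dependent, arm-differential
recruitment, giving ground truth for type-I error and power studies
(`calibrate_detector`).

## Worked example

Generate the shipped synthetic example of a biased cluster trial — 57
schools, recruitment after randomisation with ~50% uptake in control
clusters versus ~58% under intervention — and audit its baseline table:

```
$ clusterbias fixture --name biased_cluster_trial --out demo
$ clusterbias test-aggregate \
    --table demo/biased_cluster_trial_aggregate.csv \
    --design demo/biased_cluster_trial_design.json --out demo
verdict: strong_evidence_of_bias
```

The design JSON records ρ = 0.10, k = 57, N = 586, hence DEFF = 1.93. The
markdown report begins:

```
Verdict: **strong_evidence_of_bias**

- tests summarised: 10
- significant at alpha = 0.05: 4 (expected under the null: 0.50)
- highly significant (p < 0.0001): 1
- exact binomial tail probability of >= 4 significant tests: 0.0010

| covariate | method | statistic (adj.) | p unadjusted | p adjusted | flags |
|---|---|---|---|---|---|
| score1 | t_pooled | 3.7304 | 1.96e-12 | 2.10e-04 | significant |
| score2 | t_pooled | 3.9760 | 7.45e-14 | 7.89e-05 | highly significant |
...
```

Four of ten covariates are significant after the (conservative) DEFF
adjustment where 0.5 were expected; the chance of that many under the
all-nulls-true binomial is about 0.001, so the trial's recruited groups
were very unlikely to have been formed by randomisation alone. The
companion `clean_individual_trial` fixture (504 participants, 20
covariates, recruitment before randomisation) shows the benign pattern:
one marginally significant test and `consistent_with_null`.

The same workflow is available as library calls
(`read_aggregate_table` / `run_aggregate_table` / `summarise`), and
`test-ipd` runs the mixed-model analysis on participant-level CSVs.

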