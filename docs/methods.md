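# Methods

## Model and procedure

The package treats a two-arm trial's baseline table as K independent
hypothesis tests of covariate balance. In a trial whose groups were formed
by randomisation alone, each null is true, each p-value is (approximately)
uniform, and the count of tests significant at α is Binomial(K, α). When
recruitment happens after cluster allocation is revealed, recruitment can
depend on arm and on covariates jointly, and the recruited groups differ
systematically; the baseline tests then have power against exactly that
mechanism. The pipeline is: per-covariate test → clustering adjustment →
count/flag summary → verdict.

### Design effect

DEFF = 1 + (m̄ − 1)ρ with m̄ = N/k. One DEFF is computed for the whole
trial — N is the total number of consenting participants and k the total
number of clusters randomised across both arms — because the adjustment is
applied to two-arm statistics, not per arm. ρ is an *assumed* (design-time)
ICC supplied by the user; when only IPD are in hand an ANOVA estimate can
be substituted, with the usual caveat that estimated ICCs from a single
trial are noisy.

### Aggregate-table tests

Continuous covariates: two-sample t from (n, mean, SD) per arm. The pooled
equal-variance test is the default (the classic form for baseline tables);
Welch with Satterthwaite df is available by flag. Categorical covariates:
Pearson χ² on the arms × levels table, no continuity correction by default,
all-zero levels dropped, multi-level tables tested as-is.

Two adjustment conventions are implemented and never silently substituted
for one another:

* **statistic_division** — t/DEFF with unchanged df; χ² cell counts divided
  by DEFF, which by the scaling property of the Pearson statistic equals
  χ²/DEFF with unchanged df (the implementation computes the adjusted
  statistic as that exact ratio so the identity holds in floating point).
  Dividing t by DEFF rather than √DEFF over-corrects the t-statistic's
  scale (√DEFF would be the variance-inflation analogue); the convention is
  retained as the default because it is the literal published audit rule,
  and its conservatism only strengthens a positive finding.
* **effective_sample_size** — each arm's n replaced by n/DEFF; statistic
  and df recomputed (for the pooled t this shrinks t by √DEFF and the df to
  N/DEFF − 2). This is the calibrated convention: under the null with a
  correctly specified ICC its rejection rate is the nominal α (verified by
  simulation in the test suite and the acceptance script).

Both conventions are monotone in DEFF (p never decreases), DEFF = 1 is the
identity, and degenerate rows (zero SDs, one-arm tables) become flagged
results in batch mode so a single bad covariate cannot abort a table run.

### IPD tests

Per continuous covariate, the random-intercept model
y_ij = μ + β·arm_j + u_j + e_ij is fitted by full maximum likelihood.
Because both fixed-effect columns are constant within cluster, profiling
gives closed-form GLS estimates and residual variance for any variance
ratio λ = σ²_u/σ²_e, so the fit is a bounded deterministic scalar
optimisation of the profile likelihood over λ ∈ [0, 10⁴] (optimised on a
log1p scale, xatol 10⁻¹⁰, ~1e-8 relative in λ). The λ = 0 endpoint — the
nested OLS fit — is always evaluated and wins ties, which guarantees the
returned log-likelihood is never below the OLS log-likelihood and makes
the all-singleton-cluster case (flat likelihood) land on the t-test limit.
Boundary fits are reported, not hidden.

ML rather than REML keeps the self-contained profile implementation exact
and matches the Wald-test target; variance components are therefore
slightly smaller than REML-based package defaults (statsmodels MixedLM
with ML is the independent cross-check in the test suite). The Wald
reference is standard normal — simpler than a between-cluster-df t and
mildly anti-conservative with few clusters, so results carry a warning
below 20 clusters.

Binary covariates are deliberately not given a logistic GLMM: the
recommended mixed-model analysis is stated generically, a bespoke GLMM
would dominate the codebase, and the ICC-adjusted χ² (ANOVA ICC of the 0/1
values → DEFF → cell division) captures the same variance inflation. The
ANOVA estimator is (MSB − MSW)/(MSB + (m₀ − 1)MSW) with the standard
unbalanced-design m₀, truncated at 0.

Missing covariate values are dropped per covariate (complete case per
test).

### Verdict rule

With K usable tests, n_sig below α (default 0.05) and n_high below the
stringent threshold (default 10⁻⁴, configurable — "highly significant" has
no canonical numeric definition):

* strong_evidence_of_bias iff P(Bin(K, α) ≥ n_sig) < 0.01 **or**
  (K ≥ 10 and n_high ≥ 2);
* caution iff the tail probability is < 0.10 or n_high ≥ 1;
* otherwise consistent_with_null.

The tail probability is exact (`scipy.stats.binom.sf`, verified against
rational enumeration for K ≤ 30). The rule is monotone: adding a
significant result at fixed K never moves the verdict toward
consistent_with_null. Under the null study conditions below, the spurious
strong-verdict rate is ~0.2% (< 2%). The binomial null assumes independent
covariates; correlated baselines make it approximate, which every report
states in its footer.

## Synthetic-data generator

The simulator emulates a post-randomisation-recruitment cluster trial: k
clusters (default emulation: 57, split 28/29) are assigned to arms by
permuting labels; cluster sizes are negative-binomial dispersed with floor
2 (mean 20, dispersion 0.15 by default), so the single-m̄ DEFF formula is —
as in real trials — an approximation; covariates are cluster-random-
intercept normals with specified marginal ICC, binary covariates via a
latent-Gaussian threshold so ICC has one coherent meaning (the latent ICC
exceeds the ICC of the observed 0/1 values); recruitment is individual
logistic in the standardised covariates with arm-specific intercepts and
slopes. Logistic selection is the minimal mechanism that produces
covariate imbalance from differential recruitment; intercepts are
calibrated numerically (fixed-seed Monte-Carlo + bisection) to hit target
marginal fractions, e.g. 50% control / 58% intervention for the biased
emulation. One base seed feeds a counter-derived substream per replicate,
so any replicate regenerates in isolation.

What the generator does **not** emulate: correlated covariates,
cluster-level recruiters with shared idiosyncrasies, outcome models or
treatment effects, cluster-level attrition, missing data. Passing
calibration tests therefore show the procedure behaves correctly when the
ICC is correctly specified and covariates are independent — not that the
binomial summary is exact for strongly correlated real baseline tables.

### Study conditions used in tests and the acceptance script

Chosen once as a realistic mid-sized cluster trial: 57 clusters of mean
size 20 (≈1140 eligible), 10 covariates (5 continuous, 5 binary with
prevalences 0.3–0.5), covariate ICC 0.05 for calibration runs (a typical
school/primary-care value) and 0.10 for the biased emulation (which,
with ~54% overall recruitment, lands the design effect near 1.9–2.0);
null recruitment 54% in both arms (midpoint of the emulated 50%/58%).
Monte-Carlo sizes: 2000 replicates for null calibration, 500 for the
mixed-model recovery grid (β ∈ {0, 0.3, 0.6} × ICC ∈ {0, 0.05, 0.15},
30 clusters × 20) and for power monotonicity. All Monte-Carlo assertions
use ±3 standard-error envelopes (cluster-robust where tests share a
trial); the literal taken-at-face-value reading "bias smaller than one SE"
would fail an unbiased estimator a third of the time, so 3 SE is the
package-wide envelope convention.

## Numerical choices and edge cases

* Exact identities are implemented as identities (χ² scaling; DEFF = 1
  short-circuits to the unadjusted result) rather than recomputed.
* Degenerate inputs produce flagged results in batch contexts and
  exceptions in direct calls: zero SDs (p = 1 or 0 with a warning flag),
  one-arm categorical tables, single observed level of a binary covariate,
  effective sample sizes too small for a test.
* ANOVA ICC at zero within-cluster variance returns just under 1 with a
  boundary warning; negative estimates truncate to 0.
* Recruitment configurations whose linear predictor saturates the logistic
  within ±4 SD of the covariates (|η| > 36.5, where float64 expit leaves
  (0, 1)) are rejected at construction.
* Fixture CSVs are written with full-precision `repr` so write→read is the
  identity and regeneration is byte-identical (checksums pinned in tests).

## Known limitations

* The Wald-z mixed-model test is anti-conservative below ~20 clusters; a
  Satterthwaite-df t would be better there and is out of scope.
* The design-effect adjustments inherit whatever error lies in the assumed
  ICC; the aggregate pathway cannot detect a mis-specified ρ.
* The statistic-division convention is conservative by construction; its
  null rejection rate is below α, so a clean result under it is weaker
  evidence of balance than under the effective-sample-size convention.
* Only two arms, and only continuous/binary covariates, are supported for
  IPD; aggregate multi-level categorical covariates are supported as-is.
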