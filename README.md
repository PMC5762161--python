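# uoastats

Unit-of-analysis aware statistics for nested laboratory data.

## The problem

In laboratory studies the *experimental unit* — the smallest thing that can
be randomly and independently assigned to a treatment — is usually a subject
or a tissue source, while the measurements come from strata below it:
samples taken from the subject, and replicate slices or assays within each
sample. Observations from the same unit are correlated, so feeding all of
them into a t-test or logistic regression as if they were independent
(*pseudoreplication*) uses within-unit variability to judge a between-unit
treatment effect. The result is an inflated type I error rate and
confidence intervals that are far too narrow.

`uoastats` implements the full analysis ladder for this setting, from first
principles:

- **naive (pooled) analyses** — the two-sample pooled-variance t-test and
  the single-covariate binomial logistic regression, provided as the
  (invalid, but instructive) comparators;
- **subject-based analyses** — the same tests on one summary value (the
  mean) per experimental unit, which restores validity at the cost of
  discarding within-unit information;
- **nested Gaussian linear mixed models** — REML estimation of
  `y = Xβ + Z_P u_P + Z_S u_S + ε` with random intercepts for subjects and
  for samples nested within subjects, stratum (containment) degrees of
  freedom for the treatment effect, intraclass correlations, Wald intervals
  for the variance components, and likelihood-ratio tests between
  random-effect structures;
- **binomial logistic mixed models** — a subject-level random intercept on
  the log-odds scale, fitted by Laplace / adaptive Gauss–Hermite
  approximation of the marginal likelihood;
- **design tools** — the two-group sample-size formula
  `n = 2σ²(z_{α/2}+z_β)²/d²`, the design effect `VIF = 1 + (m−1)·ICC`, the
  resource-equation rule of thumb, and a Monte-Carlo engine that measures
  rejection rates, bias, CI width and coverage of each analysis rung on
  simulated nested data.

Two fully printed example datasets from a colorectal-cancer radiotherapy
study ship as fixtures: `lymph_size` (72 lymph-node diameters; 12 subjects ×
2 samples × 3 slices) and `lymph_count` (counts of nodes ≥ 2 mm out of 5
inspected, per sample). See `src/uoastats/data/MANIFEST.md`.

## Worked example

```python
from uoastats import (
    load_fixture, pooled_t_test, subject_based_t_test, fit_nested_lmm, icc,
)

size = load_fixture("lymph_size")
df = size.frame

naive = pooled_t_test(df["value"], df["group"])
print(naive)
# difference (None - Short RT) = 0.2825 (CI 0.05722 to 0.5078),
# t = 2.501 on 70 df, p = 0.01473

subject = subject_based_t_test(size)
print(subject)
# difference (None - Short RT) = 0.2825 (CI -0.3213 to 0.8863),
# t = 1.043 on 10 df, p = 0.3217

fit = fit_nested_lmm(size, levels=("subject", "sample"))
print(fit.components)
# VarianceComponents(sigma_subject=0.4365, sigma_sample=0.2336,
#                    sigma_resid=0.1221)
print(round(icc(fit.components), 3))
# 0.733
```

The naive test declares a "significant" radiotherapy effect (p = 0.015)
only because it treats 72 correlated slices as independent; with the
experimental unit respected, the same mean difference of 0.28 mm has
p = 0.32. The mixed model explains why: 73% of the total variance
(ICC = 0.733) sits between subjects, so the effective sample size is close
to the 12 subjects, not the 72 slices.

For the binomial outcome:

```python
from uoastats import load_fixture, fit_logistic_glm, fit_logistic_glmm, predict_probability

count = load_fixture("lymph_count")
print(fit_logistic_glm(count).odds_ratio)      # 0.305  (naive, se_log_or 0.264)
g = fit_logistic_glmm(count)                   # Laplace approximation
print(g.odds_ratio, g.se_log_or)               # 0.257, 0.565
print(predict_probability(g, "None"))          # 0.653
print(predict_probability(g, "Short RT"))      # 0.326
```

Both models agree on the direction of the effect, but the naive logistic
regression understates the standard error of the log odds ratio by more
than half, grossly overstating significance.

The same analyses are available from the shell:

```bash
uoa ttest --fixture lymph_size --mode naive
uoa fit-lmm --fixture lymph_size --levels subject,sample
uoa fit-glmm --fixture lymph_count
uoa design-effect --m 20 --icc 0.5
uoa samplesize --sigma 1 --d 0.5 --m 5 --icc 0.1
uoa simulate --reps 500 --seed 1 --out operating_characteristics.csv
```

## Documentation

The model, estimation details, numerical choices and known limitations are
documented in [docs/methods.md](docs/methods.md).
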