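# Methods

## Models

### Nested Gaussian linear mixed model

For slice k of sample j of subject i, with treatment applied at the subject
level,

    y_ijk = x_i' β + u_i + v_ij + ε_ijk,
    u_i ~ N(0, σ_P²),  v_ij ~ N(0, σ_S²),  ε_ijk ~ N(0, σ_ε²),

all mutually independent. `levels=("subject",)` drops the v term. Samples
and replicates are *nested* labels: v_ij is indexed by the (subject, sample)
pair, never by the sample label alone.

**Estimation.** Restricted maximum likelihood. The optimization runs over
θ_c = log(σ_c/σ_ε), the log SD *ratios*; at each θ the fixed effects β
(GLS) and the residual scale σ_ε² have closed-form profiled solutions, so
the search space is one- or two-dimensional. Writing V = σ_ε² W(θ) with
W = I + Z Γ Z′ and Γ the diagonal of squared ratios, the profiled REML
criterion is

    -2 ℓ_R(θ) = (n−p)(log 2πσ̂_ε² + 1) + log|W| + log|X′W⁻¹X|,
    σ̂_ε² = y′P_W y / (n−p),

and the ML criterion drops the log|X′W⁻¹X| term and divides by n. Because
subjects are independent, W is block diagonal; each subject's block is
handled through the Woodbury identity on a (1 + s_i)-dimensional inner
matrix (s_i = number of samples), using per-subject cross-products
(Z′Z, Z′X, Z′y, X′X, X′y, y′y) precomputed once. This is algebraically
identical to the dense computation and makes a likelihood evaluation cheap
enough for the Monte-Carlo engine. Optimization is quasi-Newton (BFGS,
gradient tolerance 1e-8) started at the ANOVA (expected-mean-squares)
method-of-moments estimates, floored at a small positive value; a
Nelder-Mead restart from equal ratios is the fallback if BFGS reports
failure away from a stationary point.

**Boundary handling.** Near σ_c = 0 the profiled criterion is flat in
log σ_c, so after the search finishes each component is snapped to an
effective zero (ratio e⁻¹²) whenever that does not worsen the criterion by
more than 1e-6. A component at the boundary is reported as ~0 with a flag
(and a warning for the sample level, since inference then effectively
reduces to the subject-only model) — never as an error.

**Inference.**

- *Fixed effects*: Wald t with containment (stratum) degrees of freedom —
  a subject-level treatment is tested against the between-subject stratum,
  df = n_subjects − p. For balanced designs this reproduces the
  subject-means t-test exactly (estimate, SE, df and CI), which is the
  classical equivalence the test suite checks. Satterthwaite or
  Kenward-Roger approximations are intentionally out of scope.
- *Variance components*: Wald intervals on the log σ scale
  (exp-transformed back), using a central-finite-difference Hessian
  (step 1e-4) of the unprofiled restricted log-likelihood in
  (log σ_P, log σ_S, log σ_ε). On the packaged size dataset these reproduce
  the published intervals to ~1%; profile-likelihood intervals would differ
  somewhat and are not implemented.
- *Random-structure comparison*: LRT = 2(ℓ_full − ℓ_reduced) between REML
  fits with identical fixed effects, floored at zero. Both the naive χ²₁
  p-value and the 50:50 χ²₀:χ²₁ boundary-mixture p-value are reported,
  since the null value σ_S = 0 sits on the edge of the parameter space; the
  mixture halves the p-value, so the naive version is conservative.
- *Residuals*: conditional (observed − fitted with BLUPs), as used in the
  boxplot-by-subject and Q-Q diagnostic series. Q-Q theoretical quantiles
  are Normal quantiles at plotting positions (i − ½)/n scaled by σ̂_ε.

### Binomial logistic mixed model

For sample j of subject i, k_ij events out of n_ij trials:

    k_ij | b_i ~ Binomial(n_ij, logit⁻¹(x_i'β + b_i)),   b_i ~ N(0, σ²).

The marginal likelihood integrates b_i out of each subject's contribution.
The integral is approximated by adaptive Gauss-Hermite quadrature centred
at the conditional mode b̂_i (found by Newton iteration, tolerance 1e-10)
and scaled by the conditional curvature; `n_quad = 1` is exactly the
Laplace approximation and is the default, matching the default of the
mixed-model software in common use — the printed reference values for the
count dataset are reproduced under this setting. Increasing `n_quad`
raises the approximated log-likelihood monotonically toward a stable limit
on the packaged data, moving the coefficients by < 0.01.

The outer optimization over (β₀, β₁, log σ) is BFGS (gradient tolerance
1e-7) started from the naive GLM coefficients and σ = 1. Standard errors
come from the inverse of the central-finite-difference observed-information
matrix of the approximated marginal likelihood; Wald z inference on the
log-odds scale. The same flat-likelihood boundary issue arises at σ → 0 as
in the Gaussian model and is handled the same way (snap to an effective
zero when not worse by 1e-6, then re-optimize β with σ fixed); at the
boundary the log-σ row of the information degenerates, so the coefficient
block is inverted on its own and the fit coincides with the GLM.

Predicted probabilities are *conditional* (random effect = 0, the typical
subject), not population-averaged: this keeps
logit(p_treated) − logit(p_control) = log(OR) as an exact identity, which
matches how the reference probabilities for the count dataset were
evidently computed.

### Classical analyses

The pooled t-test implements the textbook formulas directly
(s² = ((n₁−1)s₁² + (n₂−1)s₂²)/(n₁+n₂−2), sed = s√(1/n₁+1/n₂), two-sided p
on n₁+n₂−2 df) and is cross-checked against `scipy.stats.ttest_ind` on
random data. The subject-based test applies it to per-subject means; only
the mean is offered as a summary statistic (precision-weighted summaries
are deliberately not implemented, as no weighting rule is specified for
them). The naive logistic GLM is a Newton-Raphson fit of the
aggregated-binomial likelihood (convergence: relative log-likelihood change
< 1e-10, max 100 iterations; diverging coefficients or degenerate weights
are reported as separation); with the group indicator as the only covariate
it is saturated on the collapsed 2×2 table and must agree with the
direct odds-ratio formula to ~10 significant figures, which is tested.

Group orientation: differences and odds ratios are reported relative to a
reference group (default: first label in sorted order; settable via
`reference`). For the packaged datasets the sorted order makes "None" the
reference, so the reported difference is None − Short RT and the odds
ratio is Short RT versus None, matching the reference values.

## Design calculators

- `vif`: 1 + (m−1)·ICC, the factor by which within-cluster correlation
  inflates the variance of a treatment-effect estimate based on m
  correlated observations per cluster.
- `sample_size_two_group`: n = 2σ²(z_{α/2}+z_β)²/d² per group (α two-sided,
  default 0.05; power default 90%, giving multiplier (1.96+1.28)² ≈ 10.5);
  the ceiling and the raw value are both returned.
- `resource_equation_check`: nested-ANOVA error df per stratum
  (subjects: N_subj − groups; samples: N_subj(s−1); replicates: N_samp(r−1)),
  flagged adequate at ≥ 15 df.
- `naive_rejection_rate_approx`: 2Φ(−z_{α/2}/√VIF), the large-sample type-I
  error of the naive pooled analysis under clustering — the analytic oracle
  the simulation engine is checked against.

## Synthetic data and the Monte-Carlo engine

`simulate_nested_dataset` draws balanced nested Gaussian data
y = μ + effect·[treated] + u + v + ε with independent Normal components at
each stratum; μ defaults to 0 (it is a nuisance throughout) and treatment
is assigned at the subject level. It emulates exactly the variance
structure the Gaussian model assumes — it does not produce outliers,
skewness, heteroscedasticity, missingness or serial correlation, so
passing operating-characteristic tests demonstrate correctness of the
estimators under the model, not robustness to real-data pathologies.

`run_simulation_study` runs the naive, subject-based and mixed analyses on
each replicate and aggregates rejection rate (with binomial Monte-Carlo
SE), mean estimate, mean CI width and CI coverage. Replicate r draws its
generator from the seed pair (seed, r), so runs are reproducible and
replicates independent. Per-replicate fit failures are excluded and
counted, tolerated up to 1% of replicates. Default scenario grids live in
`data/default_study.yaml` (ICC {0, 0.1, 0.5} × cluster size {2, 5, 20},
20 subjects per group, unit total variance, 1000 replicates, null effect);
every result row is labelled with its scenario and seed.

Problem sizes used by the test suite were chosen to keep the full run at a
few minutes on one core while leaving Monte-Carlo bands well inside the
tested tolerances: 2000 replicates for the false-positive-inflation check
(3 MC SEs ≈ 0.015 at the nominal 5% level), 500 replicates for REML
parameter recovery, 100 datasets for the balanced-equivalence property.

## Numerical and design choices

- REML comparisons between random structures are valid here because the
  fixed effects are identical in both fits; the code refuses the LRT
  otherwise.
- Unbiasedness of REML variance estimation is asserted on the *variance*
  scale (σ̂²), not the SD scale: σ̂ is biased downward by Jensen's
  inequality even when σ̂² is unbiased, noticeably so with only 10 subject-
  stratum df.
- The unbalanced re-analysis of the size dataset depends on which records
  are deleted; `remove_fraction` removes records uniformly at random under
  the constraint that every subject keeps at least one record, and is
  deterministic given its seed. Reproductions of an unbalanced analysis are
  therefore qualitative (estimates finite, subject-based and mixed answers
  diverging), not value-matched.
- Missing cells in printed tables ("-" or empty) are absent records, not
  zeros.
- Floating-point output of the CLI and report renderer is serialized at 6
  significant digits by default.

## Known limitations

- Random-effect structures are limited to nested intercepts (no crossed
  effects, no random slopes); residuals are homoscedastic and uncorrelated
  (no repeated-measures autocorrelation).
- The binomial model offers the logit link only, subject-level random
  intercept only.
- Variance-component intervals are Wald-on-log, which can misbehave very
  close to the boundary (they are reported as NaN when the curvature is
  degenerate).
- The t-tests assume equal group variances (no Welch variant), matching
  the pooled-variance formulas they implement.
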