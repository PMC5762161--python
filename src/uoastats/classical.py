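"""Naive and subject-summary analyses implemented from first principles.

These are the two "classical" rungs of the analysis ladder for nested data:

* the *naive* (pooled) two-sample t-test, which treats every observation as
  independent — invalid whenever observations are clustered within subjects,
  because between-replicate variability is then used to judge a
  between-subject treatment effect (pseudoreplication);
* the *subject-based* analysis, which first collapses each subject to a
  single summary value (the mean) and then applies the same t-test — valid,
  at the cost of discarding within-subject information.

For binomial outcomes the analogous pair is the 2x2-table odds ratio /
single-covariate logistic regression (naive) versus the mixed-effects
logistic model in :mod:`uoastats.glmm`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .datasets import NestedDataset
from .errors import ConvergenceError, ValidationError

__all__ = [
    "TTestResult",
    "OddsRatioResult",
    "LogisticGLMResult",
    "pooled_t_test",
    "subject_summaries",
    "subject_based_t_test",
    "odds_ratio_2x2",
    "fit_logistic_glm",
]


@dataclass(frozen=True)
class TTestResult:
    """Two-sample pooled-variance t-test summary.

    ``difference`` is mean(first group) − mean(second group), where the first
    group is the reference (by default the first label in sorted order).
    """

    group_order: tuple[str, str]
    mean_per_group: dict
    difference: float
    sed: float
    t: float
    df: int
    p: float
    ci: tuple[float, float]
    conf_level: float
    n1: int
    n2: int
    s1_sq: float
    s2_sq: float
    pooled_var: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        a, b = self.group_order
        return (
            f"difference ({a} - {b}) = {self.difference:.4g} "
            f"(CI {self.ci[0]:.4g} to {self.ci[1]:.4g}), "
            f"t = {self.t:.4g} on {self.df} df, p = {self.p:.4g}"
        )


@dataclass(frozen=True)
class OddsRatioResult:
    """Odds ratio with Wald confidence interval on the log scale."""

    odds_ratio: float
    log_or: float
    se_log_or: float
    ci: tuple[float, float]
    conf_level: float
    counts: tuple[tuple[float, float], tuple[float, float]]


@dataclass(frozen=True)
class LogisticGLMResult:
    """Maximum-likelihood logistic regression with a single group covariate."""

    group_order: tuple[str, str]
    intercept: float
    coef: float
    se_intercept: float
    se_coef: float
    odds_ratio: float
    ci: tuple[float, float]
    p: float
    deviance: float
    loglik: float
    converged: bool
    n_iter: int

    @property
    def log_or(self) -> float:
        return self.coef

    @property
    def se_log_or(self) -> float:
        return self.se_coef


def _order_groups(labels, reference=None) -> tuple[str, str]:
    uniq = sorted(set(map(str, labels)))
    if len(uniq) != 2:
        raise ValidationError(f"exactly two groups required, got {uniq}")
    if reference is not None:
        reference = str(reference)
        if reference not in uniq:
            raise ValidationError(f"reference {reference!r} not among groups {uniq}")
        uniq = [reference] + [g for g in uniq if g != reference]
    return uniq[0], uniq[1]


def pooled_t_test(
    values, groups, conf_level: float = 0.95, reference: str | None = None
) -> TTestResult:
    """Two-sample t-test with the pooled-variance standard error.

    Implements the textbook formulas directly: the pooled variance
    ``s² = ((n1−1)s1² + (n2−1)s2²) / (n1+n2−2)`` and the standard error of the
    difference ``sed = s·√(1/n1 + 1/n2)``, with ``t = d̂ / sed`` referred to a
    t distribution on ``n1+n2−2`` degrees of freedom (two-sided).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray([str(g) for g in groups])
    if len(values) != len(groups):
        raise ValidationError("values and groups must have equal length")
    g1, g2 = _order_groups(groups, reference)
    x1, x2 = values[groups == g1], values[groups == g2]
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs at least two observations")
    m1, m2 = x1.mean(), x2.mean()
    s1_sq, s2_sq = x1.var(ddof=1), x2.var(ddof=1)
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * s1_sq + (n2 - 1) * s2_sq) / df
    sed = np.sqrt(pooled) * np.sqrt(1.0 / n1 + 1.0 / n2)
    diff = m1 - m2
    if sed == 0.0:
        raise ValidationError(
            "pooled variance is zero: the t statistic is undefined"
        )
    t_stat = diff / sed
    p = 2.0 * stats.t.sf(abs(t_stat), df)
    tcrit = stats.t.ppf(0.5 + conf_level / 2.0, df)
    return TTestResult(
        group_order=(g1, g2),
        mean_per_group={g1: m1, g2: m2},
        difference=diff,
        sed=sed,
        t=t_stat,
        df=df,
        p=p,
        ci=(diff - tcrit * sed, diff + tcrit * sed),
        conf_level=conf_level,
        n1=n1,
        n2=n2,
        s1_sq=s1_sq,
        s2_sq=s2_sq,
        pooled_var=pooled,
    )


def subject_summaries(data: NestedDataset, statistic: str = "mean"):
    """One summary value per subject (experimental unit).

    Only the mean is currently supported.  With unbalanced data the
    per-subject means are based on unequal record counts and are therefore
    unweighted summaries; a warning flags this.
    """
    if data.outcome_kind != "continuous":
        raise ValidationError("subject summaries require a continuous outcome")
    if statistic != "mean":
        raise ValidationError(f"unsupported summary statistic {statistic!r}")
    grp = data.frame.groupby(["subject", "group"], observed=True)["value"]
    out = grp.agg(summary="mean", n_records="size").reset_index()
    out = out.sort_values("subject", key=lambda s: s.map(_subject_key))
    out = out.reset_index(drop=True)
    if out["n_records"].nunique() > 1:
        warnings.warn(
            "subjects contribute unequal numbers of records; per-subject means "
            "are unweighted summaries",
            UserWarning,
            stacklevel=2,
        )
    return out[["subject", "group", "n_records", "summary"]]


def _subject_key(s: str):
    return (0, int(s)) if str(s).isdigit() else (1, str(s))


def subject_based_t_test(
    data: NestedDataset, conf_level: float = 0.95, reference: str | None = None
) -> TTestResult:
    """Pooled t-test on per-subject mean summaries.

    This is the valid classical analysis when treatment is applied at the
    subject level: each experimental unit contributes exactly one value, so
    the independence assumption of the t-test holds between units.
    """
    summ = subject_summaries(data)
    return pooled_t_test(
        summ["summary"].to_numpy(),
        summ["group"].to_numpy(),
        conf_level=conf_level,
        reference=reference,
    )


def odds_ratio_2x2(
    events_a: float,
    nonevents_a: float,
    events_b: float,
    nonevents_b: float,
    conf_level: float = 0.95,
    continuity: bool = False,
) -> OddsRatioResult:
    """Odds ratio for group *a* versus group *b* from a 2x2 table.

    OR = (events_a/nonevents_a) / (events_b/nonevents_b), with the Wald
    interval built on the log scale using
    se = sqrt(1/a + 1/b + 1/c + 1/d).  An optional 0.5 continuity correction
    (off by default) handles zero cells.
    """
    cells = [events_a, nonevents_a, events_b, nonevents_b]
    if any(c < 0 for c in cells):
        raise ValidationError("2x2 cell counts must be non-negative")
    if continuity:
        cells = [c + 0.5 for c in cells]
    a, b, c, d = cells
    if min(a, b, c, d) == 0:
        raise ValidationError(
            "zero cell in 2x2 table; pass continuity=True for a 0.5 correction"
        )
    log_or = np.log((a / b) / (c / d))
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    return OddsRatioResult(
        odds_ratio=float(np.exp(log_or)),
        log_or=float(log_or),
        se_log_or=float(se),
        ci=(float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))),
        conf_level=conf_level,
        counts=((events_a, nonevents_a), (events_b, nonevents_b)),
    )


def fit_logistic_glm(
    data: NestedDataset,
    conf_level: float = 0.95,
    reference: str | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticGLMResult:
    """Naive binomial logistic regression with group as the sole covariate.

    Newton–Raphson maximum likelihood on the aggregated-binomial likelihood
    (events out of trials per record).  The group coefficient is the log
    odds ratio of the non-reference group versus the reference group.  With a
    single binary covariate the model is saturated on the collapsed 2x2 table,
    so the estimates coincide with :func:`odds_ratio_2x2`.

    This analysis ignores subject-level clustering entirely; it is provided
    as the naive comparator for :func:`uoastats.glmm.fit_logistic_glmm`.
    """
    if data.outcome_kind != "binomial":
        raise ValidationError("logistic regression requires a binomial outcome")
    g1, g2 = _order_groups(data.frame["group"], reference)
    k = data.frame["events"].to_numpy(dtype=float)
    n = data.frame["trials"].to_numpy(dtype=float)
    x = (data.frame["group"].to_numpy() == g2).astype(float)
    X = np.column_stack([np.ones_like(x), x])

    beta = np.zeros(2)
    converged = False
    ll_old = -np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = special.expit(eta)
        ll = float(np.sum(k * eta - n * np.log1p(np.exp(eta))))
        grad = X.T @ (k - n * p)
        w = n * p * (1.0 - p)
        if w.max() < 1e-12:
            raise ConvergenceError("complete separation detected (degenerate weights)")
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        beta = beta + step
        if np.abs(ll - ll_old) <= tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_old = ll
    if not converged:
        raise ConvergenceError(f"logistic GLM did not converge in {max_iter} iterations")
    if np.abs(beta).max() > 15:
        raise ConvergenceError("complete separation detected (diverging coefficients)")

    eta = X @ beta
    p_hat = special.expit(eta)
    w = n * p_hat * (1.0 - p_hat)
    cov = np.linalg.inv(X.T @ (X * w[:, None]))
    se = np.sqrt(np.diag(cov))
    # loglik / deviance including binomial coefficients
    loglik = float(
        np.sum(
            special.gammaln(n + 1)
            - special.gammaln(k + 1)
            - special.gammaln(n - k + 1)
            + k * eta
            - n * np.log1p(np.exp(eta))
        )
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        sat = np.where(k > 0, k * np.log(k / n), 0.0) + np.where(
            n - k > 0, (n - k) * np.log1p(-np.where(k < n, k / n, 0.0)), 0.0
        )
    deviance = float(2.0 * np.sum(sat - (k * eta - n * np.log1p(np.exp(eta)))))
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    p_val = 2.0 * stats.norm.sf(abs(beta[1] / se[1]))
    return LogisticGLMResult(
        group_order=(g1, g2),
        intercept=float(beta[0]),
        coef=float(beta[1]),
        se_intercept=float(se[0]),
        se_coef=float(se[1]),
        odds_ratio=float(np.exp(beta[1])),
        ci=(float(np.exp(beta[1] - z * se[1])), float(np.exp(beta[1] + z * se[1]))),
        p=float(p_val),
        deviance=deviance,
        loglik=loglik,
        converged=converged,
        n_iter=it,
    )
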