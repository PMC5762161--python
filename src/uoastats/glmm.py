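"""Binomial logistic mixed model with a subject-level random intercept.

For per-sample counts k_ij out of n_ij (sample j of subject i) the model is

    k_ij | b_i ~ Binomial(n_ij, p_ij),   logit(p_ij) = x_ij' beta + b_i,
    b_i ~ N(0, sigma^2),

with treatment as the fixed covariate.  The marginal likelihood integrates
the random intercept out of each subject's contribution; the integral is
approximated by adaptive Gauss-Hermite quadrature centred and scaled at the
conditional mode (``n_quad`` nodes), which at ``n_quad = 1`` is exactly the
Laplace approximation.  Standard errors come from the numerically
differentiated observed information of the approximated marginal
log-likelihood; Wald z inference on the log-odds scale.

The aggregated-binomial likelihood is used directly (not a Bernoulli
expansion); the two differ only by the fixed binomial coefficients, which are
included so log-likelihoods are comparable across quadrature orders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .classical import fit_logistic_glm
from .datasets import NestedDataset
from .errors import ConvergenceError, ValidationError

__all__ = ["GLMMFit", "fit_logistic_glmm", "predict_probability"]

_INNER_TOL = 1e-10
_INNER_MAX = 100


@dataclass(frozen=True)
class GLMMFit:
    """Fitted binomial logistic mixed model."""

    coefficients: pd.DataFrame
    sigma_subject: float
    or_table: pd.DataFrame
    loglik: float
    n_quad: int
    converged: bool
    n_iterations: int
    boundary: bool
    group_order: tuple[str, ...]
    conf_level: float

    @property
    def log_or(self) -> float:
        return float(self.coefficients["estimate"].iloc[1])

    @property
    def se_log_or(self) -> float:
        return float(self.coefficients["se"].iloc[1])

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.log_or))


class _MarginalLoglik:
    """Adaptive Gauss-Hermite marginal log-likelihood, one random intercept."""

    def __init__(self, data: NestedDataset, reference=None):
        if data.outcome_kind != "binomial":
            raise ValidationError("the logistic GLMM requires a binomial outcome")
        df = data.frame
        groups = sorted(df["group"].unique())
        if reference is not None:
            reference = str(reference)
            if reference not in groups:
                raise ValidationError(f"unknown reference group {reference!r}")
            groups = [reference] + [g for g in groups if g != reference]
        if len(groups) != 2:
            raise ValidationError("exactly two treatment groups required")
        per_group = df.drop_duplicates("subject").groupby("group", observed=True).size()
        if (per_group < 2).any():
            raise ValidationError("each group needs at least two subjects")
        self.groups = tuple(groups)
        self.subjects = []
        for sid, sub in df.groupby("subject", observed=True, sort=True):
            k = sub["events"].to_numpy(float)
            n = sub["trials"].to_numpy(float)
            x = float(sub["group"].iloc[0] == groups[1])
            logC = float(
                np.sum(
                    special.gammaln(n + 1)
                    - special.gammaln(k + 1)
                    - special.gammaln(n - k + 1)
                )
            )
            self.subjects.append((k, n, x, logC))

    @staticmethod
    def _mode(k, n, eta0, sigma2):
        """Newton search for the conditional mode of the random intercept."""
        b = 0.0
        for _ in range(_INNER_MAX):
            p = special.expit(eta0 + b)
            g = np.sum(k - n * p) - b / sigma2
            h = -np.sum(n * p * (1.0 - p)) - 1.0 / sigma2
            step = g / h
            b -= step
            if abs(step) < _INNER_TOL:
                break
        return b, -h

    def __call__(self, params: np.ndarray, n_quad: int) -> float:
        beta0, beta1, log_sigma = params
        sigma2 = np.exp(2.0 * log_sigma)
        nodes, weights = special.roots_hermite(n_quad)
        total = 0.0
        for k, n, x, logC in self.subjects:
            eta0 = beta0 + beta1 * x
            bhat, H = self._mode(k, n, eta0, sigma2)

            def h(b):
                eta = eta0 + b
                return (
                    float(np.sum(k * eta - n * np.log1p(np.exp(eta))))
                    - 0.5 * b * b / sigma2
                    - 0.5 * np.log(2 * np.pi * sigma2)
                )

            scale = np.sqrt(2.0 / H)
            vals = np.array([np.log(w) + t * t + h(bhat + scale * t) for t, w in zip(nodes, weights)])
            total += logC + special.logsumexp(vals) + np.log(scale)
        return total


def fit_logistic_glmm(
    data: NestedDataset,
    n_quad: int = 1,
    conf_level: float = 0.95,
    reference: str | None = None,
) -> GLMMFit:
    """Fit the binomial GLMM by maximizing the approximated marginal likelihood.

    Parameters
    ----------
    data
        Binomial :class:`~uoastats.datasets.NestedDataset` (events out of
        trials per sample, subject-level treatment).
    n_quad
        Number of adaptive Gauss-Hermite nodes; 1 is the Laplace
        approximation (the default, matching common mixed-model software).
    reference
        Reference treatment group; the reported odds ratio is the other group
        versus this one.

    Returns
    -------
    GLMMFit
        Log-odds coefficients with Wald z inference, the random-intercept SD
        on the log-odds scale, and odds ratios with exp-transformed Wald CIs.
    """
    if not (isinstance(n_quad, (int, np.integer)) and n_quad >= 1):
        raise ValidationError(f"n_quad must be an integer >= 1, got {n_quad!r}")
    ml = _MarginalLoglik(data, reference=reference)

    glm = fit_logistic_glm(data, reference=reference)
    start = np.array([glm.intercept, glm.coef, 0.0])

    def nll(params):
        return -ml(params, n_quad)

    res = optimize.minimize(
        nll, start, method="BFGS", options={"gtol": 1e-7, "maxiter": 500}
    )
    if not res.success and float(np.max(np.abs(res.jac))) > 1e-3:
        res2 = optimize.minimize(
            nll,
            start,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if res2.fun <= res.fun:
            res = res2
        else:
            raise ConvergenceError("GLMM optimization failed to converge")
    params = res.x
    # the marginal likelihood is flat in log sigma near sigma = 0, so the
    # optimizer can stall above the boundary; snap to an effective zero when
    # that does not worsen the fit (re-optimizing the coefficients there)
    trial = optimize.minimize(
        lambda b: nll(np.concatenate([b, [-10.0]])),
        params[:2],
        method="BFGS",
        options={"gtol": 1e-7},
    )
    if trial.fun <= res.fun + 1e-6:
        params = np.concatenate([trial.x, [-10.0]])
        res = trial
    loglik = -float(nll(params))
    sigma = float(np.exp(params[2]))
    boundary = sigma < 1e-4

    # observed information of (beta0, beta1) with log sigma included; the
    # Wald covariance for the coefficients is the corresponding block of the
    # inverse full-information matrix.  At the sigma ~ 0 boundary the log-sigma
    # row of the information degenerates, so the coefficient block is used on
    # its own (the fit is then effectively the fixed-effects GLM).
    if boundary:
        H = _num_hessian(lambda b: nll(np.concatenate([b, params[2:]])), params[:2])
    else:
        H = _num_hessian(nll, params)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError("singular observed information matrix") from exc
    se = np.sqrt(np.clip(np.diag(cov)[:2], 0.0, np.inf))

    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    est = params[:2]
    zvals = est / se
    terms = ["(intercept)", f"group[{ml.groups[1]}]"]
    coef = pd.DataFrame(
        {
            "term": terms,
            "estimate": est,
            "se": se,
            "z": zvals,
            "p": 2.0 * stats.norm.sf(np.abs(zvals)),
            "ci_low": est - z * se,
            "ci_high": est + z * se,
        }
    )
    or_table = pd.DataFrame(
        {
            "term": [terms[1]],
            "odds_ratio": [np.exp(est[1])],
            "ci_low": [np.exp(est[1] - z * se[1])],
            "ci_high": [np.exp(est[1] + z * se[1])],
        }
    )
    return GLMMFit(
        coefficients=coef,
        sigma_subject=sigma,
        or_table=or_table,
        loglik=loglik,
        n_quad=int(n_quad),
        converged=True,
        n_iterations=int(getattr(res, "nit", -1)),
        boundary=bool(boundary),
        group_order=ml.groups,
        conf_level=conf_level,
    )


def _num_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = h
            ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h**2)
    return H


def predict_probability(fit: GLMMFit, group: str, at_random_effect: float = 0.0) -> float:
    """Conditional predicted probability for a group at a given random effect.

    ``logit^{-1}(intercept + group coefficient + b)`` evaluated at
    ``b = at_random_effect`` (default 0, i.e. the typical subject).  Note
    these are conditional, not population-averaged, probabilities: the logit
    difference between the two groups equals the fitted log odds ratio
    exactly.
    """
    if not fit.converged:
        raise ValidationError("prediction requires a converged fit")
    group = str(group)
    if group not in fit.group_order:
        raise ValidationError(f"unknown group {group!r}; fitted groups {fit.group_order}")
    eta = float(fit.coefficients["estimate"].iloc[0]) + at_random_effect
    if group == fit.group_order[1]:
        eta += float(fit.coefficients["estimate"].iloc[1])
    return float(special.expit(eta))
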