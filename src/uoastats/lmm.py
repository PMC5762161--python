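"""REML estimation for nested Gaussian linear mixed models.

The model for a three-level nested design (slices within samples within
subjects, treatment applied to subjects) is

    y = X b + Z_P u_P + Z_S u_S + e,
    u_P ~ N(0, sigma_P^2 I),  u_S ~ N(0, sigma_S^2 I),  e ~ N(0, sigma_e^2 I),

with independent random intercepts for subjects and for samples nested
within subjects.  Estimation maximizes the restricted likelihood over the
log variance *ratios* theta_c = log(sigma_c / sigma_e); the residual scale
and the fixed effects are profiled out in closed form at every step, so the
optimization is one- or two-dimensional.  The marginal covariance is never
formed: each subject contributes an independent block
V_i = sigma_e^2 (I + Z_i Gamma Z_i'), handled through the Woodbury identity
on the (1 + n_samples_i)-dimensional inner matrix, which makes likelihood
evaluations cheap enough for Monte-Carlo use.

Fixed-effect inference uses containment (stratum) degrees of freedom: a
subject-level treatment is tested against the between-subject stratum,
df = n_subjects - n_fixed_parameters.  Variance-component intervals are Wald
intervals on the log(sigma) scale from the numerically differentiated
restricted-likelihood Hessian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datasets import NestedDataset
from .errors import ConvergenceError, ValidationError

__all__ = [
    "VarianceComponents",
    "LMMFit",
    "fit_nested_lmm",
    "icc",
    "lrt_random_structure",
    "diagnostics",
]

#: a fitted sigma ratio below this (relative to sigma_e) is a boundary estimate
_BOUNDARY_RATIO = 1e-4


@dataclass(frozen=True)
class VarianceComponents:
    """Standard deviations of the random-effect strata, in outcome units.

    ``sigma_sample`` is ``None`` for two-level (subject + residual) models.
    """

    sigma_subject: float
    sigma_sample: float | None
    sigma_resid: float

    def __post_init__(self) -> None:
        for name in ("sigma_subject", "sigma_sample", "sigma_resid"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be non-negative, got {v}")

    def as_dict(self) -> dict[str, float]:
        d = {"sigma_subject": self.sigma_subject, "sigma_resid": self.sigma_resid}
        if self.sigma_sample is not None:
            d["sigma_sample"] = self.sigma_sample
        return d

    @property
    def total_variance(self) -> float:
        s2 = self.sigma_subject**2 + self.sigma_resid**2
        if self.sigma_sample is not None:
            s2 += self.sigma_sample**2
        return s2


@dataclass(frozen=True)
class LMMFit:
    """Result of a nested linear mixed-model fit."""

    method: str
    levels: tuple[str, ...]
    fixed_effects: pd.DataFrame
    components: VarianceComponents
    component_ci: dict[str, tuple[float, float]]
    loglik: float
    fitted: np.ndarray
    residuals: np.ndarray
    converged: bool
    n_iterations: int
    boundary: dict[str, bool]
    n_obs: int
    n_subjects: int
    group_order: tuple[str, ...]
    subject_per_record: np.ndarray = field(repr=False)
    conf_level: float = 0.95

    @property
    def group_effect(self) -> pd.Series:
        """The treatment-contrast row of the fixed-effects table."""
        return self.fixed_effects.iloc[-1]

    @property
    def group_difference(self) -> dict:
        """Two-group mean difference oriented as reference minus treatment.

        Matches the sign convention of :class:`uoastats.classical.TTestResult`
        (first-listed group minus second), so balanced-design equivalence with
        the subject-means t-test can be checked term by term.
        """
        if len(self.group_order) != 2:
            raise ValidationError("group_difference is defined for two groups only")
        row = self.fixed_effects.iloc[-1]
        return {
            "difference": -row["estimate"],
            "se": row["se"],
            "t": -row["t"],
            "df": int(row["df"]),
            "p": row["p"],
            "ci": (-row["ci_high"], -row["ci_low"]),
        }


# ---------------------------------------------------------------------------
# model matrices
# ---------------------------------------------------------------------------

class _Blocks:
    """Per-subject sufficient statistics for the profiled REML objective."""

    def __init__(self, data: NestedDataset, levels, reference=None):
        if data.outcome_kind != "continuous":
            raise ValidationError("the Gaussian LMM requires a continuous outcome")
        levels = tuple(levels)
        if levels not in {("subject",), ("subject", "sample")}:
            raise ValidationError(
                f"unsupported nesting spec {levels!r}; use ('subject',) or "
                "('subject', 'sample')"
            )
        df = data.frame
        groups = sorted(df["group"].unique())
        if reference is not None:
            reference = str(reference)
            if reference not in groups:
                raise ValidationError(f"unknown reference group {reference!r}")
            groups = [reference] + [g for g in groups if g != reference]
        if len(groups) < 2:
            raise ValidationError("at least two treatment groups required")
        per_group = df.drop_duplicates("subject").groupby("group", observed=True).size()
        if (per_group < 2).any():
            raise ValidationError("each group needs at least two subjects")

        self.levels = levels
        self.groups = tuple(groups)
        self.y = df["value"].to_numpy(dtype=float)
        # treatment coding: intercept + indicators for non-reference groups
        X = np.ones((len(df), len(groups)))
        for j, g in enumerate(groups[1:], start=1):
            X[:, j] = (df["group"] == g).astype(float)
        self.X = X
        self.n, self.p = X.shape
        self.subjects = df["subject"].to_numpy()
        self.subject_ids = sorted(set(self.subjects), key=lambda s: (len(s), s))
        self.n_subjects = len(self.subject_ids)

        self.blocks = []
        for sid in self.subject_ids:
            m = self.subjects == sid
            Xi, yi = X[m], self.y[m]
            cols = [np.ones(m.sum())]  # subject intercept
            kinds = [0]
            if "sample" in levels:
                for samp in pd.unique(df.loc[m, "sample"]):
                    cols.append((df.loc[m, "sample"] == samp).to_numpy(float))
                    kinds.append(1)
            Zi = np.column_stack(cols)
            self.blocks.append(
                {
                    "Z": Zi,
                    "kind": np.asarray(kinds),
                    "ZtZ": Zi.T @ Zi,
                    "ZtX": Zi.T @ Xi,
                    "Zty": Zi.T @ yi,
                    "XtX": Xi.T @ Xi,
                    "Xty": Xi.T @ yi,
                    "yty": float(yi @ yi),
                    "mask": m,
                }
            )
        self.n_components = 2 if "sample" in levels else 1

    # -- profiled pieces ---------------------------------------------------
    def _whitened(self, gamma: np.ndarray):
        """Accumulate X'W^-1 X, X'W^-1 y, y'W^-1 y and log|W| for
        W = I + Z Gamma Z' with Gamma = diag(gamma[kind])."""
        p = self.p
        XtWX = np.zeros((p, p))
        XtWy = np.zeros(p)
        yWy = 0.0
        logdetW = 0.0
        for b in self.blocks:
            s = np.sqrt(gamma[b["kind"]])
            M = np.eye(len(s)) + (s[:, None] * b["ZtZ"] * s[None, :])
            L = np.linalg.cholesky(M)
            logdetW += 2.0 * float(np.sum(np.log(np.diag(L))))
            SX = s[:, None] * b["ZtX"]
            Sy = s * b["Zty"]
            A = np.linalg.solve(L, np.column_stack([SX, Sy]))
            AX, Ay = A[:, :-1], A[:, -1]
            XtWX += b["XtX"] - AX.T @ AX
            XtWy += b["Xty"] - AX.T @ Ay
            yWy += b["yty"] - float(Ay @ Ay)
        return XtWX, XtWy, yWy, logdetW

    def profiled_negloglik(self, theta: np.ndarray, method: str) -> float:
        """-loglik as a function of log sigma ratios, with beta and the
        residual scale profiled out."""
        theta = np.asarray(theta, dtype=float)
        if not np.all(np.isfinite(theta)) or np.any(np.abs(theta) > 40):
            return np.inf
        gamma = np.exp(2.0 * theta)
        try:
            XtWX, XtWy, yWy, logdetW = self._whitened(gamma)
        except np.linalg.LinAlgError:
            return np.inf
        sign, logdetXtWX = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtWX, XtWy)
        ypy = yWy - float(XtWy @ beta)
        if ypy <= 0:
            return np.inf
        if method == "REML":
            d = self.n - self.p
            s2 = ypy / d
            ll = -0.5 * (d * (np.log(2 * np.pi * s2) + 1.0) + logdetW + logdetXtWX)
        else:
            s2 = ypy / self.n
            ll = -0.5 * (self.n * (np.log(2 * np.pi * s2) + 1.0) + logdetW)
        return -ll

    def negloglik_full(self, eta: np.ndarray, method: str) -> float:
        """-loglik as a function of all log SDs (subject[, sample], resid);
        used for the curvature-based variance-component intervals."""
        log_sigma = np.asarray(eta, dtype=float)
        theta = log_sigma[:-1] - log_sigma[-1]
        gamma = np.exp(2.0 * theta)
        s2 = np.exp(2.0 * log_sigma[-1])
        try:
            XtWX, XtWy, yWy, logdetW = self._whitened(gamma)
        except np.linalg.LinAlgError:
            return np.inf
        sign, logdetXtWX = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtWX, XtWy)
        ypy = yWy - float(XtWy @ beta)
        if method == "REML":
            d = self.n - self.p
            ll = -0.5 * (
                d * np.log(2 * np.pi)
                + d * np.log(s2)
                + logdetW
                + logdetXtWX
                + ypy / s2
            )
        else:
            ll = -0.5 * (
                self.n * np.log(2 * np.pi) + self.n * np.log(s2) + logdetW + ypy / s2
            )
        return -ll

    def solve_beta(self, gamma: np.ndarray):
        XtWX, XtWy, yWy, _ = self._whitened(gamma)
        beta = np.linalg.solve(XtWX, XtWy)
        ypy = yWy - float(XtWy @ beta)
        return beta, np.linalg.inv(XtWX), ypy

    def blups(self, gamma: np.ndarray, beta: np.ndarray) -> np.ndarray:
        """Conditional (BLUP) contribution Z u_hat per record.

        u_hat = Gamma Z' W^-1 r with W^-1 expanded by Woodbury:
        W^-1 r = r - Z S M^-1 S Z' r, S = Gamma^{1/2}, M = I + S Z'Z S.
        """
        out = np.zeros(self.n)
        for b in self.blocks:
            ri = self.y[b["mask"]] - self.X[b["mask"]] @ beta
            s = np.sqrt(gamma[b["kind"]])
            M = np.eye(len(s)) + (s[:, None] * b["ZtZ"] * s[None, :])
            Ztr = b["Z"].T @ ri
            w = s * np.linalg.solve(M, s * Ztr)
            u = gamma[b["kind"]] * (Ztr - b["ZtZ"] @ w)
            out[b["mask"]] = b["Z"] @ u
        return out


def _anova_start(data: NestedDataset, levels) -> np.ndarray:
    """Method-of-moments (expected mean squares) starting values, as log
    sigma ratios.  Exact for balanced designs (see
    :func:`anova_variance_components`); with unbalanced data the per-stratum
    multipliers use average counts, which is good enough for a start point."""
    df = data.frame
    y = df["value"].to_numpy(float)
    grand = df.groupby("group", observed=True)["value"].transform("mean").to_numpy()
    subj_mean = df.groupby("subject", observed=True)["value"].transform("mean").to_numpy()
    n = len(y)
    n_subj = df["subject"].nunique()
    n_groups = df["group"].nunique()
    m_bar = n / n_subj

    if "sample" in levels:
        samp_mean = (
            df.groupby(["subject", "sample"], observed=True)["value"].transform("mean").to_numpy()
        )
        n_samp = len(df.drop_duplicates(["subject", "sample"]))
        r_bar = n / n_samp  # replicates per sample
        s_bar = n_samp / n_subj  # samples per subject
        # per-record stratum sums of squares already carry the count multipliers
        ms_res = np.sum((y - samp_mean) ** 2) / max(n - n_samp, 1)
        ms_samp = np.sum((samp_mean - subj_mean) ** 2) / max(n_samp - n_subj, 1)
        ms_subj = np.sum((subj_mean - grand) ** 2) / max(n_subj - n_groups, 1)
        s2_e = ms_res
        s2_s = max((ms_samp - ms_res) / r_bar, 0.0)
        s2_p = max((ms_subj - ms_samp) / (r_bar * s_bar), 0.0)
        sigmas = np.array([s2_p, s2_s, s2_e])
    else:
        ms_res = np.sum((y - subj_mean) ** 2) / max(n - n_subj, 1)
        ms_subj = np.sum((subj_mean - grand) ** 2) / max(n_subj - n_groups, 1)
        s2_p = max((ms_subj - ms_res) / m_bar, 0.0)
        sigmas = np.array([s2_p, ms_res])
    floor = 1e-4 * np.var(y) if np.var(y) > 0 else 1e-8
    sigmas = np.maximum(sigmas, floor)
    return 0.5 * np.log(sigmas[:-1] / sigmas[-1])


def anova_variance_components(data: NestedDataset, levels=("subject", "sample")):
    """Closed-form ANOVA (expected-mean-squares) variance components for a
    *balanced* nested design.

    For r replicates per sample and s samples per subject:
    ``sigma_e^2 = MS_resid``, ``sigma_S^2 = (MS_sample - MS_resid)/r`` and
    ``sigma_P^2 = (MS_subject - MS_sample)/(r s)``, where each mean square is
    the stratum sum of squares (per record) over its degrees of freedom.
    Negative solutions are truncated at zero.  Serves as the independent
    method-of-moments oracle for the REML fit on balanced data.
    """
    if not data.is_balanced:
        raise ValidationError("ANOVA estimators require a balanced design")
    df = data.frame
    y = df["value"].to_numpy(float)
    n = len(y)
    n_subj = df["subject"].nunique()
    n_groups = df["group"].nunique()
    grand = df.groupby("group", observed=True)["value"].transform("mean").to_numpy()
    subj_mean = df.groupby("subject", observed=True)["value"].transform("mean").to_numpy()
    if "sample" in levels:
        samp_mean = (
            df.groupby(["subject", "sample"], observed=True)["value"].transform("mean").to_numpy()
        )
        n_samp = len(df.drop_duplicates(["subject", "sample"]))
        r = n // n_samp
        s = n_samp // n_subj
        ss_res = np.sum((y - samp_mean) ** 2)
        ss_samp = np.sum((samp_mean - subj_mean) ** 2)
        ss_subj = np.sum((subj_mean - grand) ** 2)
        ms_res = ss_res / (n - n_samp)
        ms_samp = ss_samp / (n_samp - n_subj)
        ms_subj = ss_subj / (n_subj - n_groups)
        s2_e = ms_res
        s2_s = max((ms_samp - ms_res) / r, 0.0)
        s2_p = max((ms_subj - ms_samp) / (r * s), 0.0)
        return VarianceComponents(np.sqrt(s2_p), np.sqrt(s2_s), np.sqrt(s2_e))
    m = n // n_subj
    ss_res = np.sum((y - subj_mean) ** 2)
    ss_subj = np.sum((subj_mean - grand) ** 2)
    ms_res = ss_res / (n - n_subj)
    ms_subj = ss_subj / (n_subj - n_groups)
    s2_p = max((ms_subj - ms_res) / m, 0.0)
    return VarianceComponents(np.sqrt(s2_p), None, np.sqrt(ms_res))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_nested_lmm(
    data: NestedDataset,
    levels=("subject", "sample"),
    method: str = "REML",
    conf_level: float = 0.95,
    reference: str | None = None,
    compute_component_ci: bool = True,
) -> LMMFit:
    """Fit the nested random-intercept Gaussian mixed model.

    Parameters
    ----------
    data
        Continuous-outcome :class:`~uoastats.datasets.NestedDataset`.
    levels
        Ordered nesting spec: ``("subject",)`` for a two-level model or
        ``("subject", "sample")`` for the three-level model with samples
        nested in subjects.
    method
        ``"REML"`` (default) or ``"ML"``.
    reference
        Reference treatment group; the fixed-effect contrasts are the other
        groups minus this one.  Defaults to the first label in sorted order.

    Returns
    -------
    LMMFit
        Point estimates with stratum-df t inference for fixed effects,
        variance components with log-scale Wald intervals, the (restricted)
        log-likelihood, and conditional fitted values / residuals.
    """
    if method not in {"REML", "ML"}:
        raise ValidationError(f"method must be 'REML' or 'ML', got {method!r}")
    blocks = _Blocks(data, levels, reference=reference)
    theta0 = _anova_start(data, blocks.levels)
    theta0 = np.clip(theta0, np.log(1e-3), np.log(1e3))

    res = optimize.minimize(
        blocks.profiled_negloglik,
        theta0,
        args=(method,),
        method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    theta = res.x
    if not res.success:
        # BFGS can stall on precision loss at an essentially converged point;
        # accept if the gradient is small, else retry from a neutral start.
        gnorm = float(np.max(np.abs(res.jac)))
        if gnorm > 1e-5:
            res2 = optimize.minimize(
                blocks.profiled_negloglik,
                np.zeros_like(theta0),
                args=(method,),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
            )
            if res2.fun <= res.fun:
                res, theta = res2, res2.x
            if not (res.success or float(res.fun) < np.inf):
                raise ConvergenceError("mixed-model optimization failed to converge")

    # boundary handling: near gamma = 0 the profiled criterion is flat in the
    # log ratio, so the optimizer can stall short of the boundary; snap any
    # component to an effective zero when that does not worsen the criterion
    f_cur = float(blocks.profiled_negloglik(theta, method))
    for c in range(len(theta)):
        trial = theta.copy()
        trial[c] = -12.0
        f_trial = float(blocks.profiled_negloglik(trial, method))
        if f_trial <= f_cur + 1e-6:
            theta, f_cur = trial, min(f_trial, f_cur)

    gamma = np.exp(2.0 * theta)
    beta, XtWX_inv, ypy = blocks.solve_beta(gamma)
    dres = blocks.n - blocks.p if method == "REML" else blocks.n
    s2_e = ypy / dres
    sigma_e = float(np.sqrt(s2_e))
    sig = np.sqrt(gamma) * sigma_e
    loglik = -float(blocks.profiled_negloglik(theta, method))

    boundary = {}
    names = ["sigma_subject", "sigma_sample"][: blocks.n_components]
    for name, ratio in zip(names, np.sqrt(gamma)):
        boundary[name] = bool(ratio < _BOUNDARY_RATIO)
    boundary["sigma_resid"] = False
    if boundary.get("sigma_sample"):
        warnings.warn(
            "sample-level variance estimated at the boundary (~0); inference "
            "effectively reduces to the subject-only model",
            UserWarning,
            stacklevel=2,
        )

    if blocks.n_components == 2:
        components = VarianceComponents(float(sig[0]), float(sig[1]), sigma_e)
    else:
        components = VarianceComponents(float(sig[0]), None, sigma_e)

    # variance-component CIs: Wald on log(sigma) via numerical Hessian
    component_ci: dict[str, tuple[float, float]] = {}
    if compute_component_ci:
        eta_hat = np.concatenate([np.log(np.maximum(sig, 1e-12)), [np.log(sigma_e)]])
        H = _num_hessian(lambda e: blocks.negloglik_full(e, method), eta_hat)
        z = stats.norm.ppf(0.5 + conf_level / 2.0)
        try:
            cov = np.linalg.inv(H)
            se_log = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            se_log = np.full(len(eta_hat), np.nan)
        all_names = names + ["sigma_resid"]
        all_sig = list(sig) + [sigma_e]
        for nm, s_hat, se in zip(all_names, all_sig, se_log):
            if np.isfinite(se) and s_hat > 0:
                component_ci[nm] = (s_hat * np.exp(-z * se), s_hat * np.exp(z * se))
            else:
                component_ci[nm] = (np.nan, np.nan)

    # fixed effects: stratum (containment) df for a subject-level treatment
    se_beta = np.sqrt(np.diag(XtWX_inv) * s2_e)
    df_strat = blocks.n_subjects - blocks.p
    tcrit = stats.t.ppf(0.5 + conf_level / 2.0, df_strat)
    terms = ["(intercept)"] + [f"group[{g}]" for g in blocks.groups[1:]]
    tvals = beta / se_beta
    fixed = pd.DataFrame(
        {
            "term": terms,
            "estimate": beta,
            "se": se_beta,
            "df": df_strat,
            "t": tvals,
            "p": 2.0 * stats.t.sf(np.abs(tvals), df_strat),
            "ci_low": beta - tcrit * se_beta,
            "ci_high": beta + tcrit * se_beta,
        }
    )

    zb = blocks.blups(gamma, beta)
    fitted = blocks.X @ beta + zb
    residuals = blocks.y - fitted

    return LMMFit(
        method=method,
        levels=blocks.levels,
        fixed_effects=fixed,
        components=components,
        component_ci=component_ci,
        loglik=loglik,
        fitted=fitted,
        residuals=residuals,
        converged=True,
        n_iterations=int(res.nit) if hasattr(res, "nit") else -1,
        boundary=boundary,
        n_obs=blocks.n,
        n_subjects=blocks.n_subjects,
        group_order=blocks.groups,
        subject_per_record=blocks.subjects,
        conf_level=conf_level,
    )


def _num_hessian(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian."""
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


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------

def icc(components: VarianceComponents, level: str = "subject") -> float:
    """Intraclass correlation: the share of total variance at one stratum.

    For the subject level, ``ICC_P = sigma_P^2 / (sigma_P^2 + sigma_S^2 +
    sigma_e^2)`` — the correlation between two randomly chosen observations
    from the same subject.  Independence of all observations corresponds to
    ICC = 0.
    """
    total = components.total_variance
    if total <= 0:
        raise ValidationError("all variance components are zero; ICC undefined")
    if level == "subject":
        return components.sigma_subject**2 / total
    if level == "sample":
        if components.sigma_sample is None:
            raise ValidationError("model has no sample-level component")
        return (components.sigma_subject**2 + components.sigma_sample**2) / total
    raise ValidationError(f"unknown level {level!r}")


def lrt_random_structure(full: LMMFit, reduced: LMMFit):
    """Likelihood-ratio test between nested random-effect structures.

    Both fits must share the fixed effects and the estimation method (REML
    comparisons are valid here precisely because the fixed effects are
    identical).  Returns ``(lrt, df, p_chisq, p_boundary)`` where
    ``p_boundary`` uses the 50:50 mixture of chi-square(df-1) and
    chi-square(df) that accounts for the tested variance sitting on the
    boundary of its parameter space.
    """
    if full.method != reduced.method:
        raise ValidationError("fits use different estimation methods")
    if list(full.fixed_effects["term"]) != list(reduced.fixed_effects["term"]):
        raise ValidationError("fixed effects differ between fits; LRT invalid")
    n_full = len(full.levels)
    n_red = len(reduced.levels)
    if n_full < n_red:
        raise ValidationError("the reduced model must be nested in the full model")
    df = n_full - n_red
    lrt = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    if df == 0:
        return 0.0, 0, 1.0, 1.0
    p_chisq = float(stats.chi2.sf(lrt, df))
    if lrt == 0.0:
        p_boundary = 1.0
    else:
        lower = float(stats.chi2.sf(lrt, df - 1)) if df > 1 else 0.0
        p_boundary = 0.5 * lower + 0.5 * p_chisq
    return lrt, df, p_chisq, p_boundary


def diagnostics(fit: LMMFit):
    """Residual diagnostics as plain data series.

    Returns a dict with

    ``per_subject``
        boxplot statistics of the conditional residuals (observed − fitted)
        for each subject: median, quartiles, 1.5 IQR whiskers, outliers;
    ``qq``
        ordered residuals against theoretical Normal quantiles scaled by the
        fitted residual SD (plotting positions (i − 0.5)/n).
    """
    if not fit.converged:
        raise ValidationError("diagnostics require a converged fit")
    res = np.asarray(fit.residuals, dtype=float)
    subj = fit.subject_per_record
    rows = []
    for sid in sorted(set(subj), key=lambda s: (len(s), s)):
        r = np.sort(res[subj == sid])
        q1, med, q3 = np.percentile(r, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = r[(r >= lo_fence) & (r <= hi_fence)]
        rows.append(
            {
                "subject": sid,
                "n": len(r),
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": inside.min() if len(inside) else np.nan,
                "whisker_high": inside.max() if len(inside) else np.nan,
                "n_outliers": int(((r < lo_fence) | (r > hi_fence)).sum()),
            }
        )
    per_subject = pd.DataFrame(rows)
    n = len(res)
    probs = (np.arange(1, n + 1) - 0.5) / n
    qq = pd.DataFrame(
        {
            "observed": np.sort(res),
            "theoretical": stats.norm.ppf(probs) * fit.components.sigma_resid,
        }
    )
    return {"per_subject": per_subject, "qq": qq}
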