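"""Unified analysis reports and unit-of-analysis audits.

The report runner ties the analysis ladder together: it loads a dataset,
runs any requested subset of {naive t-test, subject-based t-test, nested
LMM, naive logistic GLM, logistic GLMM}, audits whether the requested
analysis level matches the level at which treatment was applied, and
renders the result as JSON or markdown with all numbers traceable to the
module outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np

from . import __version__, classical, glmm, lmm
from .datasets import NestedDataset, load_fixture, read_long_csv
from .errors import ValidationError

__all__ = ["AnalysisReport", "audit_units", "run_report", "render_json", "render_markdown"]

#: hierarchy strata, outermost first; "slice" is an alias for replicate
_STRATA = ("group", "subject", "sample", "replicate")
_ALIASES = {"slice": "replicate", "observation": "replicate", "record": "replicate"}


@dataclass
class AnalysisReport:
    """Structured output of :func:`run_report`."""

    dataset_summary: dict
    results: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def add_warning(self, message: str) -> None:
        self.warnings.append(message)


def audit_units(
    data: NestedDataset, treatment_level: str, analysis_level: str
) -> list[str]:
    """Warn when the analysis level sits below the treatment level.

    Treating observations from a stratum below the experimental unit as
    independent replicates (pseudoreplication) inflates the type I error
    rate; this audit flags exactly that mismatch and is silent otherwise.
    """
    t = _ALIASES.get(treatment_level, treatment_level)
    a = _ALIASES.get(analysis_level, analysis_level)
    for name in (t, a):
        if name not in _STRATA:
            raise ValidationError(f"unknown stratum {name!r}; known: {_STRATA}")
    warnings: list[str] = []
    if _STRATA.index(a) > _STRATA.index(t):
        warnings.append(
            f"unit-of-analysis mismatch: treatment applied at the {t!r} level "
            f"but analysis requested at the {a!r} level; observations below "
            f"the experimental unit are not independent replicates"
        )
    return warnings


def _dataset_summary(data: NestedDataset) -> dict:
    counts = data.strata_counts()
    return {
        "outcome_kind": data.outcome_kind,
        "n_records": data.n_records,
        "n_groups": counts["group"],
        "n_subjects": counts["subject"],
        "n_samples": counts["sample"],
        "balanced": data.is_balanced,
        "groups": data.groups,
    }


def _load(config: dict) -> NestedDataset:
    if "fixture" in config:
        return load_fixture(config["fixture"])
    if "data" in config:
        return read_long_csv(
            config["data"],
            schema=config.get("schema"),
            outcome_kind=config.get("outcome_kind", "continuous"),
            tsv=bool(config.get("tsv", False)),
        )
    raise ValidationError("config must provide either 'fixture' or 'data'")


def run_report(config: dict) -> AnalysisReport:
    """Run the analyses listed in ``config`` and assemble a report.

    Config keys: ``fixture`` or ``data`` (+ ``outcome_kind``, ``schema``,
    ``tsv``); ``analyses`` — a list drawn from ``naive_ttest``,
    ``subject_ttest``, ``lmm``, ``glm``, ``glmm``; optional ``conf_level``,
    ``reference``, ``n_quad``.  Each requested analysis appears exactly once
    in ``results``; an empty list yields the dataset summary alone.
    """
    data = _load(config)
    conf = float(config.get("conf_level", 0.95))
    reference = config.get("reference")
    report = AnalysisReport(dataset_summary=_dataset_summary(data))
    report.meta = {
        "package_version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()[:16],
    }
    analyses = list(config.get("analyses", []))
    if len(set(analyses)) != len(analyses):
        raise ValidationError("each analysis may be requested at most once")
    if not data.is_balanced and {"naive_ttest", "subject_ttest"} & set(analyses):
        report.add_warning(
            "design is unbalanced: subject summaries are based on unequal "
            "record counts"
        )
    for name in analyses:
        if name == "naive_ttest":
            report.warnings.extend(audit_units(data, "subject", "replicate"))
            df = data.frame
            res = classical.pooled_t_test(
                df["value"].to_numpy(), df["group"].to_numpy(), conf, reference
            )
            report.results[name] = _ttest_dict(res)
        elif name == "subject_ttest":
            res = classical.subject_based_t_test(data, conf, reference)
            report.results[name] = _ttest_dict(res)
        elif name == "lmm":
            levels = tuple(config.get("levels", ("subject", "sample")))
            fit = lmm.fit_nested_lmm(data, levels, conf_level=conf, reference=reference)
            report.results[name] = _lmm_dict(fit)
        elif name == "glm":
            res = classical.fit_logistic_glm(data, conf, reference)
            report.results[name] = {
                "group_order": list(res.group_order),
                "odds_ratio": res.odds_ratio,
                "log_or": res.log_or,
                "se_log_or": res.se_log_or,
                "ci": list(res.ci),
                "p": res.p,
                "deviance": res.deviance,
            }
            report.warnings.extend(audit_units(data, "subject", "sample"))
        elif name == "glmm":
            fit = glmm.fit_logistic_glmm(
                data, n_quad=int(config.get("n_quad", 1)), conf_level=conf,
                reference=reference,
            )
            report.results[name] = {
                "group_order": list(fit.group_order),
                "odds_ratio": fit.odds_ratio,
                "log_or": fit.log_or,
                "se_log_or": fit.se_log_or,
                "ci": fit.or_table[["ci_low", "ci_high"]].iloc[0].tolist(),
                "p": float(fit.coefficients["p"].iloc[1]),
                "sigma_subject": fit.sigma_subject,
                "loglik": fit.loglik,
                "n_quad": fit.n_quad,
                "predicted_probability": {
                    g: glmm.predict_probability(fit, g) for g in fit.group_order
                },
            }
        else:
            raise ValidationError(f"unknown analysis {name!r}")
    if {"glm", "glmm"} <= set(report.results):
        ratio = report.results["glmm"]["se_log_or"] / report.results["glm"]["se_log_or"]
        report.results["se_ratio_glmm_vs_glm"] = ratio
        if ratio > 1:
            report.add_warning(
                "naive logistic regression understates the log-odds-ratio "
                f"standard error by a factor of {ratio:.2f}"
            )
    return report


def _ttest_dict(res: classical.TTestResult) -> dict:
    return {
        "group_order": list(res.group_order),
        "means": dict(res.mean_per_group),
        "difference": res.difference,
        "sed": res.sed,
        "t": res.t,
        "df": res.df,
        "p": res.p,
        "ci": list(res.ci),
    }


def _lmm_dict(fit: lmm.LMMFit) -> dict:
    return {
        "method": fit.method,
        "levels": list(fit.levels),
        "fixed_effects": fit.fixed_effects.to_dict(orient="records"),
        "components": fit.components.as_dict(),
        "component_ci": {k: list(v) for k, v in fit.component_ci.items()},
        "icc_subject": lmm.icc(fit.components),
        "loglik": fit.loglik,
        "converged": fit.converged,
    }


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _round_floats(obj, sig: int):
    if isinstance(obj, float):
        if not math.isfinite(obj) or obj == 0.0:
            return obj
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), sig)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def render_json(report: AnalysisReport, sig_digits: int = 6) -> str:
    """Serialize a report to JSON with floats at ``sig_digits`` significant
    digits (round-trips through :func:`json.loads`)."""
    payload = _round_floats(asdict(report), sig_digits)
    return json.dumps(payload, indent=2, sort_keys=False)


def render_markdown(report: AnalysisReport, sig_digits: int = 6) -> str:
    payload = _round_floats(asdict(report), sig_digits)
    lines = ["# Analysis report", "", "## Dataset"]
    for k, v in payload["dataset_summary"].items():
        lines.append(f"- {k}: {v}")
    for name, res in payload["results"].items():
        lines.append("")
        lines.append(f"## {name}")
        if isinstance(res, dict):
            for k, v in res.items():
                lines.append(f"- {k}: {v}")
        else:
            lines.append(f"- value: {res}")
    if payload["warnings"]:
        lines.append("")
        lines.append("## Warnings")
        lines.extend(f"- {w}" for w in payload["warnings"])
    lines.append("")
    return "\n".join(lines)
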