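"""End-to-end MAIHDA orchestration: per sex, per outcome, Models 1 -> 3.

Model sequence:

* Model 1 (null): intercept + stratum random intercept.
* Model 2 (main effects): adds the five behaviour codes used to construct
  the strata (four binary guideline indicators; smoking as current/never
  dummies with previous smokers as the reference).
* Model 3 (adjusted): adds the confounders — age and TDI centred at their
  sex-specific post-exclusion means, non-white ethnicity and not-employed
  indicators.

The pipeline applies the exclusion cascade, assigns strata, centres
covariates per sex within the analysis set, fits the requested models with
the requested estimator, and computes VPC/PCV, stratum predictions,
interaction flags, ranked tables and collinearity diagnostics.  A report is
a pure function of (input table, configuration): serialization is
deterministic and carries a configuration hash for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .linear import fit_linear, linear_blups
from .logistic import fit_logistic, logistic_eb_intercepts
from .metrics import MaihdaSummary, predict_strata, rank_strata
from .prep import (
    CONFOUNDER_COLUMNS,
    apply_exclusions,
    collinearity_diagnostics,
    recode_behaviours,
)
from .strata import assign_strata, encode_strata_frame

logger = logging.getLogger("maihda")

OUTCOMES = ("bmi", "obesity", "overweight")
_CONTRAST = {
    "bmi": "bmi-linear",
    "obesity": "obesity-vs-normal",
    "overweight": "overweight-vs-normal",
}

BEHAVIOUR_TERMS = ("sleep_meets", "fv_meets", "alcohol_meets", "pa_meets",
                   "smoking_current", "smoking_never")
CONFOUNDER_TERMS = ("age_c", "tdi_c", "ethnicity_nonwhite", "not_employed")


class AnalysisConfigError(ValueError):
    """Invalid analysis configuration."""


@dataclass
class AnalysisConfig:
    input: str | Path | pd.DataFrame
    outcome: str = "bmi"
    sex: str = "both"
    models: tuple[int, ...] = (1, 2, 3)
    method: str = "reml"
    quadrature_order: int = 15
    outdir: str | Path | None = None
    seed: int = 0
    precision: dict = field(default_factory=lambda: {"bmi": 1, "probability": 2, "percent": 2})

    def validate(self) -> None:
        if self.outcome not in OUTCOMES:
            raise AnalysisConfigError(f"outcome must be one of {OUTCOMES}")
        if self.sex not in ("male", "female", "both"):
            raise AnalysisConfigError("sex must be 'male', 'female' or 'both'")
        if not self.models or any(m not in (1, 2, 3) for m in self.models):
            raise AnalysisConfigError("models must be a non-empty subset of {1, 2, 3}")
        if sorted(self.models) != list(self.models):
            raise AnalysisConfigError("models must be in increasing order")
        if self.method.lower() not in ("reml", "ml"):
            raise AnalysisConfigError("method must be 'reml' or 'ml'")
        if self.quadrature_order < 2:
            raise AnalysisConfigError("quadrature_order must be >= 2")

    def describe(self) -> dict:
        d = dataclasses.asdict(self)
        d["input"] = str(self.input) if not isinstance(self.input, pd.DataFrame) else "<in-memory frame>"
        d["outdir"] = str(self.outdir) if self.outdir is not None else None
        d["models"] = list(self.models)
        return d


def center_covariates(X: pd.DataFrame, columns) -> tuple[pd.DataFrame, dict[str, float]]:
    """Centre named numeric columns at their means; returns (X, centering means).

    Centering is computed on the given analysis set (the pipeline calls this
    per sex, after exclusions).
    """
    X = X.copy()
    means: dict[str, float] = {}
    for col in columns:
        if col not in X.columns:
            raise KeyError(f"cannot centre missing column {col!r}")
        mean = float(X[col].mean())
        X[col] = X[col] - mean
        means[col] = mean
    return X, means


def build_design(coded: pd.DataFrame, model: int) -> tuple[pd.DataFrame, dict[str, float]]:
    """Design matrix for one model of the sequence (records must be complete)."""
    n = len(coded)
    X = pd.DataFrame({"intercept": np.ones(n)}, index=coded.index)
    centering: dict[str, float] = {}
    if model >= 2:
        for col in ("sleep_meets", "fv_meets", "alcohol_meets", "pa_meets"):
            X[col] = coded[col].astype(float)
        X["smoking_current"] = (coded["smoking_code"] == 1).astype(float)
        X["smoking_never"] = (coded["smoking_code"] == 2).astype(float)
    if model >= 3:
        conf = pd.DataFrame({
            "age_c": coded["age"].astype(float),
            "tdi_c": coded["tdi"].astype(float),
        }, index=coded.index)
        conf, centering = center_covariates(conf, ["age_c", "tdi_c"])
        X["age_c"] = conf["age_c"]
        X["tdi_c"] = conf["tdi_c"]
        X["ethnicity_nonwhite"] = (coded["ethnicity"] == "non-white").astype(float)
        X["not_employed"] = (coded["employment"] == "not-employed-or-retired").astype(float)
    return X, centering


@dataclass
class MaihdaReport:
    config: dict
    config_hash: str
    version: str
    cells: dict[str, dict] = field(default_factory=dict)

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "config": self.config,
            "config_hash": self.config_hash,
            "version": self.version,
            "cells": self.cells,
        }
        return json.dumps(payload, indent=indent, sort_keys=True, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (pd.Series,)):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _load_table(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    return pd.read_csv(source)


def _ensure_coded(table: pd.DataFrame) -> pd.DataFrame:
    if "sleep_hours" in table.columns:
        return recode_behaviours(table)
    required = {"sleep_meets", "fv_meets", "alcohol_meets", "pa_meets", "smoking_code", "bmi"}
    missing = required - set(table.columns)
    if missing:
        raise AnalysisConfigError(f"input is neither raw nor coded: missing {sorted(missing)}")
    if "weight_status" not in table.columns:
        from .prep import _weight_status_vec
        table = table.copy()
        table["weight_status"] = _weight_status_vec(table["bmi"])
    return table


def run_maihda(config: AnalysisConfig) -> MaihdaReport:
    """Run the full analysis described by ``config`` and return the report.

    Each (sex, outcome) cell runs prep -> strata -> models -> metrics; a
    failure in one cell is recorded with its reason and other cells proceed.
    """
    config.validate()
    table = _load_table(config.input)
    if 3 in config.models:
        # confounder column names coincide in the raw and coded layouts, so
        # this validation runs before any recoding or fitting
        missing = [c for c in CONFOUNDER_COLUMNS if c not in table.columns]
        if missing:
            raise AnalysisConfigError(f"model 3 requires confounder columns; missing {missing}")
    coded_all = _ensure_coded(table)

    sexes = ("male", "female") if config.sex == "both" else (config.sex,)
    desc = config.describe()
    config_hash = hashlib.sha256(
        json.dumps(desc, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    report = MaihdaReport(config=desc, config_hash=config_hash, version=__version__)

    for sex in sexes:
        cell_key = f"{sex}:{config.outcome}"
        try:
            report.cells[cell_key] = _run_cell(coded_all, sex, config)
        except Exception as exc:  # noqa: BLE001 - cell isolation is the contract
            logger.error("cell %s failed: %s", cell_key, exc)
            report.cells[cell_key] = {"error": f"{type(exc).__name__}: {exc}"}

    if config.outdir is not None:
        write_outputs(report, config.outdir)
    return report


def _run_cell(coded_all: pd.DataFrame, sex: str, config: AnalysisConfig) -> dict:
    is_linear = config.outcome == "bmi"
    contrast = _CONTRAST[config.outcome]
    sub = coded_all[coded_all["sex"] == sex]
    if len(sub) == 0:
        raise ValueError(f"no records for sex {sex!r}")
    analysis, ledger = apply_exclusions(sub, contrast)
    analysis = analysis.copy()
    analysis["stratum"] = encode_strata_frame(analysis)
    index = assign_strata(analysis)
    groups = analysis["stratum"].to_numpy()

    if is_linear:
        y = analysis["bmi"].to_numpy(dtype=float)
    elif config.outcome == "obesity":
        y = (analysis["weight_status"] == "obese").to_numpy().astype(float)
    else:
        y = (analysis["weight_status"] == "overweight").to_numpy().astype(float)

    summary = MaihdaSummary(outcome_kind="linear" if is_linear else "logistic")
    cell: dict = {
        "sex": sex,
        "outcome": config.outcome,
        "contrast": contrast,
        "n_analysis": int(len(analysis)),
        "n_strata_nonempty": int(sum(1 for v in index.counts.values() if v > 0)),
        "exclusions": json.loads(ledger.to_json()),
        "models": {},
    }

    null_s2u = None
    for model in config.models:
        X, centering = build_design(analysis, model)
        if is_linear:
            fit = fit_linear(y, X, groups, method=config.method)
            intercepts = linear_blups(fit, y, X, groups)
            sigma2_e = fit.sigma2_e
        else:
            fit = fit_logistic(y, X, groups, quadrature_order=config.quadrature_order)
            intercepts = logistic_eb_intercepts(fit, y, X, groups)
            sigma2_e = None
        if fit.boundary:
            logger.warning("model %d (%s, %s): boundary estimate sigma2_u = 0",
                           model, sex, config.outcome)
        if model == 1:
            null_s2u = fit.sigma2_u
        # PCV is relative to the null model and undefined without one (or
        # when the null between-stratum variance sits on the zero boundary)
        reference = null_s2u if (model != 1 and null_s2u not in (None, 0.0)) else None
        summary.add_model(model, fit.sigma2_u, sigma2_e, reference)

        predictions = predict_strata(fit, y, X, index, intercepts)
        ranked, bottom, top = rank_strata(predictions, k=5)
        flagged = predictions.loc[predictions["interaction_flag"], "stratum"].tolist()
        if flagged:
            logger.warning("model %d (%s, %s): interaction flags for strata %s",
                           model, sex, config.outcome, flagged)
        cell["models"][str(model)] = {
            "fit": fit.to_dict(),
            "centering": centering,
            "predictions": predictions.to_dict(orient="list"),
            "ranked_bottom5": bottom["stratum"].tolist(),
            "ranked_top5": top["stratum"].tolist(),
            "interaction_flags": flagged,
        }

    cell["summary"] = summary.to_dict()
    max_model = max(config.models)
    if max_model >= 2:
        X_max, _ = build_design(analysis, max_model)
        diag = collinearity_diagnostics(X_max.drop(columns="intercept"))
        cell["collinearity"] = {
            "max_vif": diag.max_vif if np.isfinite(diag.max_vif) else "inf",
            "vif": {k: (v if np.isfinite(v) else "inf") for k, v in diag.vif.items()},
            "max_abs_correlation": float(
                diag.correlations.where(~np.eye(len(diag.correlations), dtype=bool)).abs().max().max()
            ),
            "exactly_collinear": diag.infinite,
        }
    return cell


def write_outputs(report: MaihdaReport, outdir) -> None:
    """Serialize the report bundle and per-cell CSV tables under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.to_json())
    for cell_key, cell in report.cells.items():
        if "error" in cell:
            continue
        tag = cell_key.replace(":", "_")
        coef_rows = []
        var_rows = []
        for model, payload in cell["models"].items():
            fit = payload["fit"]
            cov = np.asarray(fit["cov_beta"])
            for i, (term, est) in enumerate(fit["beta"].items()):
                se = float(np.sqrt(cov[i, i]))
                row = {"model": model, "term": term, "estimate": est,
                       "ci_lo": est - 1.96 * se, "ci_hi": est + 1.96 * se}
                if "odds_ratios" in fit:
                    orr = fit["odds_ratios"][term]
                    row |= {"OR": orr["or"], "OR_ci_lo": orr["ci_lo"], "OR_ci_hi": orr["ci_hi"]}
                coef_rows.append(row)
            summ = cell["summary"]["per_model"][model]
            var_rows.append({"model": model, **summ})
            pd.DataFrame(payload["predictions"]).to_csv(
                outdir / f"strata_{tag}_model{model}.csv", index=False,
                quoting=2,  # QUOTE_NONNUMERIC keeps the leading zeros of keys
            )
        pd.DataFrame(coef_rows).to_csv(outdir / f"coefficients_{tag}.csv", index=False)
        pd.DataFrame(var_rows).to_csv(outdir / f"variance_{tag}.csv", index=False)
        (outdir / f"exclusions_{tag}.json").write_text(json.dumps(cell["exclusions"], indent=2))


def render_report(bundle_path, fmt: str = "csv", outdir=None) -> str:
    """Render a serialized report bundle as CSV files or a markdown summary.

    Returns the markdown text (markdown mode) or the output directory used
    (csv mode, defaulting to the bundle's directory).
    """
    bundle_path = Path(bundle_path)
    payload = json.loads(bundle_path.read_text())
    report = MaihdaReport(
        config=payload["config"], config_hash=payload["config_hash"],
        version=payload["version"], cells=payload["cells"],
    )
    if fmt == "csv":
        outdir = Path(outdir) if outdir is not None else bundle_path.parent
        write_outputs(report, outdir)
        return str(outdir)
    if fmt != "markdown":
        raise ValueError("format must be 'csv' or 'markdown'")
    lines = [f"# MAIHDA report (config {report.config_hash})", ""]
    for cell_key, cell in report.cells.items():
        lines.append(f"## {cell_key}")
        if "error" in cell:
            lines += [f"FAILED: {cell['error']}", ""]
            continue
        lines.append(f"n = {cell['n_analysis']}, non-empty strata = {cell['n_strata_nonempty']}")
        lines += ["", "| model | sigma2_u | VPC % | PCV % |", "|---|---|---|---|"]
        for model, summ in cell["summary"]["per_model"].items():
            lines.append(
                f"| {model} | {summ['sigma2_u']:.4g} | {summ['vpc_pct']:.2f} | {summ['pcv_pct']:.2f} |"
            )
        last = str(max(int(m) for m in cell["models"]))
        payload_last = cell["models"][last]
        lines += ["", f"Model {last} lowest-5 strata: {', '.join(payload_last['ranked_bottom5'])}",
                  f"Model {last} highest-5 strata: {', '.join(payload_last['ranked_top5'])}",
                  f"Interaction flags: {payload_last['interaction_flags'] or 'none'}", ""]
    text = "\n".join(lines)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.md").write_text(text)
    return text
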