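"""MAIHDA variance decomposition and stratum-level prediction metrics.

* VPC (variance partition coefficient): share of total outcome variance
  attributable to between-stratum differences, in percent.  For logistic
  models the individual-level variance is not estimated; the latent-scale
  convention fixes it at the variance of the standard logistic distribution,
  pi^2/3 (~= 3.29).
* PCV (proportional change in variance): percentage *reduction* in
  between-stratum variance relative to the null model when fixed effects are
  added.  A negative value (variance increased) is possible and reported
  as-is.
* Stratum predictions: for every one of the 48 strata, the predicted outcome
  including and excluding the stratum random intercept, each with a 95% CI,
  alongside the observed stratum mean and an interaction flag raised when
  the two CIs are disjoint (strict comparison on unrounded values).

Prediction CIs are Wald intervals on the linear-predictor scale: the
excluding-RE interval uses the fixed-effect covariance at the stratum-mean
covariate row; the including-RE interval adds the posterior variance of the
random intercept (the covariance between fixed and random parts is ignored,
a documented approximation).  Logistic intervals are built on the logit
scale around the logit of the averaged member probability and then
inverse-linked, which keeps them inside [0, 1] and around the point
estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .linear import LinearFit
from .logistic import LogisticFit
from .strata import decode_stratum, enumerate_strata, StratumIndex

#: variance of the standard logistic distribution, pi^2 / 3
LATENT_LOGISTIC_VARIANCE = np.pi**2 / 3.0

_Z95 = 1.959963984540054

#: design columns directly determined by the stratum key (used to build
#: fixed-part rows for empty strata)
_STRATUM_DETERMINED = ("sleep_meets", "fv_meets", "alcohol_meets", "pa_meets",
                       "smoking_current", "smoking_never")


def compute_vpc(sigma2_u: float, sigma2_e: float | None = None) -> float:
    """VPC in percent: 100 * s2u / (s2u + s2_within).

    ``sigma2_e=None`` selects the logistic latent-scale convention, fixing
    the within component at pi^2/3.
    """
    if sigma2_u < 0:
        raise ValueError("sigma2_u must be >= 0")
    within = LATENT_LOGISTIC_VARIANCE if sigma2_e is None else float(sigma2_e)
    if within <= 0:
        raise ValueError("within-stratum variance component must be > 0")
    return 100.0 * sigma2_u / (sigma2_u + within)


def compute_pcv(sigma2_u_null: float, sigma2_u_model: float) -> float:
    """PCV in percent: 100 * (s2_null - s2_model) / s2_null.

    Positive values are reductions (fixed effects absorbing between-stratum
    variance); values cannot exceed 100; negative values mean the variance
    increased and are returned unchanged.
    """
    if sigma2_u_null <= 0:
        raise ValueError("null-model between-stratum variance must be > 0")
    if sigma2_u_model < 0:
        raise ValueError("sigma2_u_model must be >= 0")
    return 100.0 * (sigma2_u_null - sigma2_u_model) / sigma2_u_null


@dataclass
class MaihdaSummary:
    """Variance decomposition across the null / main-effects / adjusted sequence."""

    outcome_kind: str                     # "linear" | "logistic"
    per_model: dict[int, dict] = field(default_factory=dict)

    def add_model(self, model: int, sigma2_u: float, sigma2_e: float | None,
                  null_sigma2_u: float | None = None) -> None:
        vpc = compute_vpc(sigma2_u, sigma2_e if self.outcome_kind == "linear" else None)
        if null_sigma2_u is None:
            pcv = 0.0
        else:
            pcv = compute_pcv(null_sigma2_u, sigma2_u)
        self.per_model[model] = {
            "sigma2_u": float(sigma2_u),
            "sigma2_within": float(sigma2_e) if sigma2_e is not None else LATENT_LOGISTIC_VARIANCE,
            "vpc_pct": float(vpc),
            "pcv_pct": float(pcv),
            "variance_increased": bool(pcv < 0),
        }

    def to_dict(self) -> dict:
        return {"outcome_kind": self.outcome_kind,
                "per_model": {str(k): v for k, v in self.per_model.items()}}


def _stratum_design_rows(X: pd.DataFrame, index: StratumIndex) -> np.ndarray:
    """Mean covariate row per stratum; empty strata get behaviour columns from
    the decoded key and remaining columns at analysis-set column means."""
    cols = list(X.columns)
    Xv = X.to_numpy(dtype=float)
    col_means = Xv.mean(axis=0)
    keys = enumerate_strata()
    rows = np.empty((len(keys), len(cols)))
    for i, key in enumerate(keys):
        members = index.members[key]
        if len(members) > 0:
            rows[i] = Xv[members].mean(axis=0)
        else:
            row = col_means.copy()
            decoded = decode_stratum(key)
            for j, col in enumerate(cols):
                if col == "intercept":
                    row[j] = 1.0
                elif col in _STRATUM_DETERMINED:
                    if col == "smoking_current":
                        row[j] = 1.0 if decoded["smoking_code"] == 1 else 0.0
                    elif col == "smoking_never":
                        row[j] = 1.0 if decoded["smoking_code"] == 2 else 0.0
                    else:
                        row[j] = float(decoded[col])
            rows[i] = row
    return rows


def predict_strata(fit: LinearFit | LogisticFit, y, X: pd.DataFrame,
                   index: StratumIndex, intercepts: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum predictions with and without the random intercept.

    ``intercepts`` is the BLUP / EB frame from :func:`maihda.linear.linear_blups`
    or :func:`maihda.logistic.logistic_eb_intercepts` for the same fit.
    Returns one row per stratum key (all 48; empty strata flagged) with the
    observed stratum mean, predictions, CIs, random-intercept summary and the
    interaction flag from CI non-overlap.
    """
    if not isinstance(X, pd.DataFrame):
        raise TypeError("X must be a DataFrame with named design columns")
    y = np.asarray(y, dtype=float).ravel()
    if len(y) != len(X):
        raise ValueError("model/data mismatch: y and X differ in length")
    if index.n_total != len(y):
        raise ValueError("model/data mismatch: stratum index covers a different analysis set")
    is_logistic = isinstance(fit, LogisticFit)
    beta = fit.beta.to_numpy()
    cov_beta = fit.cov_beta.to_numpy()
    keys = enumerate_strata()
    u_map = intercepts.reindex(keys)
    u_hat = u_map["u_hat"].to_numpy(dtype=float)
    u_sd = u_map["post_sd"].to_numpy(dtype=float)
    sigma_u = np.sqrt(fit.sigma2_u)
    # strata absent from the fitted levels carry the prior
    missing = np.isnan(u_hat)
    u_hat[missing] = 0.0
    u_sd[missing] = sigma_u
    u_lo = u_map["ci_lo"].to_numpy(dtype=float)
    u_hi = u_map["ci_hi"].to_numpy(dtype=float)
    u_lo[missing] = -_Z95 * sigma_u
    u_hi[missing] = _Z95 * sigma_u

    xbar = _stratum_design_rows(X, index)
    se_fixed = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", xbar, cov_beta, xbar), 0.0))
    se_incl = np.sqrt(se_fixed**2 + u_sd**2)
    eta = X.to_numpy(dtype=float) @ beta

    n_arr = np.array([index.counts[k] for k in keys])
    observed = np.full(len(keys), np.nan)
    pred_excl = np.empty(len(keys))
    pred_incl = np.empty(len(keys))
    for i, key in enumerate(keys):
        members = index.members[key]
        if len(members) > 0:
            observed[i] = float(y[members].mean())
            eta_m = eta[members]
        else:
            eta_m = xbar[i] @ beta
        if is_logistic:
            pred_excl[i] = float(np.mean(expit(eta_m)))
            pred_incl[i] = float(np.mean(expit(eta_m + u_hat[i])))
        else:
            pred_excl[i] = float(np.mean(eta_m))
            pred_incl[i] = pred_excl[i] + u_hat[i]

    if is_logistic:
        eta_excl = logit(np.clip(pred_excl, 1e-12, 1 - 1e-12))
        eta_incl = logit(np.clip(pred_incl, 1e-12, 1 - 1e-12))
        excl_lo, excl_hi = expit(eta_excl - _Z95 * se_fixed), expit(eta_excl + _Z95 * se_fixed)
        incl_lo, incl_hi = expit(eta_incl - _Z95 * se_incl), expit(eta_incl + _Z95 * se_incl)
    else:
        excl_lo, excl_hi = pred_excl - _Z95 * se_fixed, pred_excl + _Z95 * se_fixed
        incl_lo, incl_hi = pred_incl - _Z95 * se_incl, pred_incl + _Z95 * se_incl

    out = pd.DataFrame(
        {
            "stratum": keys,
            "n": n_arr,
            "observed": observed,
            "pred_incl": pred_incl,
            "incl_lo": incl_lo,
            "incl_hi": incl_hi,
            "pred_excl": pred_excl,
            "excl_lo": excl_lo,
            "excl_hi": excl_hi,
            "u_hat": u_hat,
            "u_lo": u_lo,
            "u_hi": u_hi,
            "empty": n_arr == 0,
        }
    )
    out["interaction_flag"] = flag_interactions(out)
    return out


def flag_interactions(predictions: pd.DataFrame) -> pd.Series:
    """Multiplicative-effect flag: True iff the including-RE and excluding-RE
    95% CIs are strictly disjoint (compared on unrounded values)."""
    for lo, hi in (("incl_lo", "incl_hi"), ("excl_lo", "excl_hi")):
        if (predictions[lo] > predictions[hi]).any():
            raise ValueError(f"malformed interval: {lo} > {hi}")
    disjoint = (predictions["incl_lo"] > predictions["excl_hi"]) | (
        predictions["incl_hi"] < predictions["excl_lo"]
    )
    return disjoint.rename("interaction_flag")


def rank_strata(predictions: pd.DataFrame, k: int = 5,
                include_empty: bool = False) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Rank strata ascending by the including-RE prediction.

    Ties break by stratum key (lexicographic).  Returns ``(ordered table,
    bottom-k slice, top-k slice)``; ``k`` larger than the table truncates
    with a warning.  Empty strata are excluded from the ranking by default.
    """
    if len(predictions) == 0:
        raise ValueError("predictions are empty")
    table = predictions if include_empty else predictions[~predictions["empty"]]
    table = table.sort_values(["pred_incl", "stratum"], kind="mergesort").reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    if k > len(table):
        warnings.warn(f"k={k} exceeds the {len(table)} ranked strata; truncating")
        k = len(table)
    return table, table.head(k).copy(), table.tail(k).copy()
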