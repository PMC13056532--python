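"""Cohort preparation: guideline recoding, weight status, exclusions, descriptives.

The raw person-level table uses the following column names (the CSV dialect
written by :mod:`maihda.synthetic` and accepted by the pipeline):

========================  =====================================================
column                    meaning
========================  =====================================================
``sex``                   ``"male"`` / ``"female"``
``sleep_hours``           usual sleep duration, hours/day
``fv_portions``           fruit-and-vegetable intake, portions/day
``alcohol_units``         alcohol intake, units/week
``pa_moderate_min``       moderate-intensity physical activity, minutes/week
``pa_vigorous_min``       vigorous-intensity physical activity, minutes/week
``smoking``               ``"current"`` / ``"previous"`` / ``"never"``
``age``                   years
``tdi``                   Townsend Deprivation Index (more negative = less
                          deprived)
``ethnicity``             ``"white"`` / ``"non-white"``
``employment``            ``"employed"`` / ``"not-employed-or-retired"``
``bmi``                   body-mass index, kg/m^2
========================  =====================================================

Recoding follows UK public-health guidelines: sleep 7-9 h/day; at least 5
portions of fruit and vegetables per day; no more than 14 units of alcohol per
week; at least 150 min moderate OR 75 min vigorous physical activity per week.
Smoking is coded 0 = previous, 1 = current, 2 = never.  Missing raw values
propagate to missing codes; missingness is data, never an error here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .strata import DIGIT_COLUMNS

RAW_COLUMNS = (
    "sex",
    "sleep_hours",
    "fv_portions",
    "alcohol_units",
    "pa_moderate_min",
    "pa_vigorous_min",
    "smoking",
    "age",
    "tdi",
    "ethnicity",
    "employment",
    "bmi",
)

CONFOUNDER_COLUMNS = ("age", "tdi", "ethnicity", "employment")

# guideline thresholds
SLEEP_LO, SLEEP_HI = 7.0, 9.0          # hours/day, inclusive
FV_MIN = 5.0                           # portions/day
ALCOHOL_MAX = 14.0                     # units/week, inclusive ("no more than")
PA_MODERATE_MIN = 150.0                # minutes/week
PA_VIGOROUS_MIN = 75.0                 # minutes/week

SMOKING_CODE = {"previous": 0, "current": 1, "never": 2}

WEIGHT_STATUS_LEVELS = ("underweight", "normal", "overweight", "obese")

#: exclusion reasons in the order they are applied (first applicable wins)
EXCLUSION_ORDER = (
    "missing_lifestyle",
    "missing_confounders",
    "missing_bmi",
    "underweight",
    "outcome_contrast",
)

CONTRASTS = ("bmi-linear", "obesity-vs-normal", "overweight-vs-normal")


def classify_weight_status(bmi: float) -> str:
    """BMI category on half-open intervals.

    underweight [0, 18.5), normal [18.5, 25), overweight [25, 30),
    obese [30, inf).  The categories partition (0, inf) exactly; 30.0 is
    obese (WHO convention).
    """
    bmi = float(bmi)
    if not np.isfinite(bmi) or bmi <= 0:
        raise ValueError(f"BMI must be finite and positive, got {bmi!r}")
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def _weight_status_vec(bmi: pd.Series) -> pd.Series:
    """Vectorised weight status; missing BMI gives missing status."""
    values = pd.to_numeric(bmi, errors="coerce")
    bad = values.notna() & ((values <= 0) | ~np.isfinite(values))
    if bad.any():
        raise ValueError(f"BMI must be finite and positive; {int(bad.sum())} offending records")
    bins = [0.0, 18.5, 25.0, 30.0, np.inf]
    out = pd.cut(values, bins=bins, labels=WEIGHT_STATUS_LEVELS, right=False, include_lowest=True)
    return out.astype(object).where(values.notna(), np.nan)


def recode_behaviours(raw: pd.DataFrame) -> pd.DataFrame:
    """Recode raw lifestyle measures against the guidelines.

    Returns a coded frame with ``sleep_meets``/``fv_meets``/``alcohol_meets``/
    ``pa_meets`` in {0, 1}, ``smoking_code`` in {0, 1, 2} (float columns so a
    missing input yields NaN), the confounders and BMI carried through, and
    ``weight_status``.  Extra columns of ``raw`` (e.g. a simulated ``obese``
    indicator) are carried through unchanged.
    """
    raw = raw.reset_index(drop=True)

    def binary(cond: pd.Series, present: pd.Series) -> pd.Series:
        return cond.astype(float).where(present, np.nan)

    sleep = pd.to_numeric(raw["sleep_hours"], errors="coerce")
    fv = pd.to_numeric(raw["fv_portions"], errors="coerce")
    alcohol = pd.to_numeric(raw["alcohol_units"], errors="coerce")
    moderate = pd.to_numeric(raw["pa_moderate_min"], errors="coerce")
    vigorous = pd.to_numeric(raw["pa_vigorous_min"], errors="coerce")

    coded = pd.DataFrame({"sex": raw["sex"]})
    coded["sleep_meets"] = binary((sleep >= SLEEP_LO) & (sleep <= SLEEP_HI), sleep.notna())
    coded["fv_meets"] = binary(fv >= FV_MIN, fv.notna())
    coded["alcohol_meets"] = binary(alcohol <= ALCOHOL_MAX, alcohol.notna())
    # the two activity thresholds combine as a logical OR; either component
    # missing marks the code missing (complete-case convention)
    pa_known = moderate.notna() & vigorous.notna()
    pa_meets = (moderate >= PA_MODERATE_MIN) | (vigorous >= PA_VIGOROUS_MIN)
    coded["pa_meets"] = binary(pa_meets, pa_known)
    coded["smoking_code"] = raw["smoking"].map(SMOKING_CODE).astype(float)

    # absent confounder columns become all-missing (complete-case handling
    # downstream); lifestyle and BMI columns are mandatory
    for col in ("age", "tdi"):
        coded[col] = pd.to_numeric(raw[col], errors="coerce") if col in raw.columns else np.nan
    for col in ("ethnicity", "employment"):
        coded[col] = raw[col] if col in raw.columns else np.nan
    coded["bmi"] = pd.to_numeric(raw["bmi"], errors="coerce")
    coded["weight_status"] = _weight_status_vec(coded["bmi"])

    for col in raw.columns:
        if col not in RAW_COLUMNS:
            coded[col] = raw[col]
    return coded


@dataclass
class ExclusionLedger:
    """Accounting of the exclusion cascade; every input record appears exactly once."""

    input_total: int
    retained_total: int
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_excluded(self) -> int:
        return int(sum(self.counts.values()))

    def validate(self) -> None:
        if self.input_total != self.retained_total + self.total_excluded:
            raise ValueError(
                f"ledger does not balance: input {self.input_total} != "
                f"retained {self.retained_total} + excluded {self.total_excluded}"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "input_total": self.input_total,
                "retained_total": self.retained_total,
                "excluded_total": self.total_excluded,
                "counts": {k: int(self.counts.get(k, 0)) for k in EXCLUSION_ORDER},
            },
            indent=2,
            sort_keys=True,
        )


def apply_exclusions(coded: pd.DataFrame, contrast: str = "bmi-linear") -> tuple[pd.DataFrame, ExclusionLedger]:
    """Apply the exclusion cascade for one outcome contrast.

    Records are dropped, in order, for: missing lifestyle codes, missing
    confounders, missing BMI, underweight, and (for the binary contrasts)
    the weight-status category outside the contrast.  Each record is counted
    under the first applicable reason only.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    if len(coded) == 0:
        raise ValueError("apply_exclusions: empty input")

    n_input = len(coded)
    remaining = coded.reset_index(drop=True)
    counts: dict[str, int] = {}

    masks = {
        "missing_lifestyle": lambda df: df[list(DIGIT_COLUMNS)].isna().any(axis=1),
        "missing_confounders": lambda df: df[list(CONFOUNDER_COLUMNS)].isna().any(axis=1),
        "missing_bmi": lambda df: df["bmi"].isna(),
        "underweight": lambda df: df["weight_status"] == "underweight",
    }
    if contrast == "obesity-vs-normal":
        masks["outcome_contrast"] = lambda df: df["weight_status"] == "overweight"
    elif contrast == "overweight-vs-normal":
        masks["outcome_contrast"] = lambda df: df["weight_status"] == "obese"
    else:
        masks["outcome_contrast"] = lambda df: pd.Series(False, index=df.index)

    for reason in EXCLUSION_ORDER:
        drop = masks[reason](remaining)
        counts[reason] = int(drop.sum())
        remaining = remaining.loc[~drop].reset_index(drop=True)

    ledger = ExclusionLedger(input_total=n_input, retained_total=len(remaining), counts=counts)
    ledger.validate()
    return remaining, ledger


def percent(n: int, total: int, decimals: int = 1) -> float:
    """Table percentage: 100*n/total rounded to ``decimals`` (default 1)."""
    if total <= 0:
        raise ValueError("percentage denominator must be positive")
    return round(100.0 * n / total, decimals)


def descriptive_table(coded: pd.DataFrame) -> pd.DataFrame:
    """Descriptive summary per sex: N (%) per categorical level, mean (SD)
    for age and TDI, median (IQR) for BMI, N (%) per weight-status category.

    Returns a long frame with columns ``variable``, ``level``, ``statistic``,
    ``male``, ``female``.  Raises if either sex is absent.
    """
    if "weight_status" not in coded.columns:
        coded = coded.assign(weight_status=_weight_status_vec(coded["bmi"]))
    rows: list[dict] = []
    sexes = ("male", "female")
    groups = {}
    for sex in sexes:
        sub = coded[coded["sex"] == sex]
        if len(sub) == 0:
            raise ValueError(f"descriptive_table: no records for sex {sex!r}")
        groups[sex] = sub

    def add(variable, level, statistic, fmt):
        rows.append(
            {"variable": variable, "level": level, "statistic": statistic}
            | {sex: fmt(groups[sex]) for sex in sexes}
        )

    add("sample", "", "N", lambda g: len(g))

    categorical = [
        ("smoking", "smoking_code", {0.0: "previous", 1.0: "current", 2.0: "never"}),
        ("fruit_veg", "fv_meets", {0.0: "not-meets", 1.0: "meets"}),
        ("physical_activity", "pa_meets", {0.0: "not-meets", 1.0: "meets"}),
        ("alcohol", "alcohol_meets", {0.0: "not-meets", 1.0: "meets"}),
        ("sleep", "sleep_meets", {0.0: "not-meets", 1.0: "meets"}),
        ("ethnicity", "ethnicity", {"white": "white", "non-white": "non-white"}),
        ("employment", "employment", {"employed": "employed", "not-employed-or-retired": "not-employed-or-retired"}),
        ("weight_status", "weight_status", {s: s for s in WEIGHT_STATUS_LEVELS}),
    ]
    for variable, col, levels in categorical:
        for value, label in levels.items():
            add(variable, label, "N", lambda g, c=col, v=value: int((g[c] == v).sum()))
            add(variable, label, "%", lambda g, c=col, v=value: percent(int((g[c] == v).sum()), int(g[c].notna().sum())))

    for variable in ("age", "tdi"):
        add(variable, "", "mean", lambda g, c=variable: round(float(g[c].mean()), 1))
        add(variable, "", "SD", lambda g, c=variable: round(float(g[c].std(ddof=1)), 1))
    add("bmi", "", "median", lambda g: round(float(g["bmi"].median()), 1))
    add("bmi", "", "IQR_low", lambda g: round(float(g["bmi"].quantile(0.25)), 1))
    add("bmi", "", "IQR_high", lambda g: round(float(g["bmi"].quantile(0.75)), 1))

    return pd.DataFrame(rows, columns=["variable", "level", "statistic", "male", "female"])


@dataclass
class CollinearityDiagnostics:
    correlations: pd.DataFrame
    vif: pd.Series
    max_vif: float
    infinite: list[str]


def collinearity_diagnostics(X: pd.DataFrame) -> CollinearityDiagnostics:
    """Pairwise correlations and variance inflation factors for a predictor matrix.

    ``X`` holds the predictors without an intercept column (an intercept is
    included in each auxiliary regression).  VIF_k = 1/(1 - R^2_k) with R^2_k
    from regressing predictor k on the others; an exactly collinear predictor
    is reported as infinite and flagged.
    """
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValueError("collinearity diagnostics need at least 2 predictors")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more observations than predictors")
    values = X.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("predictor matrix contains missing or non-finite values")

    corr = X.corr()
    n, p = values.shape
    ones = np.ones((n, 1))
    vifs = {}
    infinite = []
    for k, name in enumerate(X.columns):
        yk = values[:, k]
        others = np.delete(values, k, axis=1)
        A = np.hstack([ones, others])
        coef, *_ = np.linalg.lstsq(A, yk, rcond=None)
        resid = yk - A @ coef
        sst = float(np.sum((yk - yk.mean()) ** 2))
        if sst == 0.0:
            raise ValueError(f"predictor {name!r} is constant")
        r2 = 1.0 - float(resid @ resid) / sst
        if 1.0 - r2 < 1e-12:
            vifs[name] = np.inf
            infinite.append(name)
        else:
            vifs[name] = 1.0 / (1.0 - r2)
    vif = pd.Series(vifs, name="VIF")
    return CollinearityDiagnostics(
        correlations=corr, vif=vif, max_vif=float(vif.max()), infinite=infinite
    )
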