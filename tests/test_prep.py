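"""Guideline recoding, weight status, exclusion cascade, descriptives, collinearity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from maihda.prep import (
    CollinearityDiagnostics,
    apply_exclusions,
    classify_weight_status,
    collinearity_diagnostics,
    descriptive_table,
    percent,
    recode_behaviours,
)


def _raw_row(**overrides):
    row = {
        "sex": "male", "sleep_hours": 8.0, "fv_portions": 6.0, "alcohol_units": 10.0,
        "pa_moderate_min": 200.0, "pa_vigorous_min": 0.0, "smoking": "never",
        "age": 55.0, "tdi": -1.5, "ethnicity": "white", "employment": "employed",
        "bmi": 24.0,
    }
    row.update(overrides)
    return row


def _recode_one(**overrides) -> pd.Series:
    return recode_behaviours(pd.DataFrame([_raw_row(**overrides)])).iloc[0]


@pytest.mark.parametrize(
    "field,value,code_col,expected",
    [
        ("sleep_hours", 8.0, "sleep_meets", 1),
        ("sleep_hours", 7.0, "sleep_meets", 1),     # 7-9 h inclusive
        ("sleep_hours", 9.0, "sleep_meets", 1),
        ("sleep_hours", 6.9, "sleep_meets", 0),
        ("sleep_hours", 9.1, "sleep_meets", 0),
        ("fv_portions", 5.0, "fv_meets", 1),        # at least 5 portions
        ("fv_portions", 4.9, "fv_meets", 0),
        ("alcohol_units", 14.0, "alcohol_meets", 1),  # "no more than 14" is inclusive
        ("alcohol_units", 14.1, "alcohol_meets", 0),
        ("alcohol_units", 0.0, "alcohol_meets", 1),
        ("smoking", "current", "smoking_code", 1),
        ("smoking", "previous", "smoking_code", 0),
        ("smoking", "never", "smoking_code", 2),
    ],
)
def test_recoding_thresholds(field, value, code_col, expected):
    assert _recode_one(**{field: value})[code_col] == expected


@pytest.mark.parametrize(
    "moderate,vigorous,expected",
    [
        (150.0, 0.0, 1),   # moderate threshold alone
        (0.0, 75.0, 1),    # vigorous threshold alone
        (149.9, 74.9, 0),  # neither (no combined-equivalence scoring)
        (300.0, 100.0, 1),
    ],
)
def test_physical_activity_is_or_of_two_thresholds(moderate, vigorous, expected):
    row = _recode_one(pa_moderate_min=moderate, pa_vigorous_min=vigorous)
    assert row["pa_meets"] == expected


def test_missing_raw_values_propagate_to_missing_codes():
    row = _recode_one(sleep_hours=np.nan, smoking=np.nan, pa_vigorous_min=np.nan)
    assert np.isnan(row["sleep_meets"])
    assert np.isnan(row["smoking_code"])
    assert np.isnan(row["pa_meets"])
    assert row["fv_meets"] == 1  # untouched fields still coded


@pytest.mark.parametrize(
    "bmi,expected",
    [
        (17.0, "underweight"),
        (18.5, "normal"),
        (24.9, "normal"),
        (25.0, "overweight"),
        (29.9, "overweight"),
        (30.0, "obese"),     # boundary belongs to obesity
        (45.0, "obese"),
    ],
)
def test_weight_status_categories(bmi, expected):
    assert classify_weight_status(bmi) == expected


def test_weight_status_partitions_the_positive_axis():
    # brute force over a 0.1-step grid: total, mutually-exclusive classification
    order = {"underweight": 0, "normal": 1, "overweight": 2, "obese": 3}
    grid = np.round(np.arange(0.1, 80.0, 0.1), 10)
    statuses = [classify_weight_status(b) for b in grid]
    assert all(s in order for s in statuses)
    assert sorted(set(statuses), key=order.get) == list(order)
    # monotone: category index never decreases along the grid
    indices = [order[s] for s in statuses]
    assert all(a <= b for a, b in zip(indices, indices[1:]))


@pytest.mark.parametrize("bad", [0.0, -3.0, np.nan, np.inf])
def test_weight_status_rejects_nonpositive_or_nonfinite(bad):
    with pytest.raises(ValueError):
        classify_weight_status(bad)


def test_exclusion_cascade_on_constructed_fixture():
    rows = [
        _raw_row(alcohol_units=np.nan),   # missing lifestyle
        _raw_row(tdi=np.nan),             # missing confounder
        _raw_row(bmi=np.nan),             # missing BMI
        _raw_row(bmi=17.0),               # underweight
        _raw_row(),                       # complete, normal weight
    ]
    coded = recode_behaviours(pd.DataFrame(rows))
    analysis, ledger = apply_exclusions(coded, "bmi-linear")
    assert len(analysis) == 1
    assert [ledger.counts[r] for r in ("missing_lifestyle", "missing_confounders",
                                       "missing_bmi", "underweight", "outcome_contrast")] == [1, 1, 1, 1, 0]
    ledger.validate()


def test_exclusion_precedence_counts_first_applicable_reason_only():
    # a record missing both lifestyle and BMI is counted under lifestyle
    coded = recode_behaviours(pd.DataFrame([_raw_row(alcohol_units=np.nan, bmi=np.nan), _raw_row()]))
    _, ledger = apply_exclusions(coded, "bmi-linear")
    assert ledger.counts["missing_lifestyle"] == 1
    assert ledger.counts["missing_bmi"] == 0


def test_binary_contrasts_drop_the_out_of_contrast_category():
    coded = recode_behaviours(pd.DataFrame(
        [_raw_row(bmi=22.0), _raw_row(bmi=27.0), _raw_row(bmi=33.0)]
    ))
    obesity, ledger_o = apply_exclusions(coded, "obesity-vs-normal")
    assert sorted(obesity["weight_status"]) == ["normal", "obese"]
    assert ledger_o.counts["outcome_contrast"] == 1
    overweight, ledger_w = apply_exclusions(coded, "overweight-vs-normal")
    assert sorted(overweight["weight_status"]) == ["normal", "overweight"]
    assert ledger_w.counts["outcome_contrast"] == 1


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_ledger_conservation_under_random_missingness(seed):
    rng = np.random.default_rng(seed)
    n = 60
    frame = pd.DataFrame([_raw_row(bmi=float(b)) for b in rng.uniform(16, 45, n)])
    for col in ("sleep_hours", "tdi", "bmi"):
        frame.loc[rng.random(n) < 0.25, col] = np.nan
    coded = recode_behaviours(frame)
    analysis, ledger = apply_exclusions(coded, "obesity-vs-normal")
    ledger.validate()
    assert ledger.input_total == n
    assert ledger.retained_total == len(analysis)
    # permuting the input never changes the counts
    perm = frame.sample(frac=1.0, random_state=1)
    _, ledger2 = apply_exclusions(recode_behaviours(perm), "obesity-vs-normal")
    assert ledger2.counts == ledger.counts


def test_empty_input_is_an_error():
    with pytest.raises(ValueError):
        apply_exclusions(recode_behaviours(pd.DataFrame([_raw_row()])).iloc[:0], "bmi-linear")


def test_descriptive_table_matches_independent_recomputation(small_cohort):
    records, _ = small_cohort
    table = descriptive_table(records)
    male = records[records["sex"] == "male"]
    never = table[(table["variable"] == "smoking") & (table["level"] == "never")]
    n_never = int((male["smoking_code"] == 2).sum())
    assert never[never["statistic"] == "N"]["male"].iloc[0] == n_never
    assert never[never["statistic"] == "%"]["male"].iloc[0] == percent(n_never, len(male))
    med = table[(table["variable"] == "bmi") & (table["statistic"] == "median")]["male"].iloc[0]
    assert med == round(float(male["bmi"].median()), 1)


def test_descriptive_percentages_sum_to_100(small_cohort):
    records, _ = small_cohort
    table = descriptive_table(records)
    pct = table[table["statistic"] == "%"]
    for variable, group in pct.groupby("variable"):
        for sex in ("male", "female"):
            assert abs(group[sex].sum() - 100.0) <= 0.1, (variable, sex)


def test_descriptive_table_requires_both_sexes(small_cohort):
    records, _ = small_cohort
    with pytest.raises(ValueError, match="female"):
        descriptive_table(records[records["sex"] == "male"])


def test_vif_is_one_for_orthogonal_predictors():
    # exactly mean-centred, mutually orthogonal contrast columns
    block = np.array([
        [1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1],
    ], dtype=float)
    X = pd.DataFrame(np.tile(block, (100, 1)), columns=list("abc"))
    diag = collinearity_diagnostics(X)
    assert isinstance(diag, CollinearityDiagnostics)
    assert np.allclose(diag.vif, 1.0, atol=1e-8)


def test_vif_closed_form_for_correlated_pair():
    rng = np.random.default_rng(1)
    n = 2000
    x1 = rng.normal(size=n)
    x2 = 0.6 * x1 + rng.normal(size=n)
    X = pd.DataFrame({"x1": x1, "x2": x2})
    diag = collinearity_diagnostics(X)
    r = float(np.corrcoef(x1, x2)[0, 1])
    expected = 1.0 / (1.0 - r * r)
    assert np.allclose(diag.vif, expected, rtol=1e-10)
    assert diag.max_vif == pytest.approx(expected)


def test_duplicated_column_is_flagged_infinite():
    rng = np.random.default_rng(2)
    x = rng.normal(size=100)
    X = pd.DataFrame({"x": x, "x_copy": x, "z": rng.normal(size=100)})
    diag = collinearity_diagnostics(X)
    assert diag.infinite == ["x", "x_copy"]
    assert np.isinf(diag.max_vif)
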