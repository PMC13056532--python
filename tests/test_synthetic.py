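"""Synthetic cohort generator: determinism, calibration, round-trip, ground truth."""

import math

import numpy as np
import pandas as pd
import pytest

from maihda import (
    SyntheticConfig,
    compute_vpc,
    emit_raw_questionnaire,
    fit_linear,
    generate_cohort,
    inject_stratum_interaction,
    recode_behaviours,
)
from maihda.pipeline import build_design
from maihda.strata import DIGIT_COLUMNS, StratumKeyError, encode_strata_frame
from maihda.synthetic import SyntheticConfigError

ZERO_EFFECTS = {
    sex: {k: 0.0 for k in ("sleep_meets", "fv_meets", "alcohol_meets", "pa_meets",
                           "smoking_current", "smoking_never")}
    for sex in ("male", "female")
}


def test_same_config_and_seed_give_identical_cohorts():
    cfg = SyntheticConfig(n_per_sex=500, seed=42)
    rec1, truth1 = generate_cohort(cfg)
    rec2, truth2 = generate_cohort(cfg)
    pd.testing.assert_frame_equal(rec1, rec2)
    assert truth1.stratum_offsets == truth2.stratum_offsets
    assert truth1.implied_between_stratum_variance == truth2.implied_between_stratum_variance


def test_different_seed_changes_the_cohort():
    rec1, _ = generate_cohort(SyntheticConfig(n_per_sex=200, seed=1))
    rec2, _ = generate_cohort(SyntheticConfig(n_per_sex=200, seed=2))
    assert not rec1["bmi"].equals(rec2["bmi"])


@pytest.mark.parametrize(
    "overrides,match",
    [
        ({"n_per_sex": 0}, "n_per_sex"),
        ({"residual_sd_bmi": 0.0}, "residual_sd_bmi"),
        ({"extra_stratum_sd": -1.0}, "extra_stratum_sd"),
        ({"behaviour_prevalences": {"male": {"fv_meets": 1.2}}}, "fv_meets"),
        ({"behaviour_prevalences": {"male": {"smoking": {"never": 0.9}}}}, "smoking"),
        ({"obesity_rule": "coin-flip"}, "obesity_rule"),
    ],
)
def test_invalid_configuration_errors_name_the_field(overrides, match):
    with pytest.raises(SyntheticConfigError, match=match):
        SyntheticConfig.from_dict(overrides).validate()


def test_inject_interaction_returns_new_config_only():
    cfg = SyntheticConfig(n_per_sex=100, seed=0)
    cfg2 = inject_stratum_interaction(cfg, "11112", 2.0)
    assert cfg.interaction_offsets == {}
    assert cfg2.interaction_offsets == {"11112": 2.0}
    assert cfg2.n_per_sex == cfg.n_per_sex


def test_inject_zero_offset_leaves_cohort_unchanged_under_same_seed():
    cfg = SyntheticConfig(n_per_sex=300, seed=5)
    rec1, _ = generate_cohort(cfg)
    rec2, _ = generate_cohort(inject_stratum_interaction(cfg, "01112", 0.0))
    pd.testing.assert_frame_equal(rec1, rec2)


def test_inject_invalid_key_raises():
    with pytest.raises(StratumKeyError):
        inject_stratum_interaction(SyntheticConfig(), "99999", 1.0)


def test_injected_offset_shifts_only_the_target_stratum():
    cfg = SyntheticConfig(n_per_sex=20_000, seed=9)
    rec0, _ = generate_cohort(cfg)
    rec1, truth1 = generate_cohort(inject_stratum_interaction(cfg, "11112", 2.0))
    assert truth1.stratum_offsets["male"]["11112"] == pytest.approx(2.0)
    target = rec0["stratum"] == "11112"
    shift = rec1.loc[target, "bmi"].to_numpy() - rec0.loc[target, "bmi"].to_numpy()
    assert np.allclose(shift, 2.0)
    other = rec0["stratum"] != "11112"
    assert np.allclose(rec1.loc[other, "bmi"], rec0.loc[other, "bmi"])


def test_emitted_raw_measures_lie_in_code_consistent_ranges(small_cohort):
    records, _ = small_cohort
    raw = emit_raw_questionnaire(records)
    meets_sleep = records["sleep_meets"] == 1
    assert raw.loc[meets_sleep, "sleep_hours"].between(7, 9).all()
    assert ~raw.loc[~meets_sleep, "sleep_hours"].between(7, 9).any()
    meets_alc = records["alcohol_meets"] == 1
    assert (raw.loc[meets_alc, "alcohol_units"] <= 14).all()
    assert (raw.loc[~meets_alc, "alcohol_units"] > 14).all()
    meets_fv = records["fv_meets"] == 1
    assert (raw.loc[meets_fv, "fv_portions"] >= 5).all()
    pa = (raw["pa_moderate_min"] >= 150) | (raw["pa_vigorous_min"] >= 75)
    assert (pa == (records["pa_meets"] == 1)).all()


def test_recoding_round_trip_reproduces_generated_codes():
    for seed in (0, 7):
        records, _ = generate_cohort(SyntheticConfig(n_per_sex=2000, seed=seed))
        coded = recode_behaviours(emit_raw_questionnaire(records))
        for col in DIGIT_COLUMNS:
            assert (coded[col].to_numpy() == records[col].to_numpy()).all(), col
        assert (encode_strata_frame(coded) == records["stratum"]).all()


def test_additive_model_reproduces_linear_predictor_exactly():
    # near-zero residual noise exposes the linear predictor directly
    cfg = SyntheticConfig(n_per_sex=3000, seed=3, residual_sd_bmi=1e-9)
    records, truth = generate_cohort(cfg)
    assert all(v == 0.0 for sex in ("male", "female") for v in truth.stratum_offsets[sex].values())
    for sex in ("male", "female"):
        sub = records[records["sex"] == sex]
        eff = truth.fixed_effects_bmi[sex]
        expected = (
            truth.intercept_bmi[sex]
            + eff["sleep_meets"] * sub["sleep_meets"]
            + eff["fv_meets"] * sub["fv_meets"]
            + eff["alcohol_meets"] * sub["alcohol_meets"]
            + eff["pa_meets"] * sub["pa_meets"]
            + eff["smoking_current"] * (sub["smoking_code"] == 1)
            + eff["smoking_never"] * (sub["smoking_code"] == 2)
        )
        assert np.allclose(sub["bmi"], expected, atol=1e-6)


def test_marginal_calibration_within_three_binomial_ses():
    records, _ = generate_cohort(SyntheticConfig(n_per_sex=100_000, seed=13))
    from maihda.synthetic import DEFAULT_PREVALENCES
    n = 100_000
    for sex in ("male", "female"):
        sub = records[records["sex"] == sex]
        prev = DEFAULT_PREVALENCES[sex]
        checks = {
            "sleep_meets": (sub["sleep_meets"] == 1).mean(),
            "fv_meets": (sub["fv_meets"] == 1).mean(),
            "alcohol_meets": (sub["alcohol_meets"] == 1).mean(),
            "pa_meets": (sub["pa_meets"] == 1).mean(),
        }
        for key, observed in checks.items():
            p = prev[key]
            se = math.sqrt(p * (1 - p) / n)
            assert abs(observed - p) <= 3 * se, (sex, key)
        for level, code in (("previous", 0), ("current", 1), ("never", 2)):
            p = prev["smoking"][level]
            se = math.sqrt(p * (1 - p) / n)
            assert abs((sub["smoking_code"] == code).mean() - p) <= 3 * se, (sex, level)


def test_no_true_stratum_variance_yields_negligible_null_vpc():
    # all behaviour effects zero, no latent deviation: the null model should
    # find (numerically) no between-stratum variance
    cfg = SyntheticConfig(n_per_sex=50_000, seed=17, behaviour_effects_bmi=ZERO_EFFECTS)
    records, _ = generate_cohort(cfg)
    male = records[records["sex"] == "male"]
    fit = fit_linear(male["bmi"], build_design(male, 1)[0], encode_strata_frame(male))
    assert compute_vpc(fit.sigma2_u, fit.sigma2_e) < 0.5


def test_independent_logit_rule_draws_obesity_from_latent_model():
    cfg = SyntheticConfig(n_per_sex=50_000, seed=23, obesity_rule="independent-logit",
                          logit_stratum_sd=0.0)
    records, truth = generate_cohort(cfg)
    assert truth.obesity_rule == "independent-logit"
    male = records[records["sex"] == "male"]
    expected = 1.0 / (1.0 + math.exp(-truth.logit_intercept["male"]))
    assert male["obese"].mean() == pytest.approx(expected, abs=0.01)
    # under the default threshold rule obesity is exactly BMI >= 30
    rec_thr, _ = generate_cohort(SyntheticConfig(n_per_sex=1000, seed=23))
    assert ((rec_thr["bmi"] >= 30).astype(int) == rec_thr["obese"]).all()
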