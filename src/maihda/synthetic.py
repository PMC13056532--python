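"""Synthetic cohort generator with known ground truth.

Emulates the structure of a sex-stratified adult cohort in which five coded
lifestyle behaviours (sleep, fruit & vegetables, alcohol, physical activity,
smoking) define 48 strata, BMI is generated additively from guideline
adherence plus an optional latent stratum-level deviation, and obesity status
is derived either by thresholding BMI at 30 kg/m^2 or from an independent
random-intercept logit model on the latent scale.

Defaults reproduce published descriptive marginals (behaviour prevalences,
age/TDI moments, ethnicity and employment proportions) and the
confounder-adjusted additive behaviour effects on BMI of a large UK cohort,
with a residual SD of sqrt(15.15) kg/m^2.  Behaviours are sampled
independently across variables; raw questionnaire measures are drawn
uniformly within the range consistent with each drawn code, so recoding the
emitted raw table reproduces the generated codes exactly.

All randomness flows from a single integer seed through one
``numpy.random.default_rng`` stream with a fixed draw order (per sex: the
five behaviour codes, raw measures, confounders, stratum latent offsets,
residual BMI noise, then any latent-logit draws).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import prep
from .strata import enumerate_strata, is_valid_key, StratumKeyError

SEXES = ("male", "female")
BEHAVIOUR_KEYS = ("sleep_meets", "fv_meets", "alcohol_meets", "pa_meets")
EFFECT_KEYS = BEHAVIOUR_KEYS + ("smoking_current", "smoking_never")

#: per-sex behaviour prevalences (proportions of the descriptive sample)
DEFAULT_PREVALENCES: dict[str, dict] = {
    "male": {
        "sleep_meets": 0.755,
        "fv_meets": 0.272,
        "alcohol_meets": 0.249,
        "pa_meets": 0.821,
        "smoking": {"previous": 0.405, "current": 0.112, "never": 0.483},
    },
    "female": {
        "sleep_meets": 0.771,
        "fv_meets": 0.385,
        "alcohol_meets": 0.479,
        "pa_meets": 0.832,
        "smoking": {"previous": 0.355, "current": 0.080, "never": 0.565},
    },
}

#: per-sex additive BMI shifts (kg/m^2) per behaviour level, reference =
#: not-meets / previous smoker (confounder-adjusted main effects)
DEFAULT_EFFECTS_BMI: dict[str, dict[str, float]] = {
    "male": {
        "sleep_meets": -0.64,
        "fv_meets": 0.10,
        "alcohol_meets": -0.31,
        "pa_meets": -1.08,
        "smoking_current": -0.93,
        "smoking_never": -0.99,
    },
    "female": {
        "sleep_meets": -0.56,
        "fv_meets": -0.39,
        "alcohol_meets": 0.17,
        "pa_meets": -1.50,
        "smoking_current": -0.50,
        "smoking_never": -0.44,
    },
}

DEFAULT_INTERCEPT_BMI = {"male": 29.82, "female": 28.60}

DEFAULT_CONFOUNDERS: dict[str, dict[str, float]] = {
    "male": {"age_mean": 56.7, "age_sd": 8.0, "tdi_mean": -1.6, "tdi_sd": 2.9,
             "p_nonwhite": 0.067, "p_not_employed": 0.369},
    "female": {"age_mean": 55.7, "age_sd": 7.9, "tdi_mean": -1.7, "tdi_sd": 2.7,
               "p_nonwhite": 0.076, "p_not_employed": 0.399},
}

#: BMI shift per unit of each (centred) confounder; zero by default
DEFAULT_CONFOUNDER_EFFECTS = {"age": 0.0, "tdi": 0.0, "nonwhite": 0.0, "not_employed": 0.0}

DEFAULT_RESIDUAL_SD = math.sqrt(15.15)

#: latent-logit obesity defaults (grand-mean log odds of obesity vs normal weight)
DEFAULT_LOGIT_INTERCEPT = {"male": math.log(1.11), "female": math.log(0.51)}

OBESITY_RULES = ("bmi-threshold", "independent-logit")


class SyntheticConfigError(ValueError):
    """Raised when a synthetic-cohort configuration is invalid."""


def _deep_update(base: dict, overrides: Mapping | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (overrides or {}).items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters for one synthetic cohort.

    ``extra_stratum_sd`` is the SD (kg/m^2) of a latent per-stratum BMI
    deviation beyond the additive behaviour effects; with the default 0 and no
    ``interaction_offsets`` the generative model is purely additive in the
    behaviour codes.  ``interaction_offsets`` maps stratum keys to additional
    BMI offsets (kg/m^2).  Under ``obesity_rule="independent-logit"`` obesity
    is drawn from logit(pi_j) = logit_intercept + logit effects + u_j with
    u_j ~ N(0, logit_stratum_sd^2) on the latent scale, independent of BMI.
    """

    n_per_sex: int = 10_000
    behaviour_prevalences: dict = field(default_factory=lambda: _deep_update(DEFAULT_PREVALENCES, None))
    behaviour_effects_bmi: dict = field(default_factory=lambda: _deep_update(DEFAULT_EFFECTS_BMI, None))
    confounder_distributions: dict = field(default_factory=lambda: _deep_update(DEFAULT_CONFOUNDERS, None))
    confounder_effects_bmi: dict = field(default_factory=lambda: dict(DEFAULT_CONFOUNDER_EFFECTS))
    intercept_bmi: dict = field(default_factory=lambda: dict(DEFAULT_INTERCEPT_BMI))
    residual_sd_bmi: float = DEFAULT_RESIDUAL_SD
    extra_stratum_sd: float = 0.0
    interaction_offsets: dict = field(default_factory=dict)
    obesity_rule: str = "bmi-threshold"
    logit_intercept: dict = field(default_factory=lambda: dict(DEFAULT_LOGIT_INTERCEPT))
    logit_effects: dict = field(default_factory=lambda: {sex: {k: 0.0 for k in EFFECT_KEYS} for sex in SEXES})
    logit_stratum_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_sex < 1:
            raise SyntheticConfigError("n_per_sex must be >= 1")
        if not (self.residual_sd_bmi > 0):
            raise SyntheticConfigError("residual_sd_bmi must be > 0")
        if self.extra_stratum_sd < 0:
            raise SyntheticConfigError("extra_stratum_sd must be >= 0")
        if self.logit_stratum_sd < 0:
            raise SyntheticConfigError("logit_stratum_sd must be >= 0")
        if self.obesity_rule not in OBESITY_RULES:
            raise SyntheticConfigError(f"obesity_rule must be one of {OBESITY_RULES}")
        for sex in SEXES:
            prev = self.behaviour_prevalences[sex]
            for key in BEHAVIOUR_KEYS:
                p = prev[key]
                if not (0.0 <= p <= 1.0):
                    raise SyntheticConfigError(f"behaviour_prevalences[{sex}][{key}] = {p} not in [0, 1]")
            smoking = prev["smoking"]
            for level, p in smoking.items():
                if not (0.0 <= p <= 1.0):
                    raise SyntheticConfigError(f"behaviour_prevalences[{sex}][smoking][{level}] = {p} not in [0, 1]")
            if abs(sum(smoking.values()) - 1.0) > 1e-9:
                raise SyntheticConfigError(f"behaviour_prevalences[{sex}][smoking] must sum to 1")
            conf = self.confounder_distributions[sex]
            for key in ("p_nonwhite", "p_not_employed"):
                if not (0.0 <= conf[key] <= 1.0):
                    raise SyntheticConfigError(f"confounder_distributions[{sex}][{key}] not in [0, 1]")
            for key in ("age_sd", "tdi_sd"):
                if conf[key] <= 0:
                    raise SyntheticConfigError(f"confounder_distributions[{sex}][{key}] must be > 0")
        for key in self.interaction_offsets:
            if not is_valid_key(key):
                raise StratumKeyError(f"interaction_offsets key {key!r} is not a valid stratum key")

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticConfig":
        """Build a config from a (YAML-loaded) mapping, deep-merging nested defaults."""
        data = dict(data)
        defaults = cls()
        kwargs: dict = {}
        for f in dataclasses.fields(cls):
            if f.name not in data:
                continue
            value = data.pop(f.name)
            current = getattr(defaults, f.name)
            if isinstance(current, dict) and isinstance(value, Mapping):
                kwargs[f.name] = _deep_update(current, value)
            else:
                kwargs[f.name] = value
        if data:
            raise SyntheticConfigError(f"unknown configuration fields: {sorted(data)}")
        return cls(**kwargs)


def inject_stratum_interaction(config: SyntheticConfig, stratum: str, offset_bmi: float) -> SyntheticConfig:
    """Return a config with an additional BMI offset (kg/m^2) for one stratum."""
    if not is_valid_key(stratum):
        raise StratumKeyError(f"invalid stratum key {stratum!r}")
    offsets = dict(config.interaction_offsets)
    offsets[stratum] = offsets.get(stratum, 0.0) + float(offset_bmi)
    return config.replace(interaction_offsets=offsets)


@dataclass
class TrueParameters:
    """Realised generating values emitted alongside every cohort.

    ``stratum_offsets`` holds, per sex, the realised latent deviation plus any
    injected interaction offset for each of the 48 strata;
    ``implied_between_stratum_variance`` is the prevalence-weighted variance of
    those offsets (the level-2 variance beyond the additive fixed effects).
    """

    intercept_bmi: dict[str, float]
    fixed_effects_bmi: dict[str, dict[str, float]]
    confounder_effects_bmi: dict[str, float]
    stratum_offsets: dict[str, dict[str, float]]
    residual_sd_bmi: float
    implied_between_stratum_variance: dict[str, float]
    stratum_probabilities: dict[str, dict[str, float]]
    obesity_rule: str
    logit_intercept: dict[str, float] | None = None
    logit_stratum_offsets: dict[str, dict[str, float]] | None = None


def _stratum_probabilities(prev: Mapping) -> np.ndarray:
    """Theoretical probability of each stratum (enumeration order) under independence."""
    keys = enumerate_strata()
    p_b = {k: prev[k] for k in BEHAVIOUR_KEYS}
    p_smk = [prev["smoking"]["previous"], prev["smoking"]["current"], prev["smoking"]["never"]]
    out = np.empty(len(keys))
    for i, key in enumerate(keys):
        d = [int(c) for c in key]
        p = 1.0
        for j, bk in enumerate(BEHAVIOUR_KEYS):
            p *= p_b[bk] if d[j] == 1 else 1.0 - p_b[bk]
        p *= p_smk[d[4]]
        out[i] = p
    return out


def _uniform_above(rng: np.random.Generator, low: float, high: float, size: int) -> np.ndarray:
    """Uniform draw strictly above ``low`` (open at the lower endpoint)."""
    return rng.uniform(np.nextafter(low, high), high, size)


def generate_cohort(config: SyntheticConfig) -> tuple[pd.DataFrame, TrueParameters]:
    """Generate a person-level cohort plus its realised ground truth.

    Returns a frame with one row per person carrying both the raw
    questionnaire measures (see :data:`maihda.prep.RAW_COLUMNS`) and the drawn
    behaviour codes (``sleep_meets`` ... ``smoking_code``), the stratum key,
    and the ``obese`` indicator derived per ``config.obesity_rule``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    keys = enumerate_strata()
    frames = []
    offsets_by_sex: dict[str, dict[str, float]] = {}
    implied_var: dict[str, float] = {}
    probs_by_sex: dict[str, dict[str, float]] = {}
    logit_offsets_by_sex: dict[str, dict[str, float]] = {}

    for sex in SEXES:
        n = config.n_per_sex
        prev = config.behaviour_prevalences[sex]
        eff = config.behaviour_effects_bmi[sex]
        conf = config.confounder_distributions[sex]
        ceff = config.confounder_effects_bmi

        # behaviour codes (independent across variables)
        sleep = (rng.random(n) < prev["sleep_meets"]).astype(int)
        fv = (rng.random(n) < prev["fv_meets"]).astype(int)
        alcohol = (rng.random(n) < prev["alcohol_meets"]).astype(int)
        pa = (rng.random(n) < prev["pa_meets"]).astype(int)
        p_smk = np.array([prev["smoking"]["previous"], prev["smoking"]["current"], prev["smoking"]["never"]])
        smoking = rng.choice(3, size=n, p=p_smk)

        # raw measures consistent with the drawn codes
        sleep_hours = np.where(
            sleep == 1,
            rng.uniform(prep.SLEEP_LO, prep.SLEEP_HI, n),
            np.where(rng.random(n) < 0.5, rng.uniform(4.0, prep.SLEEP_LO, n),
                     _uniform_above(rng, prep.SLEEP_HI, 12.0, n)),
        )
        fv_portions = np.where(fv == 1, rng.uniform(prep.FV_MIN, 10.0, n), rng.uniform(0.0, prep.FV_MIN, n))
        alcohol_units = np.where(alcohol == 1, rng.uniform(0.0, prep.ALCOHOL_MAX, n),
                                 _uniform_above(rng, prep.ALCOHOL_MAX, 50.0, n))
        via_moderate = rng.random(n) < 0.5
        pa_moderate = np.where(
            pa == 1,
            np.where(via_moderate, rng.uniform(prep.PA_MODERATE_MIN, 600.0, n),
                     rng.uniform(0.0, prep.PA_MODERATE_MIN, n)),
            rng.uniform(0.0, prep.PA_MODERATE_MIN, n),
        )
        pa_vigorous = np.where(
            pa == 1,
            np.where(via_moderate, rng.uniform(0.0, prep.PA_VIGOROUS_MIN, n),
                     rng.uniform(prep.PA_VIGOROUS_MIN, 300.0, n)),
            rng.uniform(0.0, prep.PA_VIGOROUS_MIN, n),
        )

        # confounders
        age = rng.normal(conf["age_mean"], conf["age_sd"], n)
        tdi = rng.normal(conf["tdi_mean"], conf["tdi_sd"], n)
        nonwhite = (rng.random(n) < conf["p_nonwhite"]).astype(int)
        not_employed = (rng.random(n) < conf["p_not_employed"]).astype(int)

        # stratum membership (index in enumeration order) and latent offsets
        idx = (((sleep * 2 + fv) * 2 + alcohol) * 2 + pa) * 3 + smoking
        latent = rng.normal(0.0, config.extra_stratum_sd, len(keys)) if config.extra_stratum_sd > 0 else np.zeros(len(keys))
        offsets = latent + np.array([config.interaction_offsets.get(k, 0.0) for k in keys])

        fixed = (
            config.intercept_bmi[sex]
            + eff["sleep_meets"] * sleep
            + eff["fv_meets"] * fv
            + eff["alcohol_meets"] * alcohol
            + eff["pa_meets"] * pa
            + eff["smoking_current"] * (smoking == 1)
            + eff["smoking_never"] * (smoking == 2)
            + ceff["age"] * (age - conf["age_mean"])
            + ceff["tdi"] * (tdi - conf["tdi_mean"])
            + ceff["nonwhite"] * nonwhite
            + ceff["not_employed"] * not_employed
        )
        bmi = fixed + offsets[idx] + rng.normal(0.0, config.residual_sd_bmi, n)
        bmi = np.maximum(bmi, 12.0)  # keep BMI physiologically positive

        if config.obesity_rule == "bmi-threshold":
            obese = (bmi >= 30.0).astype(int)
            logit_latent = np.zeros(len(keys))
        else:
            logit_latent = (rng.normal(0.0, config.logit_stratum_sd, len(keys))
                            if config.logit_stratum_sd > 0 else np.zeros(len(keys)))
            leff = config.logit_effects[sex]
            eta = (
                config.logit_intercept[sex]
                + leff["sleep_meets"] * sleep
                + leff["fv_meets"] * fv
                + leff["alcohol_meets"] * alcohol
                + leff["pa_meets"] * pa
                + leff["smoking_current"] * (smoking == 1)
                + leff["smoking_never"] * (smoking == 2)
                + logit_latent[idx]
            )
            obese = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)

        probs = _stratum_probabilities(prev)
        mean_offset = float(probs @ offsets)
        implied_var[sex] = float(probs @ (offsets - mean_offset) ** 2)
        offsets_by_sex[sex] = {k: float(v) for k, v in zip(keys, offsets)}
        probs_by_sex[sex] = {k: float(v) for k, v in zip(keys, probs)}
        logit_offsets_by_sex[sex] = {k: float(v) for k, v in zip(keys, logit_latent)}

        frames.append(pd.DataFrame({
            "sex": sex,
            "sleep_hours": sleep_hours,
            "fv_portions": fv_portions,
            "alcohol_units": alcohol_units,
            "pa_moderate_min": pa_moderate,
            "pa_vigorous_min": pa_vigorous,
            "smoking": np.array(["previous", "current", "never"], dtype=object)[smoking],
            "age": age,
            "tdi": tdi,
            "ethnicity": np.where(nonwhite == 1, "non-white", "white"),
            "employment": np.where(not_employed == 1, "not-employed-or-retired", "employed"),
            "bmi": bmi,
            "sleep_meets": sleep,
            "fv_meets": fv,
            "alcohol_meets": alcohol,
            "pa_meets": pa,
            "smoking_code": smoking,
            "stratum": np.array(keys, dtype=object)[idx],
            "obese": obese,
        }))

    records = pd.concat(frames, ignore_index=True)
    truth = TrueParameters(
        intercept_bmi=dict(config.intercept_bmi),
        fixed_effects_bmi={sex: dict(config.behaviour_effects_bmi[sex]) for sex in SEXES},
        confounder_effects_bmi=dict(config.confounder_effects_bmi),
        stratum_offsets=offsets_by_sex,
        residual_sd_bmi=config.residual_sd_bmi,
        implied_between_stratum_variance=implied_var,
        stratum_probabilities=probs_by_sex,
        obesity_rule=config.obesity_rule,
        logit_intercept=dict(config.logit_intercept) if config.obesity_rule == "independent-logit" else None,
        logit_stratum_offsets=logit_offsets_by_sex if config.obesity_rule == "independent-logit" else None,
    )
    return records, truth


def emit_raw_questionnaire(records: pd.DataFrame, path=None) -> pd.DataFrame:
    """Raw-scale questionnaire table (drops the generated codes).

    Columns are :data:`maihda.prep.RAW_COLUMNS` plus the simulated ``obese``
    indicator (needed downstream when the generating obesity rule is
    ``independent-logit``).  If ``path`` is given the table is also written
    as CSV with a header row.
    """
    cols = [c for c in prep.RAW_COLUMNS] + ["obese"]
    out = records[cols].copy()
    if path is not None:
        out.to_csv(path, index=False)
    return out
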