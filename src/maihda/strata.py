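"""Encoding, decoding and enumeration of the 48 lifestyle-behaviour strata.

A stratum is one cell of the full cross-classification of the five coded
lifestyle behaviours and is identified by a 5-character digit string in the
fixed order

    (sleep, fruit & vegetables, alcohol, physical activity, smoking)

where the first four digits are 1 (meets the guideline) or 0 (does not) and
the fifth is the smoking code 0 = previous, 1 = current, 2 = never.  For
example ``"01112"`` is the stratum that misses the sleep guideline, meets the
fruit-and-vegetable, alcohol and physical-activity guidelines, and has never
smoked.  There are 2x2x2x2x3 = 48 strata.

Keys are plain strings everywhere (leading zeros significant); the digit
order is fixed and not configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping

import numpy as np
import pandas as pd

#: behaviour names in stratum-digit order
DIGIT_ORDER = ("sleep", "fruit_veg", "alcohol", "physical_activity", "smoking")

#: coded-record column feeding each digit, in digit order
DIGIT_COLUMNS = ("sleep_meets", "fv_meets", "alcohol_meets", "pa_meets", "smoking_code")

SMOKING_LABELS = {0: "previous", 1: "current", 2: "never"}
BINARY_LABELS = {0: "not-meets", 1: "meets"}

N_STRATA = 48


class StratumKeyError(KeyError):
    """Raised for malformed or unknown stratum keys."""


def enumerate_strata() -> list[str]:
    """All 48 valid stratum keys in lexicographic order.

    The order is stable across runs and platforms: ``"00000"``, ``"00001"``,
    ``"00002"``, ``"00010"``, ... , ``"11112"``.
    """
    return ["".join(map(str, digits)) for digits in product((0, 1), (0, 1), (0, 1), (0, 1), (0, 1, 2))]


_VALID_KEYS = frozenset(enumerate_strata())
_KEY_TO_INDEX = {k: i for i, k in enumerate(enumerate_strata())}


def is_valid_key(key: str) -> bool:
    return key in _VALID_KEYS


def encode_stratum(coded: Mapping) -> str:
    """Encode one coded record (mapping or Series) into its stratum key.

    Requires the five code fields of ``DIGIT_COLUMNS`` to be present and
    non-missing; a missing code raises ``ValueError`` naming the behaviour.
    """
    digits = []
    for name, col in zip(DIGIT_ORDER, DIGIT_COLUMNS):
        value = coded.get(col) if hasattr(coded, "get") else coded[col]
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise ValueError(f"cannot encode stratum: missing {name} code ({col!r})")
        digits.append(int(value))
    key = "".join(map(str, digits))
    if key not in _VALID_KEYS:
        raise StratumKeyError(f"behaviour codes {digits} do not form a valid stratum key")
    return key


def decode_stratum(key: str) -> dict:
    """Decode a key into its behaviour codes plus human-readable labels."""
    if not isinstance(key, str) or len(key) != 5 or key not in _VALID_KEYS:
        raise StratumKeyError(f"invalid stratum key {key!r}: expected one of the 48 5-digit codes")
    codes = [int(c) for c in key]
    out = dict(zip(DIGIT_COLUMNS, codes))
    out["labels"] = {
        "sleep": BINARY_LABELS[codes[0]],
        "fruit_veg": BINARY_LABELS[codes[1]],
        "alcohol": BINARY_LABELS[codes[2]],
        "physical_activity": BINARY_LABELS[codes[3]],
        "smoking": SMOKING_LABELS[codes[4]],
    }
    return out


def stratum_index_of(key: str) -> int:
    """Position of ``key`` in ``enumerate_strata()`` order."""
    try:
        return _KEY_TO_INDEX[key]
    except KeyError:
        raise StratumKeyError(f"invalid stratum key {key!r}") from None


def encode_strata_frame(coded: pd.DataFrame) -> pd.Series:
    """Vectorised ``encode_stratum`` over a coded analysis set."""
    for name, col in zip(DIGIT_ORDER, DIGIT_COLUMNS):
        if col not in coded.columns:
            raise ValueError(f"cannot encode strata: missing column {col!r} ({name})")
        if coded[col].isna().any():
            raise ValueError(f"cannot encode strata: missing {name} code in {int(coded[col].isna().sum())} records")
    parts = [coded[col].astype(int).astype(str) for col in DIGIT_COLUMNS]
    keys = parts[0].str.cat(parts[1:])
    bad = ~keys.isin(_VALID_KEYS)
    if bad.any():
        raise StratumKeyError(f"invalid behaviour codes in {int(bad.sum())} records")
    return keys.rename("stratum")


@dataclass
class StratumIndex:
    """Per-stratum membership for one analysis set.

    ``counts`` covers all 48 keys (zero-member strata retained with n = 0);
    ``members`` maps each key to the integer row positions of its members.
    """

    counts: dict[str, int]
    members: dict[str, np.ndarray] = field(repr=False)

    @property
    def n_total(self) -> int:
        return int(sum(self.counts.values()))

    def nonempty(self) -> list[str]:
        return [k for k in enumerate_strata() if self.counts[k] > 0]


def assign_strata(coded: pd.DataFrame) -> StratumIndex:
    """Assign every record of a recoded, exclusion-applied analysis set to its stratum."""
    keys = coded["stratum"] if "stratum" in coded.columns else encode_strata_frame(coded)
    keys = np.asarray(keys, dtype=object)
    counts = dict.fromkeys(enumerate_strata(), 0)
    members: dict[str, np.ndarray] = {k: np.empty(0, dtype=np.intp) for k in enumerate_strata()}
    order = np.argsort(keys, kind="stable")
    sorted_keys = keys[order]
    boundaries = np.flatnonzero(np.r_[True, sorted_keys[1:] != sorted_keys[:-1], True])
    for start, stop in zip(boundaries[:-1], boundaries[1:]):
        key = sorted_keys[start]
        if key not in _VALID_KEYS:
            raise StratumKeyError(f"invalid stratum key {key!r} in analysis set")
        counts[key] = int(stop - start)
        members[key] = np.sort(order[start:stop])
    return StratumIndex(counts=counts, members=members)
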