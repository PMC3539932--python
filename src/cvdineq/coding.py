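"""Convert raw questionnaire responses into categorical model covariates.

Every classifier retains item non-response as an explicit ``MISSING`` level
(missing-as-category), so no participant is dropped for an incomplete risk
factor. Reference levels follow the convention used throughout the analysis:
the most advantaged / normative category is the reference (shown as HR = 1.00
in output tables).
"""

from __future__ import annotations

import json
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = "missing"

#: weekly-hours value assigned to each activity frequency band
BAND_HOURS: Mapping[str, float] = {
    "never": 0.0,
    "lt1h": 0.5,
    "1to2h": 1.5,
    "ge2h": 2.5,
}

_BAND_VALUES = frozenset(BAND_HOURS.values())

# Coded covariate levels, reference level first. Order is the display and
# dummy-coding order used by the modelling layer.
COVARIATE_LEVELS: Mapping[str, Sequence[str]] = {
    "adulthood_sep": ("4_high", "3_mid_high", "2_mid_low", "1_low"),
    "childhood_sep": ("professional", "white_collar", "blue_collar", MISSING),
    "smoking": ("never", "former", "current", MISSING),
    "physical_activity": (
        "active",
        "moderately_active",
        "little_active",
        "inactive",
        MISSING,
    ),
    "alcohol": ("light", "abstainer", "moderate", "heavy", MISSING),
    "bmi_class": ("normal", "underweight", "overweight", "obese", MISSING),
    "insurance": ("private", "public", MISSING),
    "car": ("yes", "no", MISSING),
    "tenure": ("owner", "renter", MISSING),
    "financial_problems": ("none", "some", "big", MISSING),
    "nbhd_adversity": ("none", "one_or_more", MISSING),
    "housing_adversity": ("none", "one_or_more", MISSING),
    "marital": ("married", "single", "divorced", "widowed", MISSING),
    "life_events": ("none", "one", "two_or_more", MISSING),
    "sleep_anxiety_drugs": ("no", "yes", MISSING),
    "depression_nervousness": ("no", "yes", MISSING),
}

#: covariate block membership used by the nested model sequence
BLOCKS: Mapping[str, Sequence[str]] = {
    "adulthood_sep": ("adulthood_sep",),
    "childhood_sep": ("childhood_sep",),
    "material": (
        "insurance",
        "car",
        "tenure",
        "financial_problems",
        "nbhd_adversity",
        "housing_adversity",
    ),
    "behavioural": ("smoking", "physical_activity", "alcohol", "bmi_class"),
    "psychosocial": (
        "marital",
        "life_events",
        "sleep_anxiety_drugs",
        "depression_nervousness",
    ),
}

RISK_FACTORS: tuple[str, ...] = tuple(
    BLOCKS["material"] + BLOCKS["behavioural"] + BLOCKS["psychosocial"]
)


class CodingError(ValueError):
    """Raised when a raw response token cannot be coded."""

    def __init__(self, field: str, value: object, reason: str = "unrecognized value"):
        self.field = field
        self.value = value
        super().__init__(f"{reason} for {field!r}: {value!r}")


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip().lower() in ("", MISSING, "nan", "na"):
        return True
    return value is pd.NA


def classify_smoking(smoking_raw: object) -> str:
    """Smoking status: never / former / current, missing retained."""
    if _is_missing(smoking_raw):
        return MISSING
    if smoking_raw in ("never", "former", "current"):
        return str(smoking_raw)
    raise CodingError("smoking_raw", smoking_raw)


def band_to_hours(band: object) -> float:
    """Map an activity frequency band to weekly hours (0 / 0.5 / 1.5 / 2.5)."""
    if _is_missing(band):
        return float("nan")
    try:
        return BAND_HOURS[band]  # type: ignore[index]
    except (KeyError, TypeError):
        raise CodingError("activity_band", band) from None


def classify_physical_activity(
    sport_hours: float, transport_hours: float, leisure_hours: float
) -> str:
    """Physical activity class from band-mapped weekly hours.

    ``moderate`` activity is transport plus leisure time; the class is a
    monotone function of total weekly hours (sports + moderate):
    [0, 1] inactive, (1, 2.5) little_active, [2.5, 3.5) moderately_active,
    >= 3.5 active. Any missing component yields MISSING.
    """
    hours = (sport_hours, transport_hours, leisure_hours)
    if any(h is None or (isinstance(h, float) and math.isnan(h)) for h in hours):
        return MISSING
    for h in hours:
        if h not in _BAND_VALUES:
            raise CodingError("activity_hours", h, "not a band-mapped value")
    total = sport_hours + transport_hours + leisure_hours
    if total >= 3.5:
        return "active"
    if total >= 2.5:
        return "moderately_active"
    if total > 1.0:
        return "little_active"
    return "inactive"


def weekly_alcohol_units(days_per_week: object, units_per_day: object) -> float:
    """Weekly alcohol units = drinking days x units per drinking day."""
    if _is_missing(days_per_week) or _is_missing(units_per_day):
        return float("nan")
    days = float(days_per_week)  # type: ignore[arg-type]
    units = float(units_per_day)  # type: ignore[arg-type]
    if days < 0 or days > 7:
        raise CodingError("alcohol_days_per_week", days_per_week, "outside 0-7")
    if units < 0:
        raise CodingError("alcohol_units_per_day", units_per_day, "negative")
    if days == 0:
        return 0.0
    return days * units


def classify_alcohol(units_week: float, sex: str) -> str:
    """Sex-specific weekly-consumption class.

    Women: light (0, 7], moderate (7, 14], heavy > 14 units/week.
    Men:   light (0, 10], moderate (10, 21], heavy > 21 units/week.
    Zero units is an abstainer; ranges are half-open at the upper bound.
    """
    if units_week is None or (isinstance(units_week, float) and math.isnan(units_week)):
        return MISSING
    if sex not in ("male", "female"):
        raise CodingError("sex", sex)
    if units_week < 0:
        raise CodingError("units_week", units_week, "negative")
    if units_week == 0:
        return "abstainer"
    light_hi, mod_hi = (10.0, 21.0) if sex == "male" else (7.0, 14.0)
    if units_week <= light_hi:
        return "light"
    if units_week <= mod_hi:
        return "moderate"
    return "heavy"


def classify_bmi(weight: object, height: object) -> str:
    """BMI class from weight (kg) and height (m).

    Upper-inclusive bins: underweight <= 20 < normal <= 25 < overweight <= 30
    < obese.
    """
    if _is_missing(weight) or _is_missing(height):
        return MISSING
    w = float(weight)  # type: ignore[arg-type]
    h = float(height)  # type: ignore[arg-type]
    if w <= 0:
        raise CodingError("weight", weight, "nonpositive")
    if h <= 0:
        raise CodingError("height", height, "nonpositive")
    bmi = w / h**2
    if bmi <= 20.0:
        return "underweight"
    if bmi <= 25.0:
        return "normal"
    if bmi <= 30.0:
        return "overweight"
    return "obese"


def code_adversity(items: Sequence[object], n_items: int) -> str:
    """Collapse a multi-item adverse-conditions scale to none / one_or_more.

    Any observed adverse flag makes the scale positive; an all-zero fully
    observed vector is negative; otherwise (some items missing, none positive)
    the construct is unresolvable and MISSING.
    """
    if len(items) != n_items:
        raise CodingError("adversity_items", items, f"expected {n_items} items")
    observed = []
    for item in items:
        if _is_missing(item):
            continue
        flag = int(item)  # type: ignore[arg-type]
        if flag not in (0, 1):
            raise CodingError("adversity_items", item, "flag not 0/1")
        observed.append(flag)
    if any(f == 1 for f in observed):
        return "one_or_more"
    if len(observed) == n_items:
        return "none"
    return MISSING


def code_life_events(count: object) -> str:
    """Negative life events in the preceding year: none / one / two_or_more."""
    if _is_missing(count):
        return MISSING
    c = int(count)  # type: ignore[arg-type]
    if c < 0 or c > 9:
        raise CodingError("life_events_count", count, "outside nine-item inventory")
    if c == 0:
        return "none"
    if c == 1:
        return "one"
    return "two_or_more"


def _code_binary(value: object, field: str, levels: Sequence[str]) -> str:
    if _is_missing(value):
        return MISSING
    if value in levels:
        return str(value)
    raise CodingError(field, value)


# ---------------------------------------------------------------------------
# cohort-level coding


RAW_COLUMNS = [
    "id",
    "sex",
    "age_baseline",
    "education",
    "father_occupation",
    "smoking_raw",
    "sport_band",
    "transport_band",
    "leisure_band",
    "alcohol_days_per_week",
    "alcohol_units_per_day",
    "weight",
    "height",
    "insurance",
    "car",
    "tenure",
    "financial_problems",
    "nbhd_item1",
    "nbhd_item2",
    "nbhd_item3",
    "nbhd_item4",
    "housing_item1",
    "housing_item2",
    "housing_item3",
    "marital",
    "life_events_count",
    "sleep_anxiety_drugs",
    "depression_nervousness",
    "prior_cvd_5yr",
    "death_date",
    "icd_code",
    "icd_version",
    "emigration_date",
]

_EDUCATION_TO_SEP = {1: "1_low", 2: "2_mid_low", 3: "3_mid_high", 4: "4_high"}


def code_participant(row: Mapping[str, object]) -> dict[str, str]:
    """Code one raw participant record into the covariate levels."""
    edu = row.get("education")
    if _is_missing(edu):
        adult_sep = MISSING
    else:
        try:
            adult_sep = _EDUCATION_TO_SEP[int(edu)]  # type: ignore[arg-type]
        except (KeyError, ValueError):
            raise CodingError("education", edu) from None

    sport = band_to_hours(row.get("sport_band"))
    transport = band_to_hours(row.get("transport_band"))
    leisure = band_to_hours(row.get("leisure_band"))

    units = weekly_alcohol_units(
        row.get("alcohol_days_per_week"), row.get("alcohol_units_per_day")
    )
    sex = row["sex"]
    if sex not in ("male", "female"):
        raise CodingError("sex", sex)

    nbhd = [row.get(f"nbhd_item{i}") for i in range(1, 5)]
    housing = [row.get(f"housing_item{i}") for i in range(1, 4)]

    fin = row.get("financial_problems")
    return {
        "adulthood_sep": adult_sep,
        "childhood_sep": _code_binary(
            row.get("father_occupation"),
            "father_occupation",
            ("professional", "white_collar", "blue_collar"),
        ),
        "smoking": classify_smoking(row.get("smoking_raw")),
        "physical_activity": classify_physical_activity(sport, transport, leisure),
        "alcohol": classify_alcohol(units, str(sex)),
        "bmi_class": classify_bmi(row.get("weight"), row.get("height")),
        "insurance": _code_binary(row.get("insurance"), "insurance", ("private", "public")),
        "car": _code_binary(row.get("car"), "car", ("yes", "no")),
        "tenure": _code_binary(row.get("tenure"), "tenure", ("owner", "renter")),
        "financial_problems": _code_binary(
            fin, "financial_problems", ("none", "some", "big")
        ),
        "nbhd_adversity": code_adversity(nbhd, 4),
        "housing_adversity": code_adversity(housing, 3),
        "marital": _code_binary(
            row.get("marital"), "marital", ("married", "single", "divorced", "widowed")
        ),
        "life_events": code_life_events(row.get("life_events_count")),
        "sleep_anxiety_drugs": _code_binary(
            row.get("sleep_anxiety_drugs"), "sleep_anxiety_drugs", ("no", "yes")
        ),
        "depression_nervousness": _code_binary(
            row.get("depression_nervousness"), "depression_nervousness", ("no", "yes")
        ),
    }


def code_cohort(raw: pd.DataFrame) -> pd.DataFrame:
    """Code a raw cohort table; returns one row per participant.

    Carries through ``id``, ``sex`` and ``age_baseline`` unchanged. Raises
    :class:`CodingError` on the first unrecognized token.
    """
    records = []
    for row in raw.to_dict("records"):
        coded = code_participant(row)
        coded["id"] = row["id"]
        coded["sex"] = row["sex"]
        coded["age_baseline"] = row["age_baseline"]
        records.append(coded)
    out = pd.DataFrame.from_records(records)
    cols = ["id", "sex", "age_baseline"] + list(COVARIATE_LEVELS)
    return out[cols]


def read_raw_cohort(path) -> pd.DataFrame:
    """Strict CSV reader for the raw cohort schema.

    Validates the column set and reports per-column unrecognized-token counts
    before any row-level coding happens.
    """
    df = pd.read_csv(path, dtype={"icd_code": str})
    missing_cols = set(RAW_COLUMNS) - set(df.columns)
    if missing_cols:
        raise CodingError("columns", sorted(missing_cols), "missing required columns")

    allowed = {
        "sex": {"male", "female"},
        "smoking_raw": {"never", "former", "current"},
        "sport_band": set(BAND_HOURS),
        "transport_band": set(BAND_HOURS),
        "leisure_band": set(BAND_HOURS),
        "father_occupation": {"professional", "white_collar", "blue_collar"},
        "insurance": {"private", "public"},
        "car": {"yes", "no"},
        "tenure": {"owner", "renter"},
        "financial_problems": {"none", "some", "big"},
        "marital": {"married", "single", "divorced", "widowed"},
        "sleep_anxiety_drugs": {"no", "yes"},
        "depression_nervousness": {"no", "yes"},
        "prior_cvd_5yr": {"no", "yes"},
    }
    bad: dict[str, int] = {}
    for col, levels in allowed.items():
        observed = df[col].dropna().astype(str)
        n_bad = int((~observed.isin(levels)).sum())
        if n_bad:
            bad[col] = n_bad
    if bad:
        raise CodingError("tokens", bad, "unrecognized tokens per column")
    return df


def data_dictionary() -> dict:
    """JSON-serializable description of every coded level and its reference."""
    return {
        cov: {"levels": list(levels), "reference": levels[0]}
        for cov, levels in COVARIATE_LEVELS.items()
    }


def write_data_dictionary(path) -> None:
    with open(path, "w") as fh:
        json.dump(data_dictionary(), fh, indent=2)
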