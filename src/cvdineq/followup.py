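"""Survival time and CVD-death event derivation, plus analytic-sample exclusions.

Follow-up runs from the baseline survey date (1991-04-01) to the register
linkage date (2007-10-15). Deaths from circulatory causes (ICD-9 390-459,
ICD-10 I00-I99) are events; deaths from other causes, emigration, and survival
to the end of follow-up are censored (cause-specific hazard).
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

BASELINE_DATE = dt.date(1991, 4, 1)
END_DATE = dt.date(2007, 10, 15)
DAYS_PER_YEAR = 365.25
#: full administrative window in years (~16.54)
WINDOW_YEARS = (END_DATE - BASELINE_DATE).days / DAYS_PER_YEAR

_ICD9_RE = re.compile(r"^(\d{3})(\.\d+)?$")
_ICD10_RE = re.compile(r"^([A-Z])(\d{2})")


class FollowUpError(ValueError):
    pass


@dataclass(frozen=True)
class SurvivalRecord:
    id: object
    time: float  # years since baseline
    event: int  # 1 = CVD death, 0 = censored
    censor_reason: str | None  # alive_at_end / emigrated / non_cvd_death


def is_cvd_death(icd_code: str, icd_version: int) -> bool:
    """True if the cause-of-death code falls in the circulatory chapter."""
    if not icd_code or not isinstance(icd_code, str):
        raise FollowUpError(f"unparsable ICD code: {icd_code!r}")
    code = icd_code.strip().upper()
    if icd_version == 9:
        m = _ICD9_RE.match(code)
        if not m:
            raise FollowUpError(f"unparsable ICD-9 code: {icd_code!r}")
        return 390 <= int(m.group(1)) <= 459
    if icd_version == 10:
        m = _ICD10_RE.match(code)
        if not m:
            raise FollowUpError(f"unparsable ICD-10 code: {icd_code!r}")
        return m.group(1) == "I"
    raise FollowUpError(f"unknown ICD version: {icd_version!r}")


def _parse_date(value) -> dt.date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str):
        if not value.strip():
            return None
        return dt.date.fromisoformat(value.strip())
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    if isinstance(value, pd.Timestamp):
        return value.date()
    raise FollowUpError(f"unparsable date: {value!r}")


def compute_follow_up(
    participant_id,
    death_date=None,
    cvd_flag: bool | None = None,
    emigration_date=None,
) -> SurvivalRecord:
    """Derive follow-up time (years) and the CVD event indicator.

    Emigration before death takes precedence (no register linkage after
    emigration); a death on the baseline date is assigned half a day of
    follow-up to keep time strictly positive.
    """
    death = _parse_date(death_date)
    emig = _parse_date(emigration_date)
    for name, d in (("death_date", death), ("emigration_date", emig)):
        if d is not None and not (BASELINE_DATE <= d <= END_DATE):
            raise FollowUpError(f"{name} {d} outside follow-up window")

    if emig is not None and (death is None or emig < death):
        time = (emig - BASELINE_DATE).days / DAYS_PER_YEAR
        record = SurvivalRecord(participant_id, max(time, 0.5 / DAYS_PER_YEAR), 0, "emigrated")
    elif death is not None:
        time = (death - BASELINE_DATE).days / DAYS_PER_YEAR
        time = max(time, 0.5 / DAYS_PER_YEAR)
        if cvd_flag:
            record = SurvivalRecord(participant_id, time, 1, None)
        else:
            record = SurvivalRecord(participant_id, time, 0, "non_cvd_death")
    else:
        record = SurvivalRecord(participant_id, WINDOW_YEARS, 0, "alive_at_end")
    return record


def derive_survival(raw: pd.DataFrame) -> pd.DataFrame:
    """Vectorized follow-up derivation for a raw cohort table.

    Expects columns death_date, icd_code, icd_version, emigration_date
    (ISO-8601, empty = absent). Returns id, time_years, event, censor_reason.
    """
    records = []
    for row in raw.to_dict("records"):
        death = row.get("death_date")
        cvd = None
        if not pd.isna(death) and str(death).strip():
            cvd = is_cvd_death(str(row["icd_code"]), int(row["icd_version"]))
        rec = compute_follow_up(row["id"], death, cvd, row.get("emigration_date"))
        records.append(
            {
                "id": rec.id,
                "time_years": rec.time,
                "event": rec.event,
                "censor_reason": rec.censor_reason or "",
            }
        )
    return pd.DataFrame.from_records(records)


def apply_exclusions(raw: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Apply the analytic-sample exclusions.

    Removes participants younger than 40 at baseline (40 itself retained),
    those reporting severe heart problems / heart attack / stroke in the five
    years before baseline, and those with missing adulthood SEP (education).
    The tally reports per-criterion counts, which partly overlap.
    """
    age_excl = raw["age_baseline"] < 40
    cvd_excl = raw["prior_cvd_5yr"].astype(str) == "yes"
    sep_excl = raw["education"].isna()
    any_excl = age_excl | cvd_excl | sep_excl
    tally = {
        "input_n": int(len(raw)),
        "age_lt_40": int(age_excl.sum()),
        "prior_cvd": int(cvd_excl.sum()),
        "missing_adulthood_sep": int(sep_excl.sum()),
        "excluded_union": int(any_excl.sum()),
        "overlap": int(age_excl.sum() + cvd_excl.sum() + sep_excl.sum() - any_excl.sum()),
        "analytic_n": int((~any_excl).sum()),
    }
    return raw.loc[~any_excl].reset_index(drop=True), tally
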