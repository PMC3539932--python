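import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cvdineq import coding
from cvdineq.coding import (
    MISSING,
    CodingError,
    band_to_hours,
    classify_alcohol,
    classify_bmi,
    classify_physical_activity,
    classify_smoking,
    code_adversity,
    code_life_events,
    weekly_alcohol_units,
)

BANDS = [0.0, 0.5, 1.5, 2.5]
PA_ORDER = ["inactive", "little_active", "moderately_active", "active"]


class TestSmoking:
    @pytest.mark.parametrize(
        "raw,expected",
        [("never", "never"), ("former", "former"), ("current", "current"), (None, MISSING)],
    )
    def test_identity_mapping_with_missing(self, raw, expected):
        assert classify_smoking(raw) == expected

    def test_unrecognized_token_names_field_and_value(self):
        with pytest.raises(CodingError, match="smoking_raw.*quit"):
            classify_smoking("quit")

    def test_idempotent(self):
        for level in ("never", "former", "current"):
            assert classify_smoking(classify_smoking(level)) == level


class TestActivity:
    @pytest.mark.parametrize(
        "band,hours", [("never", 0.0), ("lt1h", 0.5), ("1to2h", 1.5), ("ge2h", 2.5)]
    )
    def test_band_hours(self, band, hours):
        assert band_to_hours(band) == hours

    def test_missing_band_propagates(self):
        assert math.isnan(band_to_hours(None))

    @pytest.mark.parametrize(
        "sport,transport,leisure,expected",
        [
            (0.0, 0.0, 0.5, "inactive"),
            (2.5, 0.0, 1.5, "active"),
            (1.5, 0.5, 1.5, "active"),  # total exactly 3.5
            (0.0, 0.5, 1.5, "little_active"),
            (0.5, 0.5, 1.5, "moderately_active"),
        ],
    )
    def test_classification(self, sport, transport, leisure, expected):
        assert classify_physical_activity(sport, transport, leisure) == expected

    def test_rule_table_total_single_valued_monotone(self):
        """Over all 4^3 band combinations the rule is total, single-valued,
        and monotone non-decreasing in total weekly hours."""
        by_total = {}
        for s, t, l in itertools.product(BANDS, repeat=3):
            cls = classify_physical_activity(s, t, l)
            assert cls in PA_ORDER
            by_total.setdefault(s + t + l, set()).add(cls)
        # single-valued in total hours
        assert all(len(v) == 1 for v in by_total.values())
        totals = sorted(by_total)
        ranks = [PA_ORDER.index(next(iter(by_total[t]))) for t in totals]
        assert ranks == sorted(ranks)

    def test_missing_component_yields_missing(self):
        assert classify_physical_activity(float("nan"), 0.0, 0.5) == MISSING

    def test_non_band_value_rejected(self):
        with pytest.raises(CodingError):
            classify_physical_activity(1.0, 0.0, 0.0)


class TestAlcohol:
    @pytest.mark.parametrize(
        "days,units,expected", [(0, 5, 0.0), (3, 2, 6.0), (7, 3, 21.0)]
    )
    def test_weekly_units(self, days, units, expected):
        assert weekly_alcohol_units(days, units) == expected

    def test_negative_rejected(self):
        with pytest.raises(CodingError):
            weekly_alcohol_units(3, -1)

    @pytest.mark.parametrize(
        "units,sex,expected",
        [
            (0, "female", "abstainer"),
            (10, "male", "light"),
            (10.5, "male", "moderate"),
            (21, "male", "moderate"),
            (22, "male", "heavy"),
            (7, "female", "light"),
            (14, "female", "moderate"),
            (15, "female", "heavy"),
            (float("nan"), "male", MISSING),
        ],
    )
    def test_sex_specific_cuts(self, units, sex, expected):
        assert classify_alcohol(units, sex) == expected

    @given(st.floats(min_value=0, max_value=200, allow_nan=False))
    def test_partition_of_nonnegative_axis(self, units):
        for sex in ("male", "female"):
            assert classify_alcohol(units, sex) in (
                "abstainer",
                "light",
                "moderate",
                "heavy",
            )


class TestBmi:
    def test_worked_example(self):
        # 58 kg at 1.70 m -> BMI 20.07 -> normal
        assert classify_bmi(58, 1.70) == "normal"

    @pytest.mark.parametrize(
        "bmi,expected",
        [(20.0, "underweight"), (25.0, "normal"), (30.0, "overweight"), (30.01, "obese")],
    )
    def test_boundaries_upper_inclusive(self, bmi, expected):
        assert classify_bmi(bmi, 1.0) == expected  # height 1 m keeps BMI exact

    def test_nonpositive_rejected(self):
        with pytest.raises(CodingError):
            classify_bmi(-60, 1.7)
        with pytest.raises(CodingError):
            classify_bmi(60, 0)

    def test_missing(self):
        assert classify_bmi(None, 1.7) == MISSING


class TestAdversityAndLifeEvents:
    @pytest.mark.parametrize(
        "items,n,expected",
        [
            ([0, 0, 0, 0], 4, "none"),
            ([1, 0, 0, 0], 4, "one_or_more"),
            ([0, None, 0], 3, MISSING),
            ([1, None, 0], 3, "one_or_more"),
            ([None, None, None], 3, MISSING),
        ],
    )
    def test_adversity(self, items, n, expected):
        assert code_adversity(items, n) == expected

    def test_wrong_length_rejected(self):
        with pytest.raises(CodingError):
            code_adversity([0, 0], 3)

    @pytest.mark.parametrize(
        "count,expected",
        [(0, "none"), (1, "one"), (2, "two_or_more"), (9, "two_or_more"), (None, MISSING)],
    )
    def test_life_events(self, count, expected):
        assert code_life_events(count) == expected

    def test_count_beyond_inventory_rejected(self):
        with pytest.raises(CodingError):
            code_life_events(10)


class TestCohortCoding:
    def test_every_coded_level_is_declared(self, small_cohort):
        from cvdineq.followup import apply_exclusions

        analytic, _ = apply_exclusions(small_cohort)  # drops missing-SEP rows
        coded = coding.code_cohort(analytic)
        for cov, levels in coding.COVARIATE_LEVELS.items():
            observed = set(coded[cov].astype(str).unique())
            assert observed <= set(levels), f"{cov}: {observed - set(levels)}"

    def test_coding_is_deterministic(self, small_cohort):
        a = coding.code_cohort(small_cohort.head(200))
        b = coding.code_cohort(small_cohort.head(200))
        pd.testing.assert_frame_equal(a, b)

    def test_strict_reader_reports_bad_tokens(self, tmp_path, small_cohort):
        bad = small_cohort.head(20).copy()
        bad.loc[bad.index[:3], "smoking_raw"] = "quit"
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(CodingError, match="smoking_raw"):
            coding.read_raw_cohort(path)

    def test_data_dictionary_references(self):
        dd = coding.data_dictionary()
        assert dd["marital"]["reference"] == "married"
        assert dd["adulthood_sep"]["reference"] == "4_high"
        assert dd["childhood_sep"]["reference"] == "professional"
        assert all(MISSING not in d["reference"] for d in dd.values())
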