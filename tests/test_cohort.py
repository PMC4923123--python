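"""Screening, derived physiology, fitness estimation and group summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from agefit.cohort import (
    COHORT_COLUMNS, apply_screening, categorize_activity, derive_physiology,
    estimate_ecrf, mean_resting_hr, met_to_vo2max, pooled_t_from_summaries,
    retained, summarize_groups,
)
from agefit.config import ECRFModel


def _row(**kw):
    base = dict(
        id="p1", age=70.0, gender="F", height=1.65, weight=70.0,
        resting_hr=72.0, low_exertion_min=60.0, aerobic_min=30.0,
        bdi=3.0, mmms=55.0, systolic=130.0, diastolic=80.0,
    )
    base.update(kw)
    return base


def _cohort(rows):
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


class TestScreening:
    @pytest.mark.parametrize(
        "bdi,mmms,out,reason",
        [
            (15, 55, True, "bdi"),          # above the depression cutoff
            (14, 52, False, ""),            # both boundaries retained
            (3, 51, True, "mmms"),          # at/below the mental-state cutoff
            (np.nan, 55, True, "incomplete"),
            (3, np.nan, True, "incomplete"),
        ],
    )
    def test_threshold_rules(self, bdi, mmms, out, reason):
        res = apply_screening(_cohort([_row(bdi=bdi, mmms=mmms)]))
        assert bool(res["screened_out"].iloc[0]) is out
        assert res["screen_reason"].iloc[0] == reason

    def test_pure_filter_keeps_retained_rows_identical(self, cohort54):
        screened = apply_screening(cohort54)
        kept = retained(screened).drop(columns=["screened_out", "screen_reason"])
        pd.testing.assert_frame_equal(
            kept, cohort54.loc[kept.index].drop(
                columns=["screened_out", "screen_reason"]
            ),
        )


class TestPhysiology:
    @pytest.mark.parametrize(
        "sys,dia,pp", [(139.33, 79.84, 59.49), (134.48, 78.72, 55.76), (100, 100, 0)]
    )
    def test_pulse_pressure(self, sys, dia, pp):
        res = derive_physiology(_cohort([_row(systolic=sys, diastolic=dia)]))
        assert res["pulse_pressure"].iloc[0] == pytest.approx(pp, abs=1e-9)

    def test_bmi(self):
        res = derive_physiology(_cohort([_row(height=2.0, weight=80.0)]))
        assert res["bmi"].iloc[0] == pytest.approx(20.0)

    def test_nonpositive_height_rejected(self):
        with pytest.raises(ValueError, match="height"):
            derive_physiology(_cohort([_row(height=0.0)]))

    def test_pulse_pressure_is_linear_in_group_means(self, cohort54):
        res = derive_physiology(cohort54)
        by_hand = res["systolic"].mean() - res["diastolic"].mean()
        assert res["pulse_pressure"].mean() == pytest.approx(by_hand, abs=1e-12)

    def test_mean_resting_hr(self):
        assert mean_resting_hr([60, 70, 80]) == 70.0
        with pytest.raises(ValueError):
            mean_resting_hr([])


class TestActivityCategory:
    def test_no_activity_is_lowest(self, ecrf_model):
        assert categorize_activity(0, 0, ecrf_model) == 1

    def test_heavy_aerobic_is_highest(self, ecrf_model):
        top = ecrf_model.activity_thresholds["aerobic_high"]
        assert categorize_activity(0, top + 1, ecrf_model) == 5

    def test_low_exertion_mid_band(self, ecrf_model):
        # the shipped config is the oracle: mid low-exertion band, no aerobic
        th = ecrf_model.activity_thresholds
        mid = (th["low_mid"] + th["low_high"]) / 2
        assert categorize_activity(mid, 0, ecrf_model) == 2

    @settings(deadline=None, max_examples=200)
    @given(
        low=st.floats(0, 1e4, allow_nan=False),
        aer=st.floats(0, 1e4, allow_nan=False),
    )
    def test_total_mapping(self, ecrf_model, low, aer):
        cat = categorize_activity(low, aer, ecrf_model)
        assert cat in (1, 2, 3, 4, 5)

    def test_negative_minutes_rejected(self, ecrf_model):
        with pytest.raises(ValueError):
            categorize_activity(-1, 0, ecrf_model)


class TestECRF:
    def _model(self, **kw):
        base = dict(
            intercept=0.0, coef_gender=0.0, coef_age=0.0, coef_bmi=0.0,
            coef_hr=0.0, coef_activity=(0.0,) * 5,
        )
        base.update(kw)
        return ECRFModel(**base)

    def test_all_zero_coefficients_return_intercept(self):
        row = pd.Series(_row() | {"bmi": 25.0})
        assert estimate_ecrf(row, self._model(intercept=7.5)) == 7.5

    def test_hand_dot_product(self):
        model = self._model(
            intercept=1.0, coef_gender=1.0, coef_age=1.0, coef_bmi=1.0,
            coef_hr=1.0, coef_activity=(0.0, 1.0, 2.0, 3.0, 4.0),
        )
        row = pd.Series(
            _row(gender="M", age=70.0, resting_hr=60.0,
                 low_exertion_min=0.0, aerobic_min=0.0) | {"bmi": 25.0}
        )
        # 1 + 1*1 + 70 + 25 + 60 + activity category 1 offset (0)
        assert estimate_ecrf(row, model) == pytest.approx(157.0)

    def test_higher_resting_hr_lowers_fitness(self):
        model = self._model(intercept=10.0, coef_hr=-0.03)
        lo = pd.Series(_row(resting_hr=60.0) | {"bmi": 25.0})
        hi = pd.Series(_row(resting_hr=80.0) | {"bmi": 25.0})
        assert estimate_ecrf(hi, model) < estimate_ecrf(lo, model)

    def test_missing_predictor_gives_nan(self, ecrf_model):
        row = pd.Series(_row() | {"bmi": np.nan})
        assert np.isnan(estimate_ecrf(row, ecrf_model))


class TestVO2max:
    @pytest.mark.parametrize("met,expected", [(6.58, 23.03), (7.88, 27.58), (0, 0)])
    def test_reference_conversions(self, met, expected):
        assert round(float(met_to_vo2max(met)), 2) == expected

    @settings(deadline=None, max_examples=100)
    @given(
        a=st.floats(-100, 100, allow_nan=False),
        b=st.floats(-100, 100, allow_nan=False),
        lam=st.floats(-10, 10, allow_nan=False),
    )
    def test_exact_linearity(self, a, b, lam):
        # linear up to float rounding of the sums/products themselves
        assert float(met_to_vo2max(a + b)) == pytest.approx(
            float(met_to_vo2max(a)) + float(met_to_vo2max(b)), rel=1e-12, abs=1e-12
        )
        assert float(met_to_vo2max(lam * a)) == pytest.approx(
            lam * float(met_to_vo2max(a)), rel=1e-12, abs=1e-12
        )


class TestGroupSummaries:
    def test_reproduces_printed_group_tests(self):
        # eCRF and age group summaries from the demographic table
        t_ecrf = pooled_t_from_summaries(7.88, 2.25, 27, 5.28, 1.97, 27)
        assert t_ecrf == pytest.approx(4.53, abs=0.02)
        t_age = pooled_t_from_summaries(70.20, 8.51, 27, 68.75, 8.51, 27)
        assert t_age == pytest.approx(0.63, abs=0.01)

    def test_hand_pooled_t(self):
        # means 0 vs 1, SDs 1, n = 2 per group -> t = 1
        assert pooled_t_from_summaries(1.0, 1.0, 2, 0.0, 1.0, 2) == pytest.approx(1.0)

    def test_identical_groups_give_t_zero(self):
        cohort = pd.DataFrame(
            [
                _row(id="a"), _row(id="b"), _row(id="c"), _row(id="d"),
            ]
        )
        cohort["y"] = [0.0, 1.0, 0.0, 1.0]
        design = pd.DataFrame(
            {"id": ["a", "b", "c", "d"], "fitness_score": [-1, -1, 1, 1]}
        )
        res = summarize_groups(cohort, design, variables=["y"])
        assert res.loc["y", "t"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_reported_undefined(self, cohort54, design54):
        cohort = cohort54.copy()
        cohort["flat"] = 5.0
        res = summarize_groups(cohort, design54, variables=["flat"])
        assert np.isnan(res.loc["flat", "t"])

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_textbook_formula(self, cohort54, design54, seed):
        rng = np.random.default_rng(seed)
        cohort = cohort54.copy()
        cohort["y"] = rng.normal(size=len(cohort))
        res = summarize_groups(cohort, design54, variables=["y"])
        row = res.loc["y"]
        sp2 = (
            (row["n_high"] - 1) * row["sd_high"] ** 2
            + (row["n_low"] - 1) * row["sd_low"] ** 2
        ) / (row["n_high"] + row["n_low"] - 2)
        t_hand = (row["mean_high"] - row["mean_low"]) / np.sqrt(
            sp2 * (1 / row["n_high"] + 1 / row["n_low"])
        )
        assert row["t"] == pytest.approx(t_hand, abs=1e-10)

    def test_gender_counts_attached(self, cohort54, design54):
        res = summarize_groups(cohort54, design54)
        counts = res.attrs["gender_counts"]
        total = sum(counts["low"].values()) + sum(counts["high"].values())
        assert total == len(retained(cohort54))
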