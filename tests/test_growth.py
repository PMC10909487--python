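"""Growth-rate arithmetic, segment dating, and the rate covariate model."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isolag import (
    GrowthRateRecord,
    HairRecord,
    count_days,
    covariate_model,
    date_segments,
    growth_rate,
    printed_summary,
    segment_count,
    summarize_rates,
)
from isolag.growth import truncate


class TestRateArithmetic:
    @pytest.mark.parametrize(
        "start,end,days",
        [
            (date(2013, 6, 8), date(2014, 7, 2), 389),
            (date(2017, 4, 27), date(2019, 6, 24), 788),
            (date(2020, 1, 1), date(2020, 1, 1), 0),
        ],
    )
    def test_count_days(self, start, end, days):
        assert count_days(start, end) == days

    def test_count_days_rejects_reversed_dates(self):
        with pytest.raises(ValueError):
            count_days(date(2020, 1, 2), date(2020, 1, 1))

    @pytest.mark.parametrize(
        "length,start,end,printed",
        [
            (200, date(2013, 6, 8), date(2014, 7, 2), 0.514),
            (320, date(2017, 4, 27), date(2019, 6, 24), 0.406),
            (168, date(2013, 6, 10), date(2014, 7, 6), 0.429),
        ],
    )
    def test_growth_rate_matches_printed_values(self, length, start, end, printed):
        assert truncate(growth_rate(length, start, end), 3) == printed

    def test_zero_day_interval_is_an_error(self):
        with pytest.raises(ValueError):
            growth_rate(100, date(2020, 1, 1), date(2020, 1, 1))

    @pytest.mark.parametrize("length,n", [(296, 37), (8, 1), (203, 25)])
    def test_segment_count_discards_distal_remainder(self, length, n):
        assert segment_count(length) == n


class TestRateSummary:
    def test_two_rates_hand_computed(self):
        s = summarize_rates([0.4, 0.6])
        assert s.mean == pytest.approx(0.5)
        assert s.sd == pytest.approx(0.1414, abs=1e-4)
        assert (s.min, s.max) == (0.4, 0.6)

    def test_identical_rates_have_zero_sd(self):
        assert summarize_rates([0.5, 0.5, 0.5]).sd == 0.0

    def test_single_record_rejected(self):
        with pytest.raises(ValueError):
            summarize_rates([0.5])

    def test_mean_lies_within_extremes(self, rng):
        rates = rng.uniform(0.3, 0.7, size=20)
        s = summarize_rates(rates)
        assert s.min <= s.mean <= s.max

    def test_printed_summary_truncates_display(self):
        # printed tables truncate decimals; 0.4898.. must display as 0.489-era
        s = printed_summary([0.4898, 0.4898, 0.6316])
        assert s.min == 0.48
        assert s.max == 0.63


class TestSegmentDating:
    def _record(self, length=200.0):
        return HairRecord(animal_id="a", start_date=date(2013, 6, 8),
                          end_date=date(2014, 7, 2), length_mm=length)

    def test_proximal_window_spans_16_days_at_half_mm_rate(self):
        w = date_segments(self._record(), rate=0.5)[0]
        assert w.t_start == pd.Timestamp("2014-06-16")
        assert w.t_end == pd.Timestamp("2014-07-02")

    def test_second_window_is_contiguous(self):
        w = date_segments(self._record(), rate=0.5)[1]
        assert w.t_start == pd.Timestamp("2014-05-31")
        assert w.t_end == pd.Timestamp("2014-06-16")

    def test_distal_window_reaches_start_when_rate_matches_length(self):
        # rate such that rate * growth_days = length: residual gap ~ 0
        rec = self._record()
        rate = rec.length_mm / 389
        windows = date_segments(rec, rate)
        gap_days = (windows[-1].t_start - pd.Timestamp(rec.start_date)) / pd.Timedelta(days=1)
        assert abs(gap_days) < 1e-6

    def test_rate_must_be_positive(self):
        with pytest.raises(ValueError):
            date_segments(self._record(), rate=0.0)

    @given(rate=st.floats(0.3, 0.7), length=st.integers(2, 40).map(lambda k: 8.0 * k))
    @settings(max_examples=50, deadline=None)
    def test_windows_are_contiguous_disjoint_and_equal(self, rate, length):
        rec = self._record(length=length)
        windows = date_segments(rec, rate)
        assert len(windows) == int(length // 8)
        durations = [w.duration_days for w in windows]
        # all durations equal 8/rate up to nanosecond rounding
        assert max(durations) - min(durations) < 1e-9
        assert durations[0] == pytest.approx(8.0 / rate, rel=1e-9)
        for a, b in zip(windows[1:], windows[:-1]):
            assert a.t_end == b.t_start  # shared boundary, exactly
        assert windows[0].t_end == pd.Timestamp(rec.end_date)


class TestCovariateModel:
    @staticmethod
    def _records(n, rng, lact=None, dry=None):
        out = []
        for i in range(n):
            days = int(rng.integers(360, 560))
            d = float(rng.uniform(80, 200)) if dry is None else dry * days
            if lact == "copy_dry":
                lac = d
            elif lact is None:
                lac = float(rng.choice([0, 120, 240]))
            else:
                lac = lact * days
            rate = float(rng.normal(0.51, 0.05))
            out.append(GrowthRateRecord(
                animal_id=f"a{i}", length_mm=rate * days, growth_days=days,
                rate_mm_per_day=rate, n_segments=int(rate * days // 8),
                days_dry=d, days_wet=days - d, days_lactating=lac))
        return out

    def test_null_effects_stay_null(self, rng):
        # rates independent of the covariates: no strong effect may appear
        table = covariate_model(self._records(50, rng))
        sub = table.loc[["prop_dry", "prop_lactating", "long_growth"]]
        assert (sub["p"] > 0.01).all()
        assert sub["t"].abs().max() < 3

    def test_perfectly_collinear_covariates_are_named(self, rng):
        recs = self._records(20, rng, lact="copy_dry")  # identical columns
        with pytest.raises(ValueError, match="prop_lactating"):
            covariate_model(recs)

    def test_constant_covariate_is_excluded_and_flagged(self, rng):
        recs = self._records(20, rng, lact=0.0)
        table = covariate_model(recs)
        assert np.isnan(table.loc["prop_lactating", "coef"])
        assert "prop_lactating" in table.attrs["excluded"]

    def test_too_few_records_rejected(self, rng):
        with pytest.raises(ValueError):
            covariate_model(self._records(3, rng))
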