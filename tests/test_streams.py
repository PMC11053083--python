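"""Stream containers, resampling, alignment and CSV round-trips."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heattwin.streams import (
    CountSeries,
    MeteoSample,
    StreamError,
    align,
    read_counts_csv,
    read_meteo_csv,
    resample_counts,
    resample_meteo,
    write_counts_csv,
    write_meteo_csv,
)

H = pd.Timedelta(hours=1)
T0 = pd.Timestamp("2020-08-16 00:00")


def make_samples(values, loc="a", interval_s=30, start=T0):
    return [
        MeteoSample(start + pd.Timedelta(seconds=i * interval_s), loc, t, rh)
        for i, (t, rh) in enumerate(values)
    ]


class TestResampleMeteo:
    def test_constant_hour_gives_one_bin_with_the_constant(self):
        samples = make_samples([(90.0, 60.0)] * 120)
        series = resample_meteo(samples, H)
        assert len(series) == 1
        assert series.frame["mean_temperature"].iloc[0] == pytest.approx(90.0)
        assert series.frame["mean_humidity"].iloc[0] == pytest.approx(60.0)

    def test_two_point_mean(self):
        samples = make_samples([(80.0, 50.0), (100.0, 70.0)])
        series = resample_meteo(samples, H)
        assert series.frame["mean_temperature"].iloc[0] == pytest.approx(90.0)
        assert series.frame["mean_humidity"].iloc[0] == pytest.approx(60.0)

    def test_linear_ramp_mean_matches_arithmetic_progression(self):
        # 70 -> 80 degF ramp sampled every 30 s across one hour: the bin
        # mean must equal the closed-form mean of the arithmetic progression
        n = 120
        temps = [70.0 + 10.0 * i / n for i in range(n)]
        expected = (temps[0] + temps[-1]) / 2
        samples = make_samples([(t, 50.0) for t in temps])
        series = resample_meteo(samples, H)
        assert series.frame["mean_temperature"].iloc[0] == pytest.approx(
            expected, abs=1e-9
        )

    def test_unsorted_input_is_rejected_with_diagnostic(self):
        samples = make_samples([(80.0, 50.0)] * 3)
        samples = [samples[1], samples[0], samples[2]]
        with pytest.raises(StreamError, match="not time-sorted"):
            resample_meteo(samples, H)

    def test_empty_input_gives_empty_series(self):
        assert len(resample_meteo([], H)) == 0

    def test_interior_empty_bin_is_a_gap_not_zero(self):
        samples = make_samples([(90.0, 60.0)], start=T0) + make_samples(
            [(92.0, 62.0)], start=T0 + pd.Timedelta(hours=2)
        )
        series = resample_meteo(samples, H)
        assert len(series) == 3
        assert np.isnan(series.frame["mean_temperature"].iloc[1])
        assert series.n_gaps == 1

    def test_mixed_locations_rejected(self):
        s = make_samples([(90.0, 60.0)], loc="a") + make_samples(
            [(90.0, 60.0)], loc="b", start=T0 + pd.Timedelta(minutes=1)
        )
        with pytest.raises(StreamError, match="one location"):
            resample_meteo(s, H)


def counts_series(values, loc="a", width=H, start=T0):
    idx = pd.date_range(start, periods=len(values), freq=width)
    return CountSeries(loc, width, pd.Series([float(v) for v in values], index=idx))


class TestResampleCounts:
    def test_hourly_to_four_hour_sum(self):
        out = resample_counts(counts_series([1, 2, 3, 4]), 4 * 3600)
        assert len(out) == 1
        assert out.counts.iloc[0] == 10.0

    def test_empty_input_empty_output(self):
        empty = CountSeries("a", H, pd.Series(dtype=float,
                                              index=pd.DatetimeIndex([])))
        assert len(resample_counts(empty, 4 * 3600)) == 0

    def test_non_multiple_width_rejected(self):
        with pytest.raises(StreamError, match="integer multiple"):
            resample_counts(counts_series([1, 2]), 5400)

    @settings(max_examples=30, deadline=None)
    @given(
        values=st.lists(st.integers(0, 500), min_size=1, max_size=168),
        factor=st.sampled_from([2, 3, 4, 6, 12, 24]),
    )
    def test_total_count_is_conserved_under_rebinning(self, values, factor):
        cs = counts_series(values)
        out = resample_counts(cs, factor * 3600)
        assert out.total == pytest.approx(cs.total)

    def test_mean_of_means_consistency_on_fully_populated_bins(self):
        # rebinning w -> 2w -> matches direct w -> 2w (sums compose)
        cs = counts_series(list(range(24)))
        via = resample_counts(resample_counts(cs, 2 * 3600), 4 * 3600)
        direct = resample_counts(cs, 4 * 3600)
        pd.testing.assert_series_equal(via.counts, direct.counts)


class TestAlign:
    def meteo(self, n, loc="a", start=T0):
        samples = make_samples([(90.0, 60.0)] * (n * 120), loc=loc, start=start)
        return resample_meteo(samples, H)

    def test_identical_grids_pair_every_bin(self):
        assert len(align(self.meteo(24), counts_series([1] * 24))) == 24

    def test_disjoint_ranges_align_to_empty(self):
        late = counts_series([1] * 4, start=T0 + pd.Timedelta(days=30))
        assert align(self.meteo(24), late).empty

    def test_partial_overlap_pairs_the_intersection(self):
        c = counts_series([1] * 12, start=T0 + pd.Timedelta(hours=12))
        assert len(align(self.meteo(24), c)) == 12

    def test_bin_width_mismatch_rejected(self):
        with pytest.raises(StreamError, match="mismatch"):
            align(self.meteo(24), counts_series([1] * 6, width=4 * H))

    def test_different_locations_share_nothing(self):
        assert align(self.meteo(24, loc="a"), counts_series([1] * 24, loc="b")).empty


class TestCsvRoundTrip:
    def test_meteo_round_trip_is_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        samples = make_samples(
            [(70 + 30 * rng.random(), 100 * rng.random()) for _ in range(10)]
        )
        path = tmp_path / "m.csv"
        write_meteo_csv(samples, path)
        back = read_meteo_csv(path)
        assert back == samples

    def test_counts_round_trip_is_identity(self, tmp_path):
        cs = counts_series([0, 3, 141, 7.5])
        path = tmp_path / "c.csv"
        write_counts_csv(cs, path)
        (back,) = read_counts_csv(path)
        assert back.location_id == cs.location_id
        assert back.bin_width == cs.bin_width
        pd.testing.assert_series_equal(
            back.counts, cs.counts, check_names=False, check_freq=False
        )

    def test_out_of_range_humidity_reported_with_row_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "time,location_id,temperature_f,relative_humidity_pct\n"
            "2020-08-16T00:00:00,a,90,50\n"
            "2020-08-16T00:00:30,a,90,150\n"
        )
        with pytest.raises(StreamError, match="row 2"):
            read_meteo_csv(path)

    def test_shuffled_rows_read_back_time_sorted(self, tmp_path):
        samples = make_samples([(80.0 + i, 50.0) for i in range(6)])
        shuffled = [samples[i] for i in [3, 0, 5, 1, 4, 2]]
        path = tmp_path / "s.csv"
        write_meteo_csv(shuffled, path)
        back = read_meteo_csv(path)
        assert back == sorted(samples, key=lambda s: s.time)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("time,location_id,temperature_f\n2020-08-16,a,90\n")
        with pytest.raises(StreamError, match="missing columns"):
            read_meteo_csv(path)


class TestInvariants:
    def test_sample_validation(self):
        with pytest.raises(StreamError):
            MeteoSample(T0, "a", 90.0, 101.0)
        with pytest.raises(StreamError):
            MeteoSample(T0, "a", float("nan"), 50.0)
        with pytest.raises(StreamError, match="unit error"):
            MeteoSample(T0, "a", 200.0, 50.0)

    def test_negative_counts_rejected(self):
        idx = pd.date_range(T0, periods=2, freq=H)
        with pytest.raises(StreamError, match="negative"):
            CountSeries("a", H, pd.Series([1.0, -1.0], index=idx))
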