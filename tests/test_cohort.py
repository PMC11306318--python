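"""Person-day aggregation, imputation, summaries and histograms."""

import math
from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from h2sindex import (
    DailyExposure,
    DayClassification,
    ExposureConstants,
    GasLog,
    StudyDataset,
    aggregate_person_day,
    dataset_to_frame,
    histogram_bins,
    impute_censored,
    index_twa_table,
    read_dataset_csv,
    season_of,
    summarize_dataset,
    write_dataset_csv,
)
from h2sindex.cohort import BandProfile
from h2sindex.errors import ConfigError
from h2sindex.gaslog import round_half_away

from conftest import make_log

BC = ExposureConstants(lod_ppm=1.6)


def make_dataset(days=(), label="C", **kwargs):
    kwargs.setdefault("n_persons", max(1, len({d.person_id for d in days}) or 1))
    return StudyDataset(label=label, days=list(days), **kwargs)


def exposure_day(index=2.725, max_ppm=1.6, censored=False, status="measured",
                 person="p1", d=date(2019, 6, 10), seg="water_network"):
    return DailyExposure(
        person_id=person,
        date=d,
        seg=seg,
        season=season_of(d),
        profile=BandProfile(max_ppm=max_ppm),
        index=index,
        cv_exceeded=max_ppm > 10.0,
        censored=censored,
        status=DayClassification(status),
    )


class TestAggregate:
    def test_single_lod_reading(self):
        day = aggregate_person_day([make_log([1.6])], constants=BC)
        assert day.index == pytest.approx(2.725)
        assert not day.censored
        assert day.n_positive_readings == 1

    def test_below_lod_day_is_censored(self):
        day = aggregate_person_day([make_log([0.0, 1.5, 0.0])], constants=BC)
        assert day.censored
        assert day.index == 0.0  # pre-imputation; sub-LOD readings are not trusted

    def test_alarm_only_log_sets_ceiling_flag(self):
        alarm = GasLog(
            person_id="p",
            alarm_times=np.array(["2019-06-10T10:00:00"], dtype="datetime64[s]"),
            alarm_ppm=np.array([29.0]),
        )
        day = aggregate_person_day([make_log([0.0, 0.0], person_id="p", start="2019-06-10T08:00:00"), alarm],
                                   constants=BC)
        assert day.cv_exceeded
        assert not day.censored

    def test_permutation_invariance(self):
        a = make_log([1.6, 0.0], start="2019-06-10T08:00:00")
        b = make_log([0.0, 5.2], start="2019-06-10T10:00:00")
        d1 = aggregate_person_day([a, b], constants=BC)
        d2 = aggregate_person_day([b, a], constants=BC)
        assert d1.index == d2.index
        assert d1.profile == d2.profile

    def test_duplicate_timestamps_resolved_by_max(self):
        a = make_log([1.6], start="2019-06-10T08:00:00")
        b = make_log([5.2], start="2019-06-10T08:00:00")
        day = aggregate_person_day([a, b], constants=BC)
        assert day.profile.max_ppm == 5.2

    def test_mixed_persons_rejected(self):
        with pytest.raises(ConfigError):
            aggregate_person_day(
                [make_log([1.6], person_id="p1"), make_log([1.6], person_id="p2")]
            )

    def test_mixed_dates_rejected(self):
        with pytest.raises(ConfigError):
            aggregate_person_day(
                [
                    make_log([1.6], start="2019-06-10T08:00:00"),
                    make_log([1.6], start="2019-06-11T08:00:00"),
                ]
            )


class TestImpute:
    def test_censored_days_get_lowest_index_constant(self):
        ds = make_dataset([exposure_day(index=0.0, max_ppm=0.0, censored=True)], lod_ppm=1.6)
        out = impute_censored(ds)
        assert round_half_away(out.days[0].index, 3) == 1.927
        assert out.days[0].imputed

    def test_real_zero_untouched_and_out_of_model_frame(self):
        ds = make_dataset(
            [
                exposure_day(index=0.0, max_ppm=0.0, censored=True, status="real_zero"),
                exposure_day(index=5.0, max_ppm=3.0),
            ]
        )
        out = impute_censored(ds)
        assert out.days[0].index == 0.0
        assert not out.days[0].imputed
        assert len(out.model_frame()) == 1

    def test_idempotent_and_noop_without_censoring(self):
        ds = make_dataset([exposure_day(index=5.0, max_ppm=3.0)])
        once = impute_censored(ds)
        twice = impute_censored(once)
        assert [d.index for d in twice.days] == [d.index for d in once.days] == [5.0]


class TestSummarize:
    def test_expert_campaign_workday_arithmetic(self):
        # 35 measurement days, 149 persons, 19 months
        ds = make_dataset([], label="A", n_persons=149, months=19.0, lod_ppm=0.1)
        row = summarize_dataset(ds, n_measured=35, n_detect=25, n_cv=8, n_over100=1)
        assert 35 * 149 == 5215
        assert row.duration_workdays == 51902
        assert row.pct_detect_of_measured == 71  # 25/35 of its own N
        assert row.pct_cv_of_detect == 32

    def test_routine_collection_arithmetic(self):
        # 1559 measurement days, 60 persons, 5.5 years
        ds = make_dataset([], label="B", n_persons=60, months=66.0)
        row = summarize_dataset(ds, n_measured=1559, n_detect=1295 * 1559 // 7083,
                                n_cv=0, n_over100=3)
        assert row.study_workdays == 1559 * 60 == 93540
        assert row.duration_workdays == 72600

    def test_daily_campaign_arithmetic(self):
        ds = make_dataset([], label="C", n_persons=60, months=7.0, frame_workdays=1807)
        row = summarize_dataset(ds, n_measured=872, n_detect=522, n_cv=118, n_over100=0)
        assert row.duration_workdays == 7700
        assert row.pct_detect_of_measured == 60
        assert row.pct_cv_of_measured == 14
        assert row.pct_cv_of_detect == 23
        assert row.pct_measured_of_study_workdays == 48

    def test_no_detects_leaves_cv_share_empty(self):
        ds = make_dataset([exposure_day(index=0.0, max_ppm=0.0, censored=True)])
        row = summarize_dataset(ds)
        assert row.n_detect == 0
        assert row.pct_cv_of_detect is None

    def test_nonpositive_months_rejected(self):
        with pytest.raises(ConfigError):
            summarize_dataset(make_dataset([], months=0.0))


class TestHistogram:
    @pytest.mark.parametrize(
        "value,lo,hi",
        [
            (1.7, 1.6, 2.0),
            (2.0, 1.6, 2.0),
            (7.3, 7.0, 8.0),
            (10.0, 9.0, 10.0),   # the ceiling value closes its bin
            (10.1, 10.0, 20.0),
            (100.0, 90.0, 100.0),
        ],
    )
    def test_bin_rule(self, value, lo, hi):
        h = histogram_bins([value])
        i = h.counts.index(1)
        assert (h.bin_edges[i], h.bin_edges[i + 1]) == (lo, hi)

    def test_overload_bin(self):
        h = histogram_bins([100.5])
        assert h.overload_count == 1
        assert sum(h.counts) == 0

    def test_at_or_below_floor_rejected(self):
        h = histogram_bins([1.6, 0.5])
        assert h.rejected_count == 2

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=150.0,
                              allow_nan=False, allow_infinity=False), max_size=100))
    def test_conservation(self, values):
        h = histogram_bins(values)
        assert sum(h.counts) + h.overload_count + h.rejected_count == len(values)


class TestIndexTwaTable:
    def test_collinear_rows_fit_perfectly(self):
        days = []
        for k, twa in enumerate([0.001, 0.01, 0.1], start=1):
            d = exposure_day(index=10.0 * twa, max_ppm=2.0, person=f"p{k}")
            d.twa_ppm = twa
            days.append(d)
        _, fits = index_twa_table(days)
        assert fits["all"]["r2"] == pytest.approx(1.0)

    def test_single_row_skips_fit(self):
        d = exposure_day()
        d.twa_ppm = 0.001
        _, fits = index_twa_table([d])
        assert "note" in fits["all"]

    def test_censored_only_dataset_full_table_empty_fit(self):
        d = exposure_day(index=0.0, max_ppm=0.0, censored=True)
        d.twa_ppm = 0.0
        table, fits = index_twa_table([d])
        assert len(table) == 1
        assert fits["excluded_rows"]["n"] == 1
        assert "note" in fits["all"]


class TestSeasonAndRoundtrip:
    @pytest.mark.parametrize(
        "d,season",
        [
            (date(2019, 2, 15), "winter"),
            (date(2019, 6, 10), "summer"),
            (date(2019, 9, 1), "autumn"),
            (date(2019, 5, 31), "spring"),
        ],
    )
    def test_season_mapping(self, d, season):
        assert season_of(d) == season

    def test_csv_roundtrip(self, tmp_path):
        ds = make_dataset(
            [
                exposure_day(index=2.725, max_ppm=1.6),
                exposure_day(index=0.0, max_ppm=0.0, censored=True, person="p2"),
            ],
            months=7.0,
            frame_workdays=100,
        )
        path = tmp_path / "ds.csv"
        write_dataset_csv(ds, path)
        back = read_dataset_csv(path)
        assert back.label == ds.label
        assert back.frame_workdays == 100
        f1, f2 = dataset_to_frame(ds), dataset_to_frame(back)
        for col in ("person_id", "index", "max_ppm", "censored", "status"):
            assert list(f1[col]) == list(f2[col])
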