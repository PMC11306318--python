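"""Gas-log parsing, excursion detection, band profiles and the index."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from h2sindex import (
    DATASET_A_CONSTANTS,
    DATASET_BC_CONSTANTS,
    GasLog,
    band_profile,
    compute_index,
    compute_twa,
    detect_excursions,
    exceeds_ceiling,
    imputation_constant,
    lowest_index_at_lod,
    parse_gas_log,
)
from h2sindex.errors import (
    ConfigError,
    OrderingError,
    ParseError,
    UndefinedStatisticError,
)
from h2sindex.gaslog import round_half_away

from conftest import make_log

# ---------------------------------------------------------------------------
# Independent oracle: a from-first-principles recomputation of the index that
# shares no code with the implementation (explicit state-machine scan).


def oracle_index(values, interval_s=15.0, mode="cumulative"):
    runs = []
    current = []
    for v in values:
        if v >= 0.1 - 1e-12:
            current.append(v)
        else:
            if current:
                runs.append(current)
            current = []
    if current:
        runs.append(current)
    if not runs:
        return 0.0
    n01 = n1 = n5 = n10 = 0
    for run in runs:
        peak = max(run)
        crossed = []
        if peak >= 0.1 - 1e-12:
            crossed.append("01")
        if peak >= 1.1 - 1e-12:
            crossed.append("1")
        if peak >= 5.1 - 1e-12:
            crossed.append("5")
        if peak >= 10.1 - 1e-12:
            crossed.append("10")
        if mode == "max_band":
            crossed = crossed[-1:]
        n01 += "01" in crossed
        n1 += "1" in crossed
        n5 += "5" in crossed
        n10 += "10" in crossed
    dur01 = sum(1 for v in values if 0.1 - 1e-12 <= v <= 5.0 + 1e-12) * interval_s / 60.0
    dur5 = sum(1 for v in values if v > 5.0 + 1e-12) * interval_s / 60.0
    mx = max(values)
    return 0.1 * n01 + 0.1 * dur01 + n1 + 5 * n5 + 5 * dur5 + 10 * n10 + mx


grid_ppm = st.integers(min_value=0, max_value=1000).map(lambda k: k / 10.0)
small_logs = st.lists(grid_ppm, min_size=1, max_size=50)


# ---------------------------------------------------------------------------
# Parsing


class TestParse:
    def test_three_line_echo(self):
        text = (
            "person_id,device_id,timestamp,ppm,flag\n"
            "p1,d1,2019-02-04T08:00:00,0.0,\n"
            "p1,d1,2019-02-04T08:00:15,1.6,\n"
            "p1,d1,2019-02-04T08:00:30,0.0,\n"
        )
        log = parse_gas_log(text)
        assert len(log) == 3
        assert log.person_id == "p1"
        np.testing.assert_allclose(log.ppm, [0.0, 1.6, 0.0])

    def test_zero_skip_gap_refilled(self):
        # two blocks 120 s apart -> 120/15 - 1 = 7 zeros reinstated
        text = (
            "p,d,2019-02-04T08:00:00,1.6,\n"
            "p,d,2019-02-04T08:02:00,1.7,\n"
        )
        log = parse_gas_log(text)
        assert len(log) == 9
        assert (log.ppm[1:-1] == 0.0).all()
        assert log.segment_breaks == ()

    def test_long_gap_splits_segments(self):
        text = (
            "p,d,2019-02-04T08:00:00,1.6,\n"
            "p,d,2019-02-04T13:00:00,1.6,\n"
        )
        log = parse_gas_log(text)
        assert len(log) == 2
        assert log.segment_breaks == (1,)
        # the two readings must be two excursions, not one joined run
        assert len(detect_excursions(log)) == 2

    def test_backwards_timestamp_rejected(self):
        text = (
            "p,d,2019-02-04T08:00:15,0.5,\n"
            "p,d,2019-02-04T08:00:00,0.5,\n"
        )
        with pytest.raises(OrderingError):
            parse_gas_log(text)

    def test_malformed_timestamp_names_line(self):
        text = "p,d,not-a-time,0.5,\n"
        with pytest.raises(ParseError, match="line 1"):
            parse_gas_log(text)

    def test_alarm_rows_become_single_datapoints(self):
        text = "p,d,2019-02-04T10:00:00,29.0,ALARM\n"
        log = parse_gas_log(text)
        assert len(log) == 0
        assert log.alarm_ppm.tolist() == [29.0]


# ---------------------------------------------------------------------------
# Excursions and band profiles


class TestExcursions:
    def test_all_zero_gives_none(self):
        assert detect_excursions(make_log([0.0, 0.0, 0.0])) == []

    def test_single_reading_excursion_and_bands(self):
        (exc,) = detect_excursions(make_log([0.0, 1.6, 0.0]))
        assert (exc.start_index, exc.end_index, exc.n_readings) == (1, 1, 1)
        assert exc.peak_ppm == 1.6
        assert exc.bands_crossed == frozenset({"B01", "B1"})

    def test_subthreshold_run_separates_excursions(self):
        excs = detect_excursions(make_log([0.0, 1.6, 0.0, 0.0, 1.6, 0.0]))
        assert len(excs) == 2

    def test_dip_within_band_is_one_peak(self):
        # 12 -> 6 -> 12 never drops below the floor: a single excursion
        excs = detect_excursions(make_log([0.0, 12.0, 6.0, 12.0, 0.0]))
        assert len(excs) == 1
        assert band_profile(make_log([0.0, 12.0, 6.0, 12.0, 0.0])).h2s10 == 1


class TestBandProfile:
    def test_single_lod_reading_cumulative(self):
        p = band_profile(make_log([1.6]), mode="cumulative")
        assert (p.h2s01, p.h2s1, p.h2s5, p.h2s10) == (1, 1, 0, 0)
        assert p.duration01_min == pytest.approx(0.25)
        assert p.max_ppm == 1.6

    def test_single_lod_reading_max_band(self):
        p = band_profile(make_log([1.6]), mode="max_band")
        assert (p.h2s01, p.h2s1) == (0, 1)

    def test_above_five_counts_only_duration5(self):
        p = band_profile(make_log([10.1]))
        assert p.duration01_min == 0.0
        assert p.duration5_min == pytest.approx(0.25)
        assert p.max_ppm == 10.1

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            band_profile(make_log([1.6]), mode="median_band")


# ---------------------------------------------------------------------------
# Index


class TestIndex:
    def test_all_censored_profile_is_zero(self):
        assert compute_index(band_profile(make_log([0.0, 0.0]))) == 0.0

    @pytest.mark.parametrize(
        "values,mode,expected",
        [
            ([1.6], "cumulative", 2.725),
            ([10.1], "cumulative", 27.45),
            ([0.0, 1.6, 0.0, 0.0, 1.6, 0.0], "cumulative", 3.85),
            ([1.6], "max_band", 2.625),
        ],
    )
    def test_hand_computed_examples(self, values, mode, expected):
        idx = compute_index(band_profile(make_log(values), mode=mode))
        assert idx == pytest.approx(expected, abs=1e-9)

    def test_imputation_constant_bc(self):
        # lowest index at the 1.6 ppm LOD with 15-s sampling, over sqrt(2)
        assert lowest_index_at_lod(DATASET_BC_CONSTANTS) == pytest.approx(2.725)
        c = imputation_constant(DATASET_BC_CONSTANTS)
        assert round_half_away(c, 3) == 1.927

    def test_imputation_constant_max_band_differs(self):
        assert lowest_index_at_lod(DATASET_BC_CONSTANTS, mode="max_band") == pytest.approx(2.625)
        c = imputation_constant(DATASET_BC_CONSTANTS, mode="max_band")
        assert round_half_away(c, 3) == 1.856

    @pytest.mark.parametrize("interval_s", [15.0, 30.0, 60.0, 120.0])
    def test_lowest_index_at_01_lod_symbolic(self, interval_s):
        # one reading at 0.1 ppm: 0.1 (peak) + 0.1*t/60 (duration) + 0.1 (max)
        got = lowest_index_at_lod(DATASET_A_CONSTANTS, interval_s=interval_s)
        assert got == pytest.approx(0.2 + 0.1 * interval_s / 60.0)


# ---------------------------------------------------------------------------
# TWA and ceiling


class TestTwaCeiling:
    def test_single_reading_twa(self):
        twa = compute_twa(make_log([1.6]), DATASET_BC_CONSTANTS)
        assert twa == pytest.approx(1.6 * 0.25 / 480.0)
        assert twa < 0.1  # below the instrument's displayable TWA floor

    def test_constant_full_shift(self):
        log = make_log([5.0] * 1920)  # 480 min at 15 s
        assert compute_twa(log, DATASET_BC_CONSTANTS) == pytest.approx(5.0)

    def test_all_zero_twa(self):
        assert compute_twa(make_log([0.0, 0.0]), DATASET_BC_CONSTANTS) == 0.0

    def test_empty_log_twa_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            compute_twa(GasLog(person_id="p"), DATASET_BC_CONSTANTS)

    @pytest.mark.parametrize("peak,expected", [(10.0, False), (10.1, True)])
    def test_ceiling_exceedance_is_strict(self, peak, expected):
        assert exceeds_ceiling(make_log([peak])) is expected

    def test_alarm_only_point_counts_toward_ceiling(self):
        log = GasLog(
            person_id="p",
            alarm_times=np.array(["2019-02-04T10:00:00"], dtype="datetime64[s]"),
            alarm_ppm=np.array([29.0]),
        )
        assert exceeds_ceiling(log)
        assert band_profile(log).max_ppm == 29.0


# ---------------------------------------------------------------------------
# Properties


class TestProperties:
    @settings(max_examples=200, deadline=None)
    @given(small_logs)
    def test_oracle_equivalence(self, values):
        """compute_index equals an independent first-principles scan."""
        log = make_log(values)
        for mode in ("cumulative", "max_band"):
            got = compute_index(band_profile(log, mode=mode))
            want = oracle_index(values, mode=mode)
            assert got == pytest.approx(want, abs=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(small_logs)
    def test_duration_conservation(self, values):
        p = band_profile(make_log(values))
        n_detected = sum(1 for v in values if v >= 0.1 - 1e-12)
        assert p.duration01_min + p.duration5_min == pytest.approx(n_detected * 0.25, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(small_logs, st.data())
    def test_monotonicity_in_detected_readings(self, values, data):
        """Raising a reading that is already at/above the detection floor
        cannot change the run structure, so the index never decreases."""
        detected = [i for i, v in enumerate(values) if v >= 0.1]
        if not detected:
            return
        i = data.draw(st.sampled_from(detected))
        bumped = list(values)
        bumped[i] = min(bumped[i] + data.draw(st.integers(1, 100)) / 10.0, 100.0)
        for mode in ("cumulative", "max_band"):
            before = compute_index(band_profile(make_log(values), mode=mode))
            after = compute_index(band_profile(make_log(bumped), mode=mode))
            assert after >= before - 1e-9

    def test_merging_two_peaks_can_lower_the_index(self):
        """Characterization: the index is deliberately peak-count sensitive,
        so filling the gap between two excursions merges them and can lower
        the value (two 0.1-ppm peaks pay 0.1 each; the merged run pays once)."""
        two_peaks = compute_index(band_profile(make_log([0.0, 0.0, 0.1, 0.0, 0.1])))
        merged = compute_index(band_profile(make_log([0.0, 0.0, 0.1, 0.1, 0.1])))
        assert two_peaks == pytest.approx(0.35)
        assert merged == pytest.approx(0.275)
        assert merged < two_peaks

    @settings(max_examples=100, deadline=None)
    @given(small_logs)
    def test_dominance_and_mode_ordering(self, values):
        log = make_log(values)
        cum = compute_index(band_profile(log, mode="cumulative"))
        mb = compute_index(band_profile(log, mode="max_band"))
        assert cum >= mb - 1e-9
        if max(values) >= 0.1:
            assert cum >= max(values)

    @settings(max_examples=100, deadline=None)
    @given(small_logs)
    def test_ceiling_iff_top_band_peak(self, values):
        log = make_log(values)  # no alarm-only points
        assert exceeds_ceiling(log) == (band_profile(log).h2s10 >= 1)
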