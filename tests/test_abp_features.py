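from datetime import datetime

import pytest

from abpauto import errors
from abpauto.abp_features import (
    FeatureConfig,
    classify_office_oh,
    detect_circadian_reversal,
    detect_noncompensatory_hr,
    detect_postprandial_hypotension,
    segment_day_night,
    summarize_abp,
)
from abpauto.io_formats import OfficeBPRecord
from conftest import event, make_trace

CFG = FeatureConfig()


def office(sup_sbp, sup_dbp, stand_sbp, stand_dbp, minutes=1.0):
    return [
        OfficeBPRecord("S1", "supine", sup_sbp, sup_dbp),
        OfficeBPRecord("S1", "standing", stand_sbp, stand_dbp,
                       minutes_after_standing=minutes),
    ]


class TestOfficeOH:
    @pytest.mark.parametrize(
        "records,expect_oh,expect_dsbp,expect_ddbp",
        [
            (office(152, 84, 115, 61), True, 37, 23),   # cohort's printed office means
            (office(120, 80, 110, 75), False, 10, 5),   # both falls below threshold
            (office(120, 80, 108, 70), True, 12, 10),   # diastolic criterion, inclusive
            (office(140, 80, 120, 75), True, 20, 5),    # systolic criterion, inclusive
        ],
    )
    def test_threshold_rule_on_means(self, records, expect_oh, expect_dsbp, expect_ddbp):
        res = classify_office_oh(records, CFG)
        assert res.is_oh is expect_oh
        assert res.delta_sbp == pytest.approx(expect_dsbp)
        assert res.delta_dbp == pytest.approx(expect_ddbp)

    def test_means_over_multiple_readings(self):
        records = [
            OfficeBPRecord("S1", "supine", 150, 84),
            OfficeBPRecord("S1", "sitting", 154, 84),
            OfficeBPRecord("S1", "standing", 120, 70, minutes_after_standing=1),
            OfficeBPRecord("S1", "standing", 140, 78, minutes_after_standing=3),
        ]
        res = classify_office_oh(records, CFG)
        assert res.delta_sbp == pytest.approx(22)
        assert res.is_oh and res.per_reading_flags == (True, False)

    def test_late_standing_reading_excluded(self):
        records = office(152, 84, 115, 61, minutes=4.0)
        with pytest.raises(errors.UnevaluableError, match="standing"):
            classify_office_oh(records, CFG)

    def test_no_baseline_reading(self):
        records = [OfficeBPRecord("S1", "standing", 115, 61, minutes_after_standing=1)]
        with pytest.raises(errors.UnevaluableError, match="supine"):
            classify_office_oh(records, CFG)


class TestSegmentDayNight:
    def trace(self):
        # hourly readings 07:00 day 1 .. 06:00 day 2
        return make_trace([(130, 80, 70)] * 24, step_min=60)

    def test_half_open_night_window(self):
        events = [event("sleep", 23), event("wake", 7, day=2)]
        day, night, used_default = segment_day_night(self.trace(), events, CFG)
        night_times = {r.time for r in night}
        assert datetime(2016, 3, 1, 23, 0) in night_times      # sleep instant is night
        assert datetime(2016, 3, 2, 6, 0) in night_times
        assert all(r.time < datetime(2016, 3, 2, 7, 0) for r in night)
        assert not used_default and len(day) + len(night) == 24

    def test_wake_before_sleep_is_inconsistent(self):
        events = [event("sleep", 23), event("wake", 7, day=1)]
        with pytest.raises(errors.JournalInconsistencyError):
            segment_day_night(self.trace(), events, CFG)

    def test_default_window_with_warning(self):
        with pytest.warns(UserWarning, match="default"):
            day, night, used_default = segment_day_night(self.trace(), [], CFG)
        assert used_default
        assert datetime(2016, 3, 2, 3, 0) in {r.time for r in night}
        assert datetime(2016, 3, 2, 6, 0) in {r.time for r in day}  # wake boundary


class TestCircadianReversal:
    def trace(self, day_sbp, night_sbp):
        rows = [(day_sbp, 80, 70)] * 16 + [(night_sbp, 75, 65)] * 8
        return make_trace(rows, step_min=60)

    EVENTS = [event("sleep", 23), event("wake", 7, day=2)]

    @pytest.mark.parametrize(
        "day_sbp,night_sbp,expected",
        [(130, 131, True), (130, 130, True), (130, 115, False)],
    )
    def test_inclusive_rule(self, day_sbp, night_sbp, expected):
        res = detect_circadian_reversal(self.trace(day_sbp, night_sbp), self.EVENTS, CFG)
        assert res.reversed is expected
        assert res.day_mean == pytest.approx(day_sbp)
        assert res.night_mean == pytest.approx(night_sbp)

    def test_small_segment_unevaluable(self):
        rows = [(130, 80, 70)] * 16 + [(120, 75, 65)] * 2
        trace = make_trace(rows, step_min=60)
        with pytest.raises(errors.UnevaluableError):
            detect_circadian_reversal(trace, self.EVENTS, CFG)

    def test_map_component(self):
        # SBP says reversal, MAP does not: night has much lower DBP
        rows = [(130, 90, 70)] * 16 + [(131, 60, 65)] * 8
        trace = make_trace(rows, step_min=60)
        sbp_res = detect_circadian_reversal(trace, self.EVENTS, CFG)
        map_res = detect_circadian_reversal(trace, self.EVENTS, CFG, component="map")
        assert sbp_res.reversed and not map_res.reversed
        assert map_res.night_mean == pytest.approx((131 + 2 * 60) / 3)


class TestPostprandialHypotension:
    def trace_with_drop(self, baseline, minimum):
        # readings every 15 min from 11:00; meal at 12:00; min at 12:45
        rows = []
        for i in range(12):
            sbp = minimum if i == 7 else baseline
            rows.append((240 + i * 15, sbp, 80, 70))  # offsets from 07:00 -> 11:00
        return make_trace(rows)

    MEAL = [event("meal", 12)]

    @pytest.mark.parametrize(
        "baseline,minimum,drop,expected",
        [(140, 118, 22, True), (140, 121, 19, False), (140, 120, 20, True)],
    )
    def test_drop_thresholds(self, baseline, minimum, drop, expected):
        res = detect_postprandial_hypotension(
            self.trace_with_drop(baseline, minimum), self.MEAL, CFG
        )
        assert res.pph is expected
        (meal,) = [w for w in res.per_meal if w.evaluable]
        assert meal.drop == pytest.approx(drop)
        assert meal.baseline_sbp == pytest.approx(baseline)

    def test_meal_without_post_readings_skipped(self):
        # two meals; second has no readings in its 75-min window
        trace = self.trace_with_drop(140, 118)  # readings end 13:45
        meals = [event("meal", 12), event("meal", 18)]
        res = detect_postprandial_hypotension(trace, meals, CFG)
        assert res.pph and res.n_evaluable == 1
        assert [w.evaluable for w in res.per_meal] == [True, False]

    def test_stale_baseline_not_used(self):
        # only pre-meal reading is 5 h before the meal -> no baseline -> unevaluable
        rows = [(0, 140, 80, 70), (330, 120, 80, 70), (345, 118, 80, 70)]
        trace = make_trace(rows)  # 07:00, then 12:30/12:45 after the 12:00 meal
        with pytest.raises(errors.UnevaluableError):
            detect_postprandial_hypotension(trace, self.MEAL, CFG)

    def test_no_meals_is_an_error(self, flat_trace):
        with pytest.raises(errors.UnevaluableError, match="meal"):
            detect_postprandial_hypotension(flat_trace, [], CFG)


class TestNoncompensatoryHR:
    def pair(self, sbp1, sbp2, dbp1, dbp2, hr1, hr2):
        return make_trace([(sbp1, dbp1, hr1), (sbp2, dbp2, hr2)])

    @pytest.mark.parametrize(
        "trace_args,abnormal,n_episodes",
        [
            ((150, 125, 85, 80, 70, 76), True, 1),    # SBP -25, HR +6 -> cond 1 fails
            ((150, 125, 85, 80, 70, 85), False, 1),   # SBP -25, HR +15 -> compensated
            ((150, 148, 85, 72, 70, 70), True, 1),    # DBP -13, HR +0 -> cond 2 fails
            ((150, 130, 85, 80, 70, 70), False, 0),   # SBP -20 exactly: not triggered
            ((150, 148, 85, 75, 70, 70), False, 0),   # DBP -10 exactly: not triggered
            ((150, 148, 85, 72, 70, 72), False, 1),   # DBP -13, HR +2 -> compensated
        ],
    )
    def test_adjacent_pair_rules(self, trace_args, abnormal, n_episodes):
        res = detect_noncompensatory_hr(self.pair(*trace_args), CFG)
        assert res.hrv_abnormal is abnormal
        assert res.n_episodes == n_episodes

    def test_single_reading_unevaluable(self):
        with pytest.raises(errors.UnevaluableError):
            detect_noncompensatory_hr(make_trace([(130, 80, 70)]), CFG)

    def test_pair_triggering_both_conditions(self):
        res = detect_noncompensatory_hr(self.pair(150, 125, 85, 70, 70, 76), CFG)
        assert res.n_episodes == 1 and len(res.episodes) == 2
        assert {e.condition for e in res.episodes} == {1, 2}
        # cond 1 fails (HR rise 6 < 10) but cond 2 is compensated (rise >= 1)
        assert [e.noncompensatory for e in sorted(res.episodes,
                                                  key=lambda e: e.condition)] == [True, False]


class TestSummary:
    @pytest.mark.parametrize("flags,total", [((True, True, True), 3),
                                             ((False, False, False), 0),
                                             ((True, False, True), 2)])
    def test_abp_total_is_component_sum(self, flags, total):
        rev, pph, hrv = flags
        from abpauto.abp_features import (CircadianResult, CompensationResult,
                                          PostprandialResult)
        c = CircadianResult(130, 131 if rev else 120, "systolic", rev, 10, 5, False)
        p = PostprandialResult((), pph, 1)
        h = CompensationResult((), hrv, int(hrv))
        s = summarize_abp(None, c, p, h, {"is_oh": "no office readings"})
        assert s.abp_total == total
        assert s.is_oh is None and s.delta_oh is None
        assert s.missing == {"is_oh": "no office readings"}

    def test_missing_component_undefines_total(self):
        from abpauto.abp_features import CompensationResult, PostprandialResult
        s = summarize_abp(None, None, PostprandialResult((), True, 1),
                          CompensationResult((), False, 0),
                          {"reversed": "segment too small"})
        assert s.abp_total is None and s.pph is True and s.reversed is None
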