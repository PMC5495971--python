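from datetime import date, datetime, timedelta

import numpy as np
import pytest

from glucolog.core import Reading, SevereHypoReport, Thresholds, ValidationError
from glucolog.outcomes import (
    count_mild_hypo,
    count_severe_hypo,
    group_smbg,
    mean_daily_smbg,
    tally_adjustments,
)
from helpers import R, make_window, union_find_hypo_episodes


def low_window(*times):
    return make_window([R(t, 3.0) for t in times])


class TestCountMildHypo:
    def test_same_hour_slot_is_one_episode(self):
        count, eps = count_mild_hypo(low_window("2014-03-01T02:10", "2014-03-01T02:50"))
        assert count == 1
        assert eps[0].min_value == 3.0

    def test_chained_consecutive_slots_one_episode(self):
        count, _ = count_mild_hypo(
            low_window("2014-03-01T02:10", "2014-03-01T03:40", "2014-03-01T04:15")
        )
        assert count == 1

    def test_two_slot_gap_splits_episodes(self):
        count, _ = count_mild_hypo(low_window("2014-03-01T02:10", "2014-03-01T05:00"))
        assert count == 2

    def test_non_transitive_variant_reanchors(self):
        win = low_window("2014-03-01T02:10", "2014-03-01T03:40", "2014-03-01T04:15")
        count, _ = count_mild_hypo(win, transitive=False)
        assert count == 2  # 02:00-anchored episode ends at 03:xx; 04:15 restarts

    def test_readings_at_threshold_are_not_events(self):
        win = make_window([R("2014-03-01T02:10", 3.4)])
        assert count_mild_hypo(win)[0] == 0

    def test_count_bounded_by_low_reading_count(self):
        rng = np.random.default_rng(3)
        times = sorted(rng.integers(0, 50 * 24 * 60, 40))
        base = datetime(2014, 1, 1)
        win = make_window([Reading(timestamp=base + timedelta(minutes=int(m)), value=3.0) for m in set(times)])
        count, eps = count_mild_hypo(win)
        assert count <= len(win)
        assert sum(len(e.reading_indices) for e in eps) == len(win)

    def test_matches_union_find_oracle_on_random_windows(self):
        rng = np.random.default_rng(42)
        base = datetime(2014, 1, 1)
        for _ in range(300):
            n = int(rng.integers(0, 80))
            minutes = sorted(set(rng.integers(0, 50 * 24 * 60, n).tolist()))
            values = rng.choice([2.5, 3.0, 6.0], size=len(minutes), p=[0.3, 0.3, 0.4])
            win = make_window(
                [Reading(timestamp=base + timedelta(minutes=int(m)), value=float(v)) for m, v in zip(minutes, values)]
            )
            assert count_mild_hypo(win)[0] == union_find_hypo_episodes(win)


class TestCountSevereHypo:
    def test_counts_only_qualifying_reports(self):
        reports = [
            SevereHypoReport(date(2014, 5, 1), True, glucose_below_2_8=True),
            SevereHypoReport(date(2014, 5, 2), True),
            SevereHypoReport(date(2014, 5, 3), False, glucose_below_2_8=True),
        ]
        assert count_severe_hypo(reports) == 1

    def test_empty_list_is_zero(self):
        assert count_severe_hypo([]) == 0


class TestGroupSMBG:
    def test_response_group_absorbs_within_two_hours(self):
        win = make_window([R("2014-03-01T14:00", 3.8), R("2014-03-01T15:30", 5.5)])
        groups = group_smbg(win)
        assert len(groups) == 1
        assert groups[0].kind == "response_group"
        assert len(groups[0].reading_indices) == 2

    def test_same_hour_slot_groups(self):
        win = make_window([R("2014-03-01T14:05", 6.0), R("2014-03-01T14:50", 6.2)])
        groups = group_smbg(win)
        assert len(groups) == 1
        assert groups[0].kind == "hour_group"

    def test_distinct_hours_stay_singletons(self):
        win = make_window([R("2014-03-01T14:05", 6.0), R("2014-03-01T16:10", 6.2)])
        assert len(group_smbg(win)) == 2

    def test_absorbed_reading_cannot_anchor(self):
        # second low is inside the first's window; third reading is within
        # 2h of the second but beyond the first -> stays separate
        win = make_window(
            [R("2014-03-01T14:00", 3.8), R("2014-03-01T15:30", 3.9), R("2014-03-01T17:00", 6.0)]
        )
        groups = group_smbg(win)
        kinds = sorted(g.kind for g in groups)
        assert len(groups) == 2
        assert kinds == ["hour_group", "response_group"]

    def test_groups_partition_readings(self):
        rng = np.random.default_rng(5)
        base = datetime(2014, 1, 1)
        for _ in range(100):
            n = int(rng.integers(0, 60))
            minutes = sorted(set(rng.integers(0, 10 * 24 * 60, n).tolist()))
            values = rng.uniform(2.0, 25.0, len(minutes))
            win = make_window(
                [Reading(timestamp=base + timedelta(minutes=int(m)), value=float(v)) for m, v in zip(minutes, values)]
            )
            groups = group_smbg(win)
            seen = [i for g in groups for i in g.reading_indices]
            assert sorted(seen) == list(range(len(win)))  # disjoint and covering
            assert len(groups) <= len(win) or not len(win)

    def test_all_normal_distinct_hours_counts_every_reading(self):
        win = make_window([R(f"2014-03-01T{h:02d}:15", 6.0) for h in range(6, 22, 3)])
        assert len(group_smbg(win)) == len(win)


class TestMeanDailySMBG:
    def _window_with_groups(self, per_day, days, availability=1.0):
        readings = [
            R(f"2014-01-{d+1:02d}T{8+3*k:02d}:00", 6.0)
            for d in range(days)
            for k in range(per_day)
        ]
        start = datetime(2014, 1, 1, 0, 0)
        from glucolog.core import ReadingWindow

        return ReadingWindow(tuple(readings), start, start + timedelta(days=days), availability)

    def test_direct_division(self):
        win = self._window_with_groups(3, 25)
        assert mean_daily_smbg(win) == pytest.approx(3.0)

    @pytest.mark.parametrize("availability,expected", [(1.0, 3.0), (0.75, 4.0), (0.5, 6.0)])
    def test_availability_correction_scales_linearly(self, availability, expected):
        win = self._window_with_groups(3, 25, availability)
        assert mean_daily_smbg(win) == pytest.approx(expected)

    def test_empty_window_is_zero(self):
        from glucolog.core import ReadingWindow

        start = datetime(2014, 1, 1)
        win = ReadingWindow((), start, start + timedelta(days=50), 1.0)
        assert mean_daily_smbg(win) == 0.0

    def test_zero_length_window_is_error(self):
        from glucolog.core import ReadingWindow

        start = datetime(2014, 1, 1)
        win = ReadingWindow((), start, start, 1.0)
        with pytest.raises(ValidationError):
            mean_daily_smbg(win)


class TestTallyAdjustments:
    def test_clinic_changes_excluded(self):
        records = [
            {"initiator": "participant"},
            {"initiator": "guardian"},
            {"initiator": "clinic"},
        ]
        tally = tally_adjustments(records)
        assert tally.total == 2

    def test_empty_is_zero(self):
        assert tally_adjustments([]).total == 0

    def test_team_contacted_flag_counted(self):
        records = [
            {"initiator": "participant", "team_contacted": True},
            {"initiator": "participant"},
        ]
        tally = tally_adjustments(records)
        assert tally.total == 2
        assert tally.team_contacted == 1

    def test_unknown_initiator_rejected(self):
        with pytest.raises(ValidationError):
            tally_adjustments([{"initiator": "dietician"}])
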