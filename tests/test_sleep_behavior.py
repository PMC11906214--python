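"""Sleep scoring, windowed summaries, and DAM-file round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from flyephys import synthgen
from flyephys.sleep_behavior import (
    ActivityRecord,
    DamParseError,
    exclude_first_day,
    read_dam,
    score_sleep,
    sleep_bouts,
    summarize,
    write_dam,
)


def record(counts, start=0):
    return ActivityRecord(np.asarray(counts, dtype=int), start_zt_min=start)


class TestScoreSleep:
    def test_four_minute_run_is_not_sleep(self):
        rec = record([1, 0, 0, 0, 0, 1, 1])
        assert score_sleep(rec).sum() == 0

    def test_five_minute_run_is_exactly_threshold(self):
        rec = record([1, 0, 0, 0, 0, 0, 1])
        assert score_sleep(rec).sum() == 5
        assert len(sleep_bouts(rec)) == 1

    def test_scripted_fixture_hand_enumeration(self):
        script = [
            synthgen.Bout(True, 5, 3.0),
            synthgen.Bout(False, 10),
            synthgen.Bout(True, 2, 3.0),
            synthgen.Bout(False, 4),
            synthgen.Bout(True, 3, 3.0),
        ]
        rec = synthgen.gen_activity_record(script, seed=0)
        assert score_sleep(rec).sum() == 10
        assert len(sleep_bouts(rec)) == 1

    def test_idempotent_and_invariant_to_appended_active_day(self):
        rec = record([0] * 7 + [2] * 5 + [0] * 3)
        base = score_sleep(rec)
        extended = record(np.concatenate([rec.counts, np.ones(1440, dtype=int)]))
        np.testing.assert_array_equal(score_sleep(extended)[: rec.n_minutes], base)

    @given(seed=st.integers(0, 300))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_bout_count_matches_bruteforce_run_lengths(self, seed):
        rng = np.random.default_rng(seed)
        counts = (rng.random(200) < 0.5).astype(int)
        rec = record(counts)
        # brute force: scan runs of zeros
        runs, run = [], 0
        for c in counts:
            if c == 0:
                run += 1
            else:
                runs.append(run)
                run = 0
        runs.append(run)
        expected = sum(1 for r in runs if r >= 5)
        assert len(sleep_bouts(rec)) == expected
        assert score_sleep(rec).sum() == sum(r for r in runs if r >= 5)


class TestSummarize:
    def test_all_zero_day(self):
        rec = record([0] * 1440)
        s = summarize(rec)
        assert s.sleep_min[(0, 720)] == 720 and s.sleep_min[(720, 1440)] == 720
        assert sum(s.bout_count.values()) == 1
        assert s.waking_activity is None

    def test_no_long_zero_runs(self):
        pattern = [0, 0, 0, 0, 1, 2]  # never 5 zeros in a row
        rec = record(pattern * 120)
        s = summarize(rec, windows=((0, 720),))
        assert s.sleep_min[(0, 720)] == 0
        assert s.bout_count[(0, 720)] == 0
        assert s.active_min[(0, 720)] == 240  # minutes with counts > 0
        assert s.awake_min[(0, 720)] == 720

    def test_three_night_bouts_attributed_to_night_window(self):
        day = [1] * 720
        night = ([1] * 60 + [0] * 30 + [1] * 60 + [0] * 45 + [1] * 60 + [0] * 60) + [1] * 405
        rec = record(day + night)
        s = summarize(rec)
        assert s.bout_count[(720, 1440)] == 3
        assert s.sleep_min[(720, 1440)] == 135
        assert s.bout_count[(0, 720)] == 0

    def test_sleep_plus_awake_equals_window_length(self):
        rng = np.random.default_rng(5)
        rec = record((rng.random(1440) < 0.6).astype(int))
        s = summarize(rec)
        for w in s.windows:
            assert s.sleep_min[w] + s.awake_min[w] == w[1] - w[0]

    def test_boundary_bout_attribution_modes(self):
        counts = [1] * 715 + [0] * 10 + [1] * 715  # bout straddles ZT12
        rec = record(counts)
        s_start = summarize(rec, bout_attribution="start")
        assert s_start.bout_count[(0, 720)] == 1 and s_start.bout_count[(720, 1440)] == 0
        s_split = summarize(rec, bout_attribution="split")
        assert s_split.bout_count[(0, 720)] == pytest.approx(0.5)
        assert s_split.bout_count[(720, 1440)] == pytest.approx(0.5)

    def test_waking_activity_counts_per_awake_minute(self):
        rec = record([3] * 10 + [0] * 10)
        s = summarize(rec, windows=((0, 720),))
        # 10 awake active minutes at 3 counts; the 10-zero run is asleep
        assert s.waking_activity == pytest.approx(3.0)

    def test_profile_shape(self):
        rec = record([0] * 1440)
        s = summarize(rec)
        assert s.profile_30min.size == 48
        assert np.nanmax(s.profile_30min) == pytest.approx(30.0)

    def test_window_outside_day_raises(self):
        with pytest.raises(ValueError):
            summarize(record([1] * 100), windows=((0, 2000),))


class TestExcludeFirstDay:
    def test_three_day_record_becomes_two(self):
        rec = record([1] * (3 * 1440), start=0)
        out = exclude_first_day(rec)
        assert out.n_minutes == 2 * 1440
        assert out.start_zt_min == 0

    def test_midday_loading_drops_partial_plus_first_day(self):
        rec = record([1] * (3 * 1440), start=300)
        out = exclude_first_day(rec)
        assert out.start_zt_min == 0
        assert out.n_minutes == 3 * 1440 - (1440 - 300) - 1440

    def test_day1_bouts_ignored_after_trim(self):
        day1 = [0] * 1440  # all asleep
        day2 = [1] * 1440  # never asleep
        rec = record(day1 + day2, start=0)
        out = exclude_first_day(rec)
        assert score_sleep(out).sum() == 0

    def test_short_record_raises(self):
        with pytest.raises(ValueError):
            exclude_first_day(record([1] * 100))


class TestDamIo:
    def test_round_trip_preserves_counts(self, tmp_path):
        rng = np.random.default_rng(7)
        recs = [
            ActivityRecord(rng.poisson(2.0, size=10), start_zt_min=0, fly_id=f"ch{i+1}")
            for i in range(2)
        ]
        path = tmp_path / "Monitor1.txt"
        write_dam(path, recs)
        back = read_dam(path)
        assert len(back) == 32
        for i in range(2):
            np.testing.assert_array_equal(back[i].counts, recs[i].counts)
        assert all(back[i].counts.sum() == 0 for i in range(2, 32))
        assert back[0].n_minutes == 10

    def test_status_error_row_dropped(self, tmp_path):
        recs = [ActivityRecord(np.arange(10), start_zt_min=0)]
        path = tmp_path / "Monitor2.txt"
        write_dam(path, recs)
        lines = path.read_text().splitlines()
        parts = lines[4].split("\t")
        parts[3] = "51"  # monitor error status
        lines[4] = "\t".join(parts)
        path.write_text("\n".join(lines) + "\n")
        back = read_dam(path)
        assert back[0].n_minutes == 9

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "Monitor3.txt"
        path.write_text("not\ta\tvalid\trow\n")
        with pytest.raises(DamParseError, match="line 1"):
            read_dam(path)
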