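"""Sleep-bout detection and the per-fly parameter panel."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from flysleep import ActivityRecording, LightProtocol, detect_sleep_bouts, per_day_panel
from flysleep.io_formats import phase_window
from flysleep.sleep import (
    ld_average,
    phase_stats,
    sfi,
    sleep_latency,
    waso,
)


def brute_force_bouts(activity, bin_seconds, move_threshold, min_sleep_min):
    """Independent oracle: explicit run-length scan, one bin at a time."""
    bouts = []
    run_start = None
    for i, v in enumerate(list(activity) + [move_threshold + 1.0]):
        if v <= move_threshold:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None:
                if (i - run_start) * bin_seconds / 60.0 >= min_sleep_min:
                    bouts.append((run_start, i))
                run_start = None
    return bouts


class TestDetection:
    def test_five_minute_run_is_one_bout(self):
        x = np.r_[np.ones(5), np.zeros(10), np.ones(5)]
        bouts = detect_sleep_bouts(x, bin_seconds=30)
        assert len(bouts) == 1
        assert bouts[0].duration_min == 5.0

    def test_shorter_run_is_wake(self):
        x = np.r_[np.ones(5), np.zeros(9), np.ones(5)]
        assert detect_sleep_bouts(x, bin_seconds=30) == []

    def test_always_active_no_sleep(self):
        assert detect_sleep_bouts(np.ones(1000), bin_seconds=30) == []

    def test_empty_series(self):
        assert detect_sleep_bouts(np.array([]), bin_seconds=30) == []

    def test_open_ended_run_kept(self):
        x = np.r_[np.ones(5), np.zeros(12)]
        bouts = detect_sleep_bouts(x, bin_seconds=30)
        assert [(b.start_bin, b.end_bin) for b in bouts] == [(5, 17)]

    def test_oracle_equivalence_on_random_series(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 120))
            x = (rng.random(n) < 0.55).astype(float) * rng.exponential(size=n)
            got = [
                (b.start_bin, b.end_bin)
                for b in detect_sleep_bouts(x, 30, 0.0, 5.0)
            ]
            assert got == brute_force_bouts(x, 30, 0.0, 5.0)

    @given(hst.data())
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_threshold_monotonicity(self, data):
        """Raising the movement threshold never decreases TST; raising the
        minimum bout length never increases the bout count."""
        n = data.draw(hst.integers(20, 200))
        seed = data.draw(hst.integers(0, 2**31 - 1))
        rng = np.random.default_rng(seed)
        x = rng.exponential(2.0, size=n) * (rng.random(n) < 0.6)
        thr_lo, thr_hi = sorted(
            [data.draw(hst.floats(0, 4)), data.draw(hst.floats(0, 4))]
        )
        tst = {
            t: sum(
                b.duration_min for b in detect_sleep_bouts(x, 30, t, 5.0)
            )
            for t in (thr_lo, thr_hi)
        }
        assert tst[thr_hi] >= tst[thr_lo]
        m_lo, m_hi = sorted(
            [data.draw(hst.floats(0.5, 30)), data.draw(hst.floats(0.5, 30))]
        )
        assert len(detect_sleep_bouts(x, 30, 0.0, m_hi)) <= len(
            detect_sleep_bouts(x, 30, 0.0, m_lo)
        )


class TestPhaseStats:
    def test_full_night_bout(self, protocol):
        w = phase_window(protocol, "NT", 1)
        bouts = detect_sleep_bouts(
            np.r_[np.ones(1440), np.zeros(1440), np.ones(100)], 30
        )
        n, mean_len, tst = phase_stats(bouts, w, 30)
        assert (n, tst) == (1, 720.0)
        assert mean_len == 720.0

    def test_boundary_bout_split_between_phases(self, protocol):
        # bout ZT11:58 .. ZT12:08 -> 2 min in DT, 8 min in NT, counted in both
        x = np.ones(protocol.bins_per_day)
        x[1436:1456] = 0.0
        bouts = detect_sleep_bouts(x, 30)
        dt = phase_stats(bouts, phase_window(protocol, "DT", 1), 30)
        nt = phase_stats(bouts, phase_window(protocol, "NT", 1), 30)
        assert dt == (1, 2.0, 2.0)
        assert nt == (1, 8.0, 8.0)

    def test_no_overlap_is_empty(self, protocol):
        x = np.ones(protocol.bins_per_day)
        x[0:20] = 0.0
        bouts = detect_sleep_bouts(x, 30)
        n, mean_len, tst = phase_stats(
            bouts, phase_window(protocol, "NT", 1), 30
        )
        assert (n, tst) == (0, 0.0)
        assert np.isnan(mean_len)

    def test_dt_plus_nt_equals_whole_day(self, protocol, rng):
        x = (rng.random(protocol.bins_per_day) < 0.5).astype(float)
        bouts = detect_sleep_bouts(x, 30)
        _, _, dt = phase_stats(bouts, phase_window(protocol, "DT", 1), 30)
        _, _, nt = phase_stats(bouts, phase_window(protocol, "NT", 1), 30)
        _, _, whole = phase_stats(bouts, phase_window(protocol, "day", 1), 30)
        assert dt + nt == pytest.approx(whole)


class TestLatency:
    def test_bout_at_phase_start_zero_latency(self):
        bouts = detect_sleep_bouts(np.r_[np.zeros(10), np.ones(10)], 30)
        assert sleep_latency(bouts, 0, 30) == 0.0

    def test_no_onset_within_cap_gets_cap(self):
        assert sleep_latency([], 0, 30) == 1440.0

    def test_night_latency_example(self, protocol):
        # first bout 86 min after ZT12
        x = np.ones(protocol.bins_per_day)
        start = 1440 + 172  # ZT12 + 86 min
        x[start : start + 20] = 0.0
        bouts = detect_sleep_bouts(x, 30)
        assert sleep_latency(bouts, 1440, 30) == 86.0

    def test_search_crosses_phase_end(self, protocol):
        # only bout starts on day 2: DT latency of day 1 still finds it
        x = np.ones(2 * protocol.bins_per_day)
        x[2880 + 120 : 2880 + 160] = 0.0
        bouts = detect_sleep_bouts(x, 30)
        assert sleep_latency(bouts, 0, 30) == 1440.0  # capped
        assert sleep_latency(bouts, 2880, 30) == 60.0

    def test_ongoing_bout_at_phase_start_zero_latency(self):
        # fly asleep across the phase boundary: it is asleep at phase start
        bouts = detect_sleep_bouts(np.r_[np.zeros(20), np.ones(50), np.zeros(20)], 30)
        assert sleep_latency(bouts, 5, 30) == 0.0

    def test_bout_ending_before_phase_start_ignored(self):
        bouts = detect_sleep_bouts(np.r_[np.zeros(20), np.ones(50), np.zeros(20)], 30)
        assert sleep_latency(bouts, 30, 30) == ((70 - 30) * 30) / 60.0


class TestFormulas:
    @pytest.mark.parametrize(
        "tst,lat,expected",
        [(720.0, 0.0, 0.0), (5.0, 576.0, 1291.0), (520.98, 78.36, 277.38)],
    )
    def test_waso_examples(self, tst, lat, expected):
        assert waso(tst, lat) == pytest.approx(expected)

    @given(
        hst.floats(0, 720), hst.floats(0, 1440)
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_waso_identity(self, tst, lat):
        assert waso(tst, lat) + tst - lat == pytest.approx(720.0)

    @pytest.mark.parametrize(
        "n,tst,expected", [(10, 500.0, 0.02), (1, 5.0, 0.2), (0, 0.0, 0.0)]
    )
    def test_sfi_examples(self, n, tst, expected):
        assert sfi(n, tst) == pytest.approx(expected)

    def test_sfi_bounded_by_bout_floor(self, rng):
        """SFI can never exceed 1/min_sleep_min = 0.2 when TST > 0."""
        for _ in range(200):
            x = (rng.random(500) < 0.5).astype(float)
            bouts = detect_sleep_bouts(x, 30)
            tst = sum(b.duration_min for b in bouts)
            assert sfi(len(bouts), tst) <= 0.2 + 1e-12


class TestPanel:
    def test_panel_matches_simulated_schedule(self, small_cohort):
        """Panel TST equals the ground-truth schedule's qualifying minutes."""
        recs, truths, _ = small_cohort
        for rec, truth in zip(recs[:4], truths[:4]):
            panel = per_day_panel(rec)
            day1 = panel[(panel["day"] == 1) & (panel["phase"] == "day")]
            expected = sum(
                (min(e, 2880) - max(s, 0)) * 0.5
                for s, e in truth.sleep_episodes
                if (e - s) >= 10 and s < 2880 and e > 0
            )
            # episodes >=5 min clipped to day 1 vs scored TST; boundary
            # episodes that only qualify via bins outside the day match too
            assert day1["tst_min"].item() == pytest.approx(expected)

    def test_identical_days_average_to_day_value(self, protocol):
        day = np.ones(protocol.bins_per_day)
        day[240:480] = 0.0  # 2 h nap at ZT02
        x = np.tile(day, protocol.days)
        rec = ActivityRecording("f", "wt", "female", protocol, x)
        panel = per_day_panel(rec)
        avg = ld_average(panel, protocol.ld_days)
        dt = avg[avg["phase"] == "DT"].iloc[0]
        assert dt["tst_min"] == 120.0
        assert dt["latency_min"] == 120.0  # ZT02 onset
        assert dt["n_bouts"] == 1.0

    def test_fly_asleep_entire_experiment(self, short_protocol):
        rec = ActivityRecording(
            "f", "wt", "female", short_protocol,
            np.zeros(short_protocol.total_bins),
        )
        panel = per_day_panel(rec)
        dt = panel[(panel["day"] == 1) & (panel["phase"] == "DT")].iloc[0]
        nt = panel[(panel["day"] == 1) & (panel["phase"] == "NT")].iloc[0]
        assert dt["tst_min"] == 720.0 and nt["tst_min"] == 720.0
        assert dt["latency_min"] == 0.0
        assert nt["waso_min"] == pytest.approx(0.0)

    def test_dd_days_whole_day_only(self, small_cohort):
        recs, _, _ = small_cohort
        panel = per_day_panel(recs[0])
        dd = panel[panel["day"] > 2]
        assert set(dd["phase"]) == {"day"}
        ld = panel[panel["day"] <= 2]
        assert set(ld["phase"]) == {"DT", "NT", "day"}
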