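"""Sleep-bout detection and the per-fly sleep parameter panel.

Sleep is scored behaviorally: a maximal run of bins with activity at or
below ``move_threshold`` (default 0 mm, so micromovements count as wake)
lasting at least ``min_sleep_min`` minutes (default 5) is one sleep bout.
From the bout list the panel derives, per experimental day and phase:

* number of bouts, mean bout length (min), total sleep time TST (min);
* sleep latency (min): time from phase start (ZT00 for DT and whole days,
  ZT12 for NT) to the onset of the first bout starting at or after it,
  searched past the phase end if necessary and capped at 24 h;
* WASO (min, night only): 720 − (NT TST − night latency);
* SFI (bouts/min): number of bouts / TST.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ActivityRecording, PhaseSlice, phase_window

__all__ = [
    "SleepBout",
    "detect_sleep_bouts",
    "phase_stats",
    "sleep_latency",
    "waso",
    "sfi",
    "per_day_panel",
    "ld_average",
    "asleep_mask",
]

NIGHT_MINUTES = 720.0  # ZT12..ZT24


@dataclass(frozen=True)
class SleepBout:
    """One sleep episode as a half-open bin interval."""

    start_bin: int
    end_bin: int
    bin_seconds: int

    @property
    def duration_min(self) -> float:
        return (self.end_bin - self.start_bin) * self.bin_seconds / 60.0


def detect_sleep_bouts(
    activity: np.ndarray,
    bin_seconds: int = 30,
    move_threshold: float = 0.0,
    min_sleep_min: float = 5.0,
) -> list[SleepBout]:
    """Maximal inactivity runs of at least ``min_sleep_min`` minutes.

    A run still open at the end of the series is kept if already long
    enough, symmetrically with runs that start at bin 0.
    """
    if move_threshold < 0:
        raise ValueError("move_threshold must be >= 0")
    x = np.asarray(activity, dtype=float)
    if len(x) == 0:
        return []
    quiet = (x <= move_threshold).astype(np.int8)
    edges = np.diff(np.concatenate(([0], quiet, [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    min_bins = int(np.ceil(min_sleep_min * 60.0 / bin_seconds))
    return [
        SleepBout(int(s), int(e), bin_seconds)
        for s, e in zip(starts, ends)
        if e - s >= min_bins
    ]


def phase_stats(
    bouts: list[SleepBout], window: PhaseSlice, bin_seconds: int
) -> tuple[int, float, float]:
    """``(n_bouts, mean_bout_length_min, tst_min)`` within a phase window.

    Bouts are clipped to the window for TST and bout length (so a bout
    straddling ZT12 splits its minutes between DT and NT, preserving
    DT + NT = whole-day TST) but each bout counts once in ``n_bouts`` of
    every phase it overlaps.  Mean bout length is NaN when no bout overlaps.
    """
    clipped_min = [
        (min(b.end_bin, window.end) - max(b.start_bin, window.start))
        * bin_seconds
        / 60.0
        for b in bouts
        if b.start_bin < window.end and b.end_bin > window.start
    ]
    n = len(clipped_min)
    if n == 0:
        return 0, float("nan"), 0.0
    return n, float(np.mean(clipped_min)), float(np.sum(clipped_min))


def sleep_latency(
    bouts: list[SleepBout],
    phase_start_bin: int,
    bin_seconds: int,
    cap_min: float = 1440.0,
) -> float:
    """Minutes from the phase start to the first bout onset at/after it.

    A bout already in progress at the phase start means the fly is asleep
    there, so latency is 0 (this is what makes WASO vanish for a fly that
    sleeps through the whole night).  The search runs past the phase end; a
    fly with no qualifying bout within ``cap_min`` minutes (default 24 h)
    receives the cap itself.
    """
    for b in bouts:
        if b.end_bin > phase_start_bin:
            lat = max(0, b.start_bin - phase_start_bin) * bin_seconds / 60.0
            return min(lat, cap_min)
    return cap_min


def waso(tst_nt_min: float, night_latency_min: float) -> float:
    """Wake after sleep onset: 720 − (NT TST − night latency), in minutes.

    This is a fixed arithmetic identity on the night window; it can exceed
    720 min when latency is large relative to night sleep.
    """
    return NIGHT_MINUTES - (tst_nt_min - night_latency_min)


def sfi(n_bouts: int, tst_min: float) -> float:
    """Sleep fragmentation index: bouts per minute of sleep.

    Defined as 0 for a fly with no sleep (no sleep, no fragmentation).  The
    5-min bout floor bounds SFI above by 1/5 = 0.2 whenever TST > 0.
    """
    if tst_min <= 0:
        return 0.0
    return n_bouts / tst_min


def asleep_mask(
    recording: ActivityRecording,
    move_threshold: float = 0.0,
    min_sleep_min: float = 5.0,
) -> np.ndarray:
    """Boolean per-bin sleep indicator derived from the detected bouts."""
    mask = np.zeros(recording.n_bins, dtype=bool)
    for b in detect_sleep_bouts(
        recording.activity,
        recording.protocol.bin_seconds,
        move_threshold,
        min_sleep_min,
    ):
        mask[b.start_bin : b.end_bin] = True
    return mask


def per_day_panel(
    recording: ActivityRecording,
    move_threshold: float = 0.0,
    min_sleep_min: float = 5.0,
    latency_cap_min: float = 1440.0,
) -> pd.DataFrame:
    """Sleep parameter panel: one row per day × phase.

    LD days get DT, NT and whole-day rows; DD days (where lights-on has no
    meaning) get whole-day rows only.  WASO is populated for NT rows only.
    Columns: fly_id, genotype, sex, day, phase, n_bouts,
    mean_bout_length_min, latency_min, tst_min, waso_min, sfi.
    """
    proto = recording.protocol
    bouts = detect_sleep_bouts(
        recording.activity, proto.bin_seconds, move_threshold, min_sleep_min
    )
    rows = []
    for day in range(1, recording.n_days + 1):
        phases = ("DT", "NT", "day") if day <= proto.ld_days else ("day",)
        for phase in phases:
            w = phase_window(proto, phase, day)
            n, mean_len, tst = phase_stats(bouts, w, proto.bin_seconds)
            lat = sleep_latency(bouts, w.start, proto.bin_seconds, latency_cap_min)
            rows.append(
                {
                    "fly_id": recording.fly_id,
                    "genotype": recording.genotype,
                    "sex": recording.sex,
                    "day": day,
                    "phase": phase,
                    "n_bouts": n,
                    "mean_bout_length_min": mean_len,
                    "latency_min": lat,
                    "tst_min": tst,
                    "waso_min": waso(tst, lat) if phase == "NT" else np.nan,
                    "sfi": sfi(n, tst),
                }
            )
    return pd.DataFrame(rows)


def ld_average(panel: pd.DataFrame, ld_days: int = 2) -> pd.DataFrame:
    """Per-fly LD values: mean across the LD days, per phase.

    Group statistics downstream operate on these per-fly values (one value
    per fly), not on pooled day records.  NaN bout lengths (phases with no
    bout on a day) are excluded from the fly's average.
    """
    ld = panel[(panel["day"] <= ld_days) & panel["phase"].isin(["DT", "NT"])]
    value_cols = [
        "n_bouts",
        "mean_bout_length_min",
        "latency_min",
        "tst_min",
        "waso_min",
        "sfi",
    ]
    return (
        ld.groupby(["fly_id", "genotype", "sex", "phase"], as_index=False)[
            value_cols
        ]
        .mean()
        .sort_values(["genotype", "sex", "phase", "fly_id"])
        .reset_index(drop=True)
    )
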