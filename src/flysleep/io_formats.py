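"""Readers, writers and protocol-aware slicing for fly locomotor recordings.

Two on-disk dialects are supported:

* **Arena CSV** — the wide CSV exported by video-tracking multiwell arenas:
  one ``time`` column (seconds since the start of the recording, i.e. since
  ZT00 of experimental day 1) followed by one distance-per-bin column (mm)
  per well.  Well metadata (genotype, sex) travels in a separate two-column
  map CSV with header ``well_id,genotype,sex``.
* **Beam-monitor text** — the tab-separated layout used by infrared
  beam-crossing activity monitors: per row a record index, date
  (``DD Mon YY``), time (``HH:MM:SS``), a status flag, six filler columns
  and 32 integer channel counts (42 columns in total).

All bin indexing is 0-based with half-open intervals; index 0 is the bin
starting at ZT00 (lights-on) of experimental day 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LightProtocol",
    "ActivityRecording",
    "PhaseSlice",
    "Viability",
    "read_zantiks_csv",
    "write_zantiks_csv",
    "read_metadata_csv",
    "read_dam_monitor",
    "write_dam_monitor",
    "phase_window",
    "slice_phase",
    "viability_filter",
]

Phase = Literal["DT", "NT", "day"]


@dataclass(frozen=True)
class LightProtocol:
    """Light regime and sampling rate of one experiment.

    The default mirrors a standard free-running design: 2 days of LD12:12
    entrainment (lights on at 07:00 local time, defining ZT00) followed by
    8 days of constant darkness, activity binned every 30 s.
    """

    ld_days: int = 2
    dd_days: int = 8
    lights_on_clock: str = "07:00"
    bin_seconds: int = 30

    def __post_init__(self) -> None:
        if self.ld_days < 0 or self.dd_days < 0:
            raise ValueError("day counts must be non-negative")
        if self.bin_seconds <= 0 or (
            60 % self.bin_seconds != 0 and self.bin_seconds % 60 != 0
        ):
            raise ValueError(
                "bin_seconds must divide 60 or be a multiple of 60, "
                f"got {self.bin_seconds}"
            )
        if 86400 % self.bin_seconds != 0:
            raise ValueError("bin_seconds must divide the day evenly")

    @property
    def days(self) -> int:
        return self.ld_days + self.dd_days

    @property
    def bins_per_day(self) -> int:
        return 86400 // self.bin_seconds

    @property
    def bins_per_half_day(self) -> int:
        return self.bins_per_day // 2

    @property
    def total_bins(self) -> int:
        return self.days * self.bins_per_day

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(
                {
                    "ld_days": self.ld_days,
                    "dd_days": self.dd_days,
                    "lights_on_clock": self.lights_on_clock,
                    "bin_seconds": self.bin_seconds,
                }
            )
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LightProtocol":
        return cls(**yaml.safe_load(Path(path).read_text()))


@dataclass
class ActivityRecording:
    """One fly's binned locomotor series, aligned so bin 0 starts at ZT00.

    ``activity`` holds the distance traveled (mm) per bin for video data, or
    beam-crossing counts per bin for monitor data (``unit`` records which).
    """

    fly_id: str
    genotype: str
    sex: str
    protocol: LightProtocol
    activity: np.ndarray
    unit: str = "mm"

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.ndim != 1:
            raise ValueError("activity must be one-dimensional")
        if np.isnan(self.activity).any():
            raise ValueError(f"fly {self.fly_id}: activity contains NaN")
        if (self.activity < 0).any():
            i = int(np.argmax(self.activity < 0))
            raise ValueError(
                f"fly {self.fly_id}: negative activity at bin {i}"
            )

    @property
    def n_bins(self) -> int:
        return len(self.activity)

    @property
    def n_days(self) -> int:
        return self.n_bins // self.protocol.bins_per_day


@dataclass(frozen=True)
class PhaseSlice:
    """A half-open bin window for one phase of one experimental day."""

    phase: Phase
    day_index: int  # 1-based
    start: int
    end: int

    @property
    def bins(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def n_bins(self) -> int:
        return self.end - self.start


def phase_window(
    protocol: LightProtocol,
    phase: Phase,
    day_index: int,
    subjective: bool = False,
) -> PhaseSlice:
    """Bin window of ``phase`` on 1-based experimental ``day_index``.

    DT is [ZT00, ZT12) and NT is [ZT12, ZT24).  On DD days those labels are
    only meaningful as *subjective* day and night and must be requested
    explicitly with ``subjective=True``.
    """
    if not 1 <= day_index <= protocol.days:
        raise ValueError(
            f"day {day_index} outside protocol (1..{protocol.days})"
        )
    if phase not in ("DT", "NT", "day"):
        raise ValueError(f"unknown phase {phase!r}")
    is_dd = day_index > protocol.ld_days
    if phase in ("DT", "NT") and is_dd and not subjective:
        raise ValueError(
            f"day {day_index} is a DD day; DT/NT are subjective there "
            "(pass subjective=True)"
        )
    d0 = (day_index - 1) * protocol.bins_per_day
    half = protocol.bins_per_half_day
    if phase == "DT":
        return PhaseSlice(phase, day_index, d0, d0 + half)
    if phase == "NT":
        return PhaseSlice(phase, day_index, d0 + half, d0 + 2 * half)
    return PhaseSlice(phase, day_index, d0, d0 + protocol.bins_per_day)


def slice_phase(
    recording: ActivityRecording,
    phase: Phase,
    day_index: int,
    subjective: bool = False,
) -> np.ndarray:
    """Activity sub-series for one phase of one day (view, not copy)."""
    w = phase_window(recording.protocol, phase, day_index, subjective)
    if w.end > recording.n_bins:
        raise ValueError(
            f"day {day_index} extends past the recording "
            f"({recording.n_bins} bins)"
        )
    return recording.activity[w.start : w.end]


# ---------------------------------------------------------------------------
# Arena (video-tracking) CSV dialect
# ---------------------------------------------------------------------------


def read_metadata_csv(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a ``well_id,genotype,sex`` map into ``{well: (genotype, sex)}``."""
    df = pd.read_csv(path, dtype=str)
    required = {"well_id", "genotype", "sex"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata CSV must have columns {sorted(required)}")
    return {
        r.well_id: (r.genotype, r.sex) for r in df.itertuples(index=False)
    }


def read_zantiks_csv(
    path: str | Path,
    protocol: LightProtocol,
    metadata: Mapping[str, tuple[str, str]],
) -> list[ActivityRecording]:
    """Read a wide arena CSV into one recording per well.

    The first column must be ``time`` in seconds since ZT00 of day 1, strictly
    increasing in steps of ``protocol.bin_seconds``.  Missing-value policy: a
    single missing bin in a well is imputed as 0 with a warning; two or more
    consecutive missing bins flag the fly, which is dropped with a warning
    (zero-filling long gaps would masquerade as sleep).
    """
    df = pd.read_csv(path)
    if df.columns[0] != "time":
        raise ValueError("first column of an arena CSV must be 'time'")
    t = df["time"].to_numpy(dtype=float)
    dt = np.diff(t)
    if (dt <= 0).any():
        i = int(np.argmax(dt <= 0)) + 1
        raise ValueError(f"non-monotone timestamps at row {i}")
    if not np.allclose(dt, protocol.bin_seconds):
        raise ValueError(
            f"bin width is not constant at {protocol.bin_seconds} s"
        )
    recordings: list[ActivityRecording] = []
    for well in df.columns[1:]:
        if well not in metadata:
            raise KeyError(f"well {well!r} missing from the metadata map")
        x = df[well].to_numpy(dtype=float)
        neg = np.nan_to_num(x, nan=0.0) < 0
        if neg.any():
            row = int(np.argmax(neg))
            raise ValueError(
                f"negative distance at row {row}, well {well!r}"
            )
        miss = np.isnan(x)
        if miss.any():
            # run lengths of consecutive NaNs
            edges = np.diff(np.concatenate(([0], miss.astype(int), [0])))
            starts = np.flatnonzero(edges == 1)
            ends = np.flatnonzero(edges == -1)
            if (ends - starts).max() >= 2:
                warnings.warn(
                    f"well {well!r}: >=2 consecutive missing bins; "
                    "fly excluded",
                    stacklevel=2,
                )
                continue
            warnings.warn(
                f"well {well!r}: {miss.sum()} isolated missing bin(s) "
                "imputed as 0",
                stacklevel=2,
            )
            x = np.nan_to_num(x, nan=0.0)
        genotype, sex = metadata[well]
        recordings.append(
            ActivityRecording(well, genotype, sex, protocol, x, unit="mm")
        )
    return recordings


def write_zantiks_csv(
    recordings: Sequence[ActivityRecording], path: str | Path
) -> None:
    """Write recordings as a wide arena CSV (inverse of ``read_zantiks_csv``)."""
    if not recordings:
        raise ValueError("nothing to write")
    proto = recordings[0].protocol
    n = recordings[0].n_bins
    if any(r.n_bins != n for r in recordings):
        raise ValueError("recordings differ in length")
    out = {"time": np.arange(n) * proto.bin_seconds}
    for r in recordings:
        out[r.fly_id] = r.activity
    pd.DataFrame(out).to_csv(path, index=False)


def write_metadata_csv(
    recordings: Sequence[ActivityRecording], path: str | Path
) -> None:
    pd.DataFrame(
        {
            "well_id": [r.fly_id for r in recordings],
            "genotype": [r.genotype for r in recordings],
            "sex": [r.sex for r in recordings],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Beam-monitor text dialect (32 channels, tab-separated, 42 columns)
# ---------------------------------------------------------------------------

_DAM_NCOLS = 42
_DAM_EPOCH = datetime(2024, 1, 1, 7, 0, 0)


def write_dam_monitor(
    recordings: Sequence[ActivityRecording], path: str | Path
) -> None:
    """Write up to 32 recordings in the beam-monitor text layout.

    Monitor files carry integer counts, so distances are rounded half-to-even;
    the mm provenance survives only in the caller's metadata.  Channels beyond
    the provided recordings are written as zeros.
    """
    if not 1 <= len(recordings) <= 32:
        raise ValueError("monitor files hold 1..32 channels")
    n = recordings[0].n_bins
    if any(r.n_bins != n for r in recordings):
        raise ValueError("recordings differ in length")
    step = timedelta(seconds=recordings[0].protocol.bin_seconds)
    counts = np.zeros((n, 32), dtype=int)
    for j, r in enumerate(recordings):
        counts[:, j] = np.rint(r.activity).astype(int)
    with open(path, "w") as fh:
        for i in range(n):
            stamp = _DAM_EPOCH + i * step
            row = [
                str(i + 1),
                stamp.strftime("%d %b %y"),
                stamp.strftime("%H:%M:%S"),
                "1",
            ] + ["0"] * 6 + [str(c) for c in counts[i]]
            fh.write("\t".join(row) + "\n")


def read_dam_monitor(
    path: str | Path,
    protocol: LightProtocol,
    metadata: Mapping[str, tuple[str, str]] | None = None,
) -> list[ActivityRecording]:
    """Read a beam-monitor text file into 32 count recordings.

    Channels are named ``c01`` .. ``c32``; an optional metadata map supplies
    genotype/sex per channel name.  All-zero channels are kept — liveness
    screening is :func:`viability_filter`'s job, not the parser's.
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != _DAM_NCOLS:
                raise ValueError(
                    f"line {lineno}: expected {_DAM_NCOLS} columns, "
                    f"got {len(parts)}"
                )
            rows.append(parts)
    counts = np.array([[float(v) for v in r[10:]] for r in rows])
    recordings = []
    for j in range(32):
        cid = f"c{j + 1:02d}"
        genotype, sex = (metadata or {}).get(cid, ("unknown", "unknown"))
        recordings.append(
            ActivityRecording(
                cid, genotype, sex, protocol, counts[:, j], unit="counts"
            )
        )
    return recordings


# ---------------------------------------------------------------------------
# Viability
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Viability:
    alive: bool
    dead_from_bin: int | None = None


def viability_filter(
    recording: ActivityRecording, lookback_h: float = 24.0
) -> Viability:
    """Flag flies whose terminal silence spans at least ``lookback_h`` hours.

    A dead fly records zeros to the end of the experiment; the returned
    ``dead_from_bin`` is the first bin of that terminal zero run.  Flies with
    any movement inside the trailing window are alive.
    """
    x = recording.activity
    lookback_bins = int(round(lookback_h * 3600 / recording.protocol.bin_seconds))
    active = np.flatnonzero(x > 0)
    first_silent = 0 if len(active) == 0 else int(active[-1]) + 1
    if len(x) - first_silent >= lookback_bins:
        return Viability(alive=False, dead_from_bin=first_silent)
    return Viability(alive=True)
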