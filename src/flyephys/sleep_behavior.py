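"""Fly sleep scoring from 1-min binned locomotor-activity counts.

Sleep in Drosophila is conventionally defined as any period of locomotor
inactivity lasting at least five consecutive minutes.  This module scores
per-minute sleep from Trikinetics DAM-style activity records, counts sleep
bouts, and summarizes sleep/activity per zeitgeber-time window (ZT0-12
lights-on, ZT12-24 lights-off under a 12h:12h cycle), including waking
activity (beam counts per awake minute) and a 30-min sleep profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SLEEP_MIN_RUN = 5       # minutes of inactivity that qualify as sleep
MINUTES_PER_DAY = 1440
DAY_WINDOWS = ((0, 720), (720, 1440))  # ZT0-12, ZT12-24, half-open in ZT minutes


class DamParseError(ValueError):
    """Raised on a malformed monitor-file row; carries the line number."""


@dataclass
class ActivityRecord:
    """1-min binned activity counts of one fly/channel.

    ``start_zt_min`` is the zeitgeber time (minutes past lights-on) of the
    first bin; multi-day records simply continue past 1440.
    """

    counts: np.ndarray
    start_zt_min: int = 0
    fly_id: str = "ch1"

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be non-negative integers")
            self.counts = self.counts.astype(int)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_minutes(self) -> int:
        return self.counts.size

    def zt_min(self) -> np.ndarray:
        """ZT minute-of-day (0..1439) for every bin."""
        return (self.start_zt_min + np.arange(self.n_minutes)) % MINUTES_PER_DAY


def _zero_runs(counts) -> list[tuple[int, int]]:
    """(start, length) of every maximal run of zero-count minutes."""
    zero = np.asarray(counts) == 0
    padded = np.concatenate(([False], zero, [False])).astype(int)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts, ends - starts))


def score_sleep(record: ActivityRecord, min_run: int = SLEEP_MIN_RUN) -> np.ndarray:
    """Per-minute sleep boolean: inside a maximal zero run of >= min_run minutes."""
    asleep = np.zeros(record.n_minutes, dtype=bool)
    for start, length in _zero_runs(record.counts):
        if length >= min_run:
            asleep[start : start + length] = True
    return asleep


def sleep_bouts(record: ActivityRecord, min_run: int = SLEEP_MIN_RUN) -> list[tuple[int, int]]:
    """(start_index, length_min) of every sleep bout (maximal zero run >= min_run)."""
    return [(s, n) for s, n in _zero_runs(record.counts) if n >= min_run]


@dataclass
class SleepSummary:
    """Windowed sleep/activity statistics of one record."""

    fly_id: str
    windows: tuple
    sleep_min: dict
    bout_count: dict
    awake_min: dict
    active_min: dict
    waking_activity: float | None
    profile_30min: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w in self.windows:
            rows.append(
                {
                    "fly": self.fly_id,
                    "window_zt": f"{w[0] // 60}-{w[1] // 60}",
                    "sleep_min": self.sleep_min[w],
                    "bout_count": self.bout_count[w],
                    "awake_min": self.awake_min[w],
                    "active_min": self.active_min[w],
                    "waking_activity": self.waking_activity,
                }
            )
        return pd.DataFrame(rows)


def summarize(
    record: ActivityRecord,
    windows=DAY_WINDOWS,
    min_run: int = SLEEP_MIN_RUN,
    bout_attribution: str = "start",
    profile_bin_min: int = 30,
) -> SleepSummary:
    """Per-window sleep minutes, bout counts, active time, waking activity.

    Windows are half-open intervals in ZT minutes, applied across every day
    of the record (pooled).  A bout is attributed to the window containing
    its first minute (``bout_attribution="start"``) or split pro rata by
    minutes (``"split"``, fractional counts).  "Active time" is the number
    of awake minutes with at least one beam count — distinct from awake
    minutes, which include awake-but-still minutes.  Waking activity (total
    counts per awake minute) is None for a record with no awake minutes.
    The 30-min profile is the mean sleep minutes per profile bin across days.
    """
    zt = record.zt_min()
    for w in windows:
        if not (0 <= w[0] < w[1] <= MINUTES_PER_DAY):
            raise ValueError(f"window {w} outside the ZT day")
    if bout_attribution not in ("start", "split"):
        raise ValueError("bout_attribution must be 'start' or 'split'")
    asleep = score_sleep(record, min_run=min_run)
    bouts = sleep_bouts(record, min_run=min_run)
    sleep_min, bout_count, awake_min, active_min = {}, {}, {}, {}
    for w in windows:
        in_w = (zt >= w[0]) & (zt < w[1])
        sleep_min[w] = int(np.sum(asleep & in_w))
        awake_min[w] = int(np.sum(~asleep & in_w))
        active_min[w] = int(np.sum((record.counts > 0) & in_w))
        if bout_attribution == "start":
            bout_count[w] = sum(1 for s, _ in bouts if in_w[s])
        else:
            total = 0.0
            for s, n in bouts:
                total += float(np.sum(in_w[s : s + n])) / n
            bout_count[w] = total
    n_awake = int(np.sum(~asleep))
    waking = float(record.counts[~asleep].sum() / n_awake) if n_awake else None

    # mean sleep minutes per 30-min ZT bin across days
    n_bins = MINUTES_PER_DAY // profile_bin_min
    sums = np.zeros(n_bins)
    cnts = np.zeros(n_bins)
    bin_of = zt // profile_bin_min
    np.add.at(sums, bin_of, asleep.astype(float))
    np.add.at(cnts, bin_of, 1.0 / profile_bin_min)
    with np.errstate(invalid="ignore", divide="ignore"):
        profile = np.where(cnts > 0, sums / np.maximum(cnts, 1e-12), np.nan)
    return SleepSummary(
        fly_id=record.fly_id,
        windows=tuple(windows),
        sleep_min=sleep_min,
        bout_count=bout_count,
        awake_min=awake_min,
        active_min=active_min,
        waking_activity=waking,
        profile_30min=profile,
    )


def exclude_first_day(record: ActivityRecord) -> ActivityRecord:
    """Drop everything before the second ZT0 (the first full day after loading)."""
    zt = record.zt_min()
    zt0s = np.nonzero(zt == 0)[0]
    if zt0s.size < 2:
        raise ValueError("record must span at least two days (a second ZT0)")
    start = int(zt0s[1])
    return ActivityRecord(
        counts=record.counts[start:].copy(), start_zt_min=0, fly_id=record.fly_id
    )


# ---------------------------------------------------------------------------
# Trikinetics DAM monitor files

_N_CHANNELS = 32
_DATE_FMT = "%d %b %y"


def read_dam(path, lights_on: str = "08:00", status_ok: int = 1) -> list[ActivityRecord]:
    """Read a Trikinetics DAM monitor file into one record per channel.

    Dialect (tab-delimited, one row per minute): reading index, date
    ("1 Jan 24"), time ("HH:MM:SS"), monitor status code, six unused
    columns, a light-sensor flag, then 32 channel counts.  Rows whose status
    differs from ``status_ok`` are dropped with a log entry; otherwise a
    malformed row raises DamParseError with its line number.  ``lights_on``
    (HH:MM) anchors ZT0.
    """
    rows = []
    times = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 11 + _N_CHANNELS:
                raise DamParseError(f"line {lineno}: expected >= {11 + _N_CHANNELS} columns")
            try:
                status = int(parts[3])
                stamp = datetime.strptime(f"{parts[1]} {parts[2]}", f"{_DATE_FMT} %H:%M:%S")
                counts = [int(c) for c in parts[11 : 11 + _N_CHANNELS]]
            except ValueError as err:
                raise DamParseError(f"line {lineno}: {err}") from err
            if status != status_ok:
                log.info("dropping status-%d row at line %d", status, lineno)
                continue
            rows.append(counts)
            times.append(stamp)
    if not rows:
        raise DamParseError("no valid data rows in file")
    counts = np.asarray(rows, dtype=int)
    h, m = (int(v) for v in lights_on.split(":"))
    first = times[0]
    start_zt = (first - first.replace(hour=h, minute=m, second=0)).total_seconds() / 60
    start_zt = int(start_zt) % MINUTES_PER_DAY
    return [
        ActivityRecord(counts=counts[:, ch], start_zt_min=start_zt, fly_id=f"ch{ch + 1}")
        for ch in range(_N_CHANNELS)
    ]


def write_dam(
    path,
    records: list[ActivityRecord],
    start: datetime | None = None,
    lights_on: str = "08:00",
    status: int = 1,
):
    """Write records (equal length, <= 32) in the monitor dialect of read_dam."""
    if not records:
        raise ValueError("no records to write")
    n = records[0].n_minutes
    if any(r.n_minutes != n for r in records):
        raise ValueError("all records must have equal length")
    if len(records) > _N_CHANNELS:
        raise ValueError(f"at most {_N_CHANNELS} channels")
    if start is None:
        h, m = (int(v) for v in lights_on.split(":"))
        start = datetime(2024, 1, 1, h, m) + timedelta(minutes=records[0].start_zt_min)
    mat = np.zeros((n, _N_CHANNELS), dtype=int)
    for ch, r in enumerate(records):
        mat[:, ch] = r.counts
    with open(path, "w") as fh:
        for i in range(n):
            stamp = start + timedelta(minutes=i)
            meta = [
                str(i + 1),
                stamp.strftime(_DATE_FMT),
                stamp.strftime("%H:%M:%S"),
                str(status),
            ] + ["0"] * 7
            fh.write("\t".join(meta + [str(c) for c in mat[i]]) + "\n")
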