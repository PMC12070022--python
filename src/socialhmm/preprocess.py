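"""Event-level smartphone logs -> midnight-aligned hourly binary channel series.

Passive monitoring apps record, per participant, intervals of app/phone
activity (start and end timestamp) plus point-like passive sampling events
(Wi-Fi scans, location fixes).  This module aggregates those records into an
hourly grid: per-hour activity fractions per channel, binary activity
indicators after thresholding, and two availability measures derived from the
passive sampling frequency (at least one sample of any kind per hour means the
collection pipeline was alive; at least one location fix per hour means GPS
specifically was alive).

All binning is done in local wall-clock time, taken from each timestamp's own
UTC offset.  On daylight-saving transitions the repeated wall-clock hour is
merged into its first occurrence and the skipped hour simply contains no
events, so it is flagged overall-unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

ACTIVITY_CHANNELS: tuple[str, ...] = (
    "social_media",
    "communication",
    "incoming_call",
    "outgoing_call",
    "phone_usage",
)
SAMPLING_CHANNELS: tuple[str, ...] = ("wifi_sample", "location_sample")
ALL_CHANNELS: tuple[str, ...] = ACTIVITY_CHANNELS + SAMPLING_CHANNELS

HOUR = timedelta(hours=1)


class PreprocessError(ValueError):
    """Raised on malformed event logs or degenerate hourly series."""


@dataclass
class EventLog:
    """Validated per-participant event records in local wall-clock time.

    ``records`` is a DataFrame with columns ``channel`` (one of
    :data:`ALL_CHANNELS`), ``start`` and ``end`` (naive local timestamps,
    ``end >= start``; sampling events may have ``end == start``).
    """

    participant_id: str
    records: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            raise PreprocessError(f"no events for participant {self.participant_id!r}")
        bad = set(self.records["channel"]) - set(ALL_CHANNELS)
        if bad:
            raise PreprocessError(
                f"unknown channel(s) {sorted(bad)} for participant {self.participant_id!r}"
            )
        if (self.records["end"] < self.records["start"]).any():
            row = self.records.index[self.records["end"] < self.records["start"]][0]
            raise PreprocessError(f"record {row}: end precedes start")


@dataclass
class HourlySeries:
    """Hourly activity fractions / binary indicators plus availability masks."""

    participant_id: str
    start: datetime  # naive local timestamp of bin 0 (on the hour)
    channels: tuple[str, ...]
    fractions: np.ndarray  # (T, C) in [0, 1]
    overall_available: np.ndarray  # (T,) bool
    gps_available: np.ndarray  # (T,) bool
    binary: np.ndarray | None = None  # (T, C) in {0, 1}, filled by binarize()
    threshold: float | None = None

    @property
    def T(self) -> int:
        return self.fractions.shape[0]

    @property
    def hour_of_day(self) -> np.ndarray:
        return np.array(
            [(self.start + t * HOUR).hour for t in range(self.T)], dtype=int
        )

    def timestamps(self) -> list[datetime]:
        return [self.start + t * HOUR for t in range(self.T)]


def _wall_clock(value: str | datetime, what: str) -> datetime:
    """Parse an ISO-8601 timestamp and return its local wall-clock naive form.

    Timestamps must carry an explicit UTC offset (or ``Z``); the wall-clock
    time is the time as written in that offset.
    """
    if isinstance(value, datetime):
        ts = value
    else:
        try:
            ts = datetime.fromisoformat(str(value).replace("Z", "+00:00"))
        except ValueError as exc:
            raise PreprocessError(f"unparseable timestamp {value!r} in {what}") from exc
    if ts.tzinfo is None:
        raise PreprocessError(f"timestamp {value!r} in {what} has unknown timezone")
    return ts.replace(tzinfo=None)


def parse_events(df: pd.DataFrame) -> list[EventLog]:
    """Validate a raw event table and split it into per-participant logs.

    Expects columns ``participant_id``, ``channel``, ``start``, ``end`` with
    ISO-8601 offset-carrying timestamps.
    """
    required = {"participant_id", "channel", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise PreprocessError(f"event table is missing column(s) {sorted(missing)}")
    out = df.copy()
    out["start"] = [_wall_clock(v, "start") for v in out["start"]]
    out["end"] = [_wall_clock(v, "end") for v in out["end"]]
    logs = []
    for pid, sub in out.groupby("participant_id", sort=True):
        logs.append(EventLog(str(pid), sub.reset_index(drop=True)))
    return logs


def _floor_hour(ts: datetime) -> datetime:
    return ts.replace(minute=0, second=0, microsecond=0)


def _union_seconds_per_hour(
    intervals: list[tuple[datetime, datetime]], start: datetime, T: int
) -> np.ndarray:
    """Seconds of the union of ``intervals`` falling in each of T hourly bins."""
    seconds = np.zeros(T)
    if not intervals:
        return seconds
    merged: list[list[datetime]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    for s, e in merged:
        t0 = max(0, int((s - start) // HOUR))
        t1 = min(T - 1, int((e - start) // HOUR))
        for t in range(t0, t1 + 1):
            lo = start + t * HOUR
            hi = lo + HOUR
            overlap = (min(e, hi) - max(s, lo)).total_seconds()
            if overlap > 0:
                seconds[t] += overlap
    return seconds


def bin_events_to_hours(log: EventLog) -> HourlySeries:
    """Aggregate an event log into per-hour activity fractions.

    The hour grid runs from the hour containing the earliest record to the
    hour containing the latest record end.  For each activity channel the
    per-hour fraction is the length of the union of that channel's intervals
    intersected with the hour, divided by 3600 s (overlapping same-channel
    events are unioned so fractions never exceed 1; events spanning hour
    boundaries contribute to every hour they overlap).  Availability masks are
    filled by :func:`compute_availability`.
    """
    rec = log.records
    start = _floor_hour(rec["start"].min())
    last = rec["end"].max()
    T = int((last - start) // HOUR) + 1
    fractions = np.zeros((T, len(ACTIVITY_CHANNELS)))
    for c, chan in enumerate(ACTIVITY_CHANNELS):
        sub = rec[rec["channel"] == chan]
        intervals = list(zip(sub["start"], sub["end"]))
        fractions[:, c] = _union_seconds_per_hour(intervals, start, T) / 3600.0
    series = HourlySeries(
        participant_id=log.participant_id,
        start=start,
        channels=ACTIVITY_CHANNELS,
        fractions=np.clip(fractions, 0.0, 1.0),
        overall_available=np.zeros(T, dtype=bool),
        gps_available=np.zeros(T, dtype=bool),
    )
    avail, gps = compute_availability(log, series)
    series.overall_available = avail
    series.gps_available = gps
    return series


def compute_availability(
    log: EventLog, series: HourlySeries
) -> tuple[np.ndarray, np.ndarray]:
    """Per-hour data-availability masks from passive sampling frequency.

    An hour is overall-available when at least one record of *any* type
    (activity interval, Wi-Fi scan, location fix) intersects it; GPS-available
    when at least one location fix falls in it.  Fewer than one sample per
    hour is the signal that collection failed, so absence is never an error.
    """
    T, start = series.T, series.start
    overall = np.zeros(T, dtype=bool)
    gps = np.zeros(T, dtype=bool)

    def hours_touched(s: datetime, e: datetime) -> range:
        t0 = int((s - start) // HOUR)
        if e <= s:  # point event
            return range(max(t0, 0), min(t0 + 1, T))
        t1 = int((e - start) // HOUR)
        if e == start + t1 * HOUR:  # end exactly on a boundary
            t1 -= 1
        return range(max(t0, 0), min(t1 + 1, T))

    for s, e, chan in zip(log.records["start"], log.records["end"], log.records["channel"]):
        for t in hours_touched(s, e):
            overall[t] = True
            if chan == "location_sample":
                gps[t] = True
    return overall, gps


def binarize(series: HourlySeries, threshold: float = 0.0) -> HourlySeries:
    """Threshold hourly fractions into binary activity indicators.

    ``threshold=0`` marks any nonzero activity as 1 (the main analysis rule);
    ``0.05`` / ``0.10`` require at least 5% / 10% of the hour (sensitivity
    analyses).  Raising the threshold can only turn 1s into 0s.
    """
    if not (0.0 <= threshold < 1.0):
        raise PreprocessError(f"threshold {threshold} outside [0, 1)")
    binary = ((series.fractions > 0) & (series.fractions >= threshold)).astype(np.int8)
    return replace(series, binary=binary, threshold=threshold)


def trim_and_align(series: HourlySeries) -> HourlySeries:
    """Drop the first calendar day so the series starts at local midnight.

    Behaviour on the day the app is installed is distorted by study
    onboarding, so every bin up to (and excluding) the first midnight strictly
    after the first record is removed; ``hour_of_day[0]`` is then 0.
    """
    if series.T < 24:
        raise PreprocessError("insufficient data after trimming")
    first_midnight = _floor_hour(series.start).replace(hour=0) + timedelta(days=1)
    offset = int((first_midnight - series.start) // HOUR)
    if offset >= series.T:
        raise PreprocessError("insufficient data after trimming")
    out = replace(
        series,
        start=first_midnight,
        fractions=series.fractions[offset:],
        overall_available=series.overall_available[offset:],
        gps_available=series.gps_available[offset:],
        binary=None if series.binary is None else series.binary[offset:],
    )
    assert out.hour_of_day[0] == 0
    return out


def mask_missing(series: HourlySeries):
    """Convert a binarized series into an observation sequence with NaN
    at hours where overall availability failed (all channels at once; no
    imputation)."""
    from .hmm import ObservationSequence

    if series.binary is None:
        raise PreprocessError("binarize() must be applied before mask_missing()")
    x = series.binary.astype(float)
    x[~series.overall_available, :] = np.nan
    return ObservationSequence(
        participant_id=series.participant_id,
        x=x,
        hour_of_day=series.hour_of_day,
        channels=series.channels,
    )


def preprocess_log(log: EventLog, threshold: float = 0.0) -> HourlySeries:
    """bin -> binarize -> trim convenience wrapper."""
    return trim_and_align(binarize(bin_events_to_hours(log), threshold))
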