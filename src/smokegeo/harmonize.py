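"""Event-stream harmonization: from raw GPS + smoking reports to a labeled
sample table.

Each self-reported smoking timestamp is expanded into a closed window
``[t - H, t + H]`` (the *half-time interval* H, typically 5-30 minutes)
approximating the true duration of the episode. Every GPS fix falling in
the union of these windows is labeled 1 (smoking), all others 0. A window
that contains no fix contributes a *fallback* sample: a smoking-labeled
row at the window centre carrying the coordinates of the fix nearest in
time. Temporal features (day of week, weekend flag, meteorological
season, and the quarter-hour bin of the day) are derived in the
participant's local wall-clock time.

Boundary conventions, chosen once and used everywhere: windows are
closed (membership at either endpoint counts), day bins are half-open
``[start, end)``, window/bin overlap requires strictly positive duration,
and the pre-quit filter is strict (``timestamp < quit``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import EmptyStreamError, FormatError, ValidationError
from .synthetic import parse_utc_offset

logger = logging.getLogger(__name__)

DEFAULT_HALF_TIMES = (5, 10, 15, 20, 30)
SEASONS = ("winter", "spring", "summer", "fall")
_MONTH_SEASON = {12: "winter", 1: "winter", 2: "winter",
                 3: "spring", 4: "spring", 5: "spring",
                 6: "summer", 7: "summer", 8: "summer",
                 9: "fall", 10: "fall", 11: "fall"}


@dataclass
class EventStream:
    """One participant's ordered fixes, reports and metadata."""

    participant_id: str
    fixes: pd.DataFrame  # timestamp, lat, lon (tz-aware, sorted)
    reports: pd.DataFrame  # timestamp, place, reason (tz-aware, sorted)
    enrollment_date: pd.Timestamp | None = None
    timezone: str = "+00:00"
    group: str = ""
    quit_datetime: pd.Timestamp | None = None
    n_malformed: int = 0


@dataclass
class SampleTable:
    """Labeled analysis rows for one participant.

    ``data`` columns: participant_id, timestamp, lat, lon, label,
    is_fallback, source_fix_idx, dow, is_weekend, season, time_bin.
    ``source_fix_idx`` indexes the raw fix a row derives from (fallback
    rows point at the copied fix), letting per-fix spatial representations
    be joined onto the table.
    """

    participant_id: str
    data: pd.DataFrame
    half_time_min: float = 15.0
    bin_width_min: int = 15
    prequit_bounds: tuple[pd.Timestamp, pd.Timestamp] | None = None
    feature_semantics: str = "onehot"  # or "literal_overlap"

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# parsing and filtering
# ---------------------------------------------------------------------------

def _read_timed_csv(path, required: Sequence[str], tz) -> tuple[pd.DataFrame, int]:
    df = pd.read_csv(path)
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True,
                        format="ISO8601")
    bad = ts.isna()
    for col in ("lat", "lon"):
        if col in required:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad |= vals.isna()
            df[col] = vals
    n_bad = int(bad.sum())
    if n_bad:
        logger.warning("%s: skipped %d malformed rows", path, n_bad)
    df = df.loc[~bad].copy()
    df["timestamp"] = ts[~bad].dt.tz_convert(tz)
    df = df.sort_values("timestamp", kind="stable").reset_index(drop=True)
    return df, n_bad


def parse_event_stream(gps_path, reports_path, metadata_row) -> EventStream:
    """Load one participant's raw CSVs, localized to their timezone.

    ``metadata_row`` is a mapping with at least ``participant_id`` and
    ``timezone``; ``enrollment_date``, ``group`` and ``quit_datetime`` are
    carried through when present. Malformed rows (unparseable timestamp
    or coordinates) are counted and dropped with a warning.
    """
    tzinfo = parse_utc_offset(str(metadata_row["timezone"]))
    fixes, bad_f = _read_timed_csv(gps_path, ("timestamp", "lat", "lon"), tzinfo)
    reports, bad_r = _read_timed_csv(reports_path, ("timestamp",), tzinfo)
    if len(fixes) == 0:
        raise EmptyStreamError(f"{gps_path}: no usable GPS fixes")
    quit_dt = metadata_row.get("quit_datetime")
    if quit_dt is not None and not pd.isna(quit_dt):
        quit_dt = pd.Timestamp(quit_dt)
        quit_dt = (quit_dt.tz_convert(tzinfo) if quit_dt.tzinfo
                   else quit_dt.tz_localize(tzinfo))
    else:
        quit_dt = None
    enroll = metadata_row.get("enrollment_date")
    enroll = pd.Timestamp(enroll) if enroll is not None else None
    return EventStream(
        participant_id=str(metadata_row["participant_id"]),
        fixes=fixes, reports=reports,
        enrollment_date=enroll,
        timezone=str(metadata_row["timezone"]),
        group=str(metadata_row.get("group", "")),
        quit_datetime=quit_dt,
        n_malformed=bad_f + bad_r,
    )


def restrict_to_prequit(stream: EventStream, quit_datetime=None) -> EventStream:
    """Keep only data strictly before the quit datetime."""
    quit_dt = quit_datetime if quit_datetime is not None else stream.quit_datetime
    if quit_dt is None:
        raise ValidationError("quit_datetime is required")
    quit_dt = pd.Timestamp(quit_dt)
    if quit_dt.tzinfo is None:
        quit_dt = quit_dt.tz_localize(parse_utc_offset(stream.timezone))
    if stream.enrollment_date is not None:
        enroll = pd.Timestamp(stream.enrollment_date)
        if enroll.tzinfo is None:
            enroll = enroll.tz_localize(quit_dt.tzinfo)
        if quit_dt < enroll:
            raise ValidationError("quit_datetime precedes enrollment")
    fixes = stream.fixes[stream.fixes["timestamp"] < quit_dt].reset_index(drop=True)
    reports = stream.reports[stream.reports["timestamp"] < quit_dt].reset_index(drop=True)
    return EventStream(stream.participant_id, fixes, reports,
                       stream.enrollment_date, stream.timezone, stream.group,
                       quit_dt, stream.n_malformed)


# ---------------------------------------------------------------------------
# windows and labels
# ---------------------------------------------------------------------------

def expand_event_window(report_time, half_time_min: float):
    """Closed window ``[t - H, t + H]`` around a reported smoking time."""
    if half_time_min <= 0:
        raise ValidationError("half_time_min must be > 0")
    t = pd.Timestamp(report_time)
    h = pd.Timedelta(minutes=half_time_min)
    return (t - h, t + h)


def _merged_windows(windows) -> tuple[np.ndarray, np.ndarray]:
    """Union of closed windows as sorted disjoint (starts, ends) in ns."""
    if len(windows) == 0:
        return np.array([], dtype="int64"), np.array([], dtype="int64")
    starts = np.array([pd.Timestamp(a).value for a, _ in windows])
    ends = np.array([pd.Timestamp(b).value for _, b in windows])
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    m_starts, m_ends = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= m_ends[-1]:  # closed intervals: touching windows merge
            m_ends[-1] = max(m_ends[-1], e)
        else:
            m_starts.append(s)
            m_ends.append(e)
    return np.array(m_starts), np.array(m_ends)


def label_samples(fix_times, windows) -> np.ndarray:
    """Binary labels: 1 iff the fix lies in the union of closed windows."""
    ts = pd.DatetimeIndex(fix_times).asi8
    m_starts, m_ends = _merged_windows(windows)
    if len(m_starts) == 0:
        return np.zeros(len(ts), dtype=int)
    pos = np.searchsorted(m_starts, ts, side="right") - 1
    inside = (pos >= 0) & (ts <= m_ends[np.clip(pos, 0, None)])
    return inside.astype(int)


def attach_fallback_samples(windows, fixes: pd.DataFrame) -> pd.DataFrame:
    """One smoking-labeled row per window that contains no fix.

    The row's timestamp is the window centre (used for temporal features)
    and its coordinates come from the fix nearest in time to the window;
    ties break toward the earlier fix. With no fixes at all, no rows are
    added and a warning is emitted.
    """
    if len(fixes) == 0:
        if len(windows):
            logger.warning("participant has no fixes; fallback rows skipped")
        return pd.DataFrame(columns=["timestamp", "lat", "lon",
                                     "source_fix_idx"])
    ts = pd.DatetimeIndex(fixes["timestamp"]).asi8
    rows = []
    for (a, b) in windows:
        av, bv = pd.Timestamp(a).value, pd.Timestamp(b).value
        inside = (ts >= av) & (ts <= bv)
        if inside.any():
            continue
        dist = np.maximum(av - ts, ts - bv)  # one side positive outside
        dist = np.maximum(dist, 0)
        j = int(np.argmin(dist))  # argmin takes the first (earlier) on ties
        center = pd.Timestamp((av + bv) // 2, tz=fixes["timestamp"].dt.tz)
        rows.append({
            "timestamp": center,
            "lat": float(fixes["lat"].iloc[j]),
            "lon": float(fixes["lon"].iloc[j]),
            "source_fix_idx": j,
        })
    return pd.DataFrame(rows, columns=["timestamp", "lat", "lon",
                                       "source_fix_idx"])


# ---------------------------------------------------------------------------
# temporal features
# ---------------------------------------------------------------------------

def temporal_featurize(timestamps, bin_width_min: int = 15) -> pd.DataFrame:
    """Derive calendar features and the local-time bin for each timestamp.

    Returns columns ``dow`` (0=Monday), ``is_weekend``, ``season`` and
    ``time_bin`` (``floor((60*hour + minute) / bin_width)``). Seasons use
    the meteorological month rule (Mar-May spring, Jun-Aug summer,
    Sep-Nov fall, Dec-Feb winter). Timestamps must be timezone-aware.
    """
    idx = pd.DatetimeIndex(timestamps)
    if idx.tz is None:
        raise ValidationError("timestamps must be timezone-aware")
    if bin_width_min <= 0 or (24 * 60) % bin_width_min != 0:
        raise ValidationError("bin_width_min must divide the day evenly")
    dow = idx.dayofweek
    return pd.DataFrame({
        "dow": dow,
        "is_weekend": (dow >= 5).astype(int),
        "season": [_MONTH_SEASON[m] for m in idx.month],
        "time_bin": (idx.hour * 60 + idx.minute) // bin_width_min,
    })


def bin_onehot(time_bins, bin_width_min: int = 15) -> np.ndarray:
    """Expand bin indices to a one-hot matrix with one 1 per row."""
    n_bins = 24 * 60 // bin_width_min
    tb = np.asarray(time_bins, dtype=int)
    out = np.zeros((len(tb), n_bins), dtype=int)
    out[np.arange(len(tb)), tb] = 1
    return out


def interval_overlap_labels(windows, day, bin_width_min: int = 15,
                            tz=None) -> np.ndarray:
    """Per-bin binary vector for one day: 1 iff a smoking window overlaps.

    Bins are half-open ``[start, start + width)``; a bin is 1 only when
    its intersection with the union of (closed) windows has strictly
    positive duration, so a window ending exactly at a bin start leaves
    that bin 0. This is the literal bin-level labeling; as classifier
    input it would leak the outcome, so models use the one-hot
    ``time_bin`` encoding instead (see :func:`temporal_featurize`).
    """
    n_bins = 24 * 60 // bin_width_min
    day_ts = pd.Timestamp(day)
    if day_ts.tzinfo is None and tz is not None:
        day_ts = day_ts.tz_localize(tz)
    day0 = day_ts.normalize()
    bin_starts = day0.value + np.arange(n_bins) * bin_width_min * 60_000_000_000
    bin_ends = bin_starts + bin_width_min * 60_000_000_000
    out = np.zeros(n_bins, dtype=int)
    m_starts, m_ends = _merged_windows(windows)
    for s, e in zip(m_starts, m_ends):
        out |= (s < bin_ends) & (e > bin_starts)
    return out.astype(int)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def build_sample_table(stream: EventStream, half_time_min: float = 15.0,
                       bin_width_min: int = 15,
                       feature_semantics: str = "onehot") -> SampleTable:
    """Compose windows, labels, fallback rows and temporal features.

    ``feature_semantics="literal_overlap"`` additionally attaches, per
    row, the day-level bin-overlap vector (columns ``ov_*``) — the
    literal reading of the quarter-hour binary features. As classifier
    input this encodes the outcome; it exists for the association
    analysis and for literal replication.
    """
    if feature_semantics not in ("onehot", "literal_overlap"):
        raise ValidationError(
            f"unknown feature_semantics '{feature_semantics}'")
    windows = [expand_event_window(t, half_time_min)
               for t in stream.reports["timestamp"]]
    labels = label_samples(stream.fixes["timestamp"], windows)

    base = stream.fixes[["timestamp", "lat", "lon"]].copy()
    base["label"] = labels
    base["is_fallback"] = 0
    base["source_fix_idx"] = np.arange(len(base))

    fb = attach_fallback_samples(windows, stream.fixes)
    if len(fb):
        fb = fb.copy()
        fb["label"] = 1
        fb["is_fallback"] = 1
        base = pd.concat([base, fb], ignore_index=True)

    base = base.sort_values("timestamp", kind="stable").reset_index(drop=True)
    feats = temporal_featurize(base["timestamp"], bin_width_min)
    data = pd.concat([base.reset_index(drop=True), feats], axis=1)
    data.insert(0, "participant_id", stream.participant_id)

    if feature_semantics == "literal_overlap" and len(data):
        tz = data["timestamp"].dt.tz
        days = data["timestamp"].dt.normalize()
        n_bins = 24 * 60 // bin_width_min
        ov = np.zeros((len(data), n_bins), dtype=int)
        for day, idx in days.groupby(days).groups.items():
            vec = interval_overlap_labels(windows, day, bin_width_min, tz)
            ov[np.asarray(idx)] = vec
        data = pd.concat(
            [data, pd.DataFrame(ov, columns=[f"ov_{b}"
                                             for b in range(n_bins)])],
            axis=1)

    bounds = None
    if stream.quit_datetime is not None and len(data):
        bounds = (data["timestamp"].iloc[0], stream.quit_datetime)
    return SampleTable(stream.participant_id, data,
                       half_time_min=half_time_min,
                       bin_width_min=bin_width_min,
                       prequit_bounds=bounds,
                       feature_semantics=feature_semantics)
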