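"""Harmonization: parsing, pre-quit filtering, window expansion,
labeling (with the brute-force oracle), fallback rows, temporal features
and the bin-overlap construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from smokegeo.errors import (EmptyStreamError, FormatError, ValidationError)
from smokegeo.harmonize import (EventStream, attach_fallback_samples,
                                bin_onehot, build_sample_table,
                                expand_event_window, interval_overlap_labels,
                                label_samples, parse_event_stream,
                                restrict_to_prequit, temporal_featurize)
from .conftest import TZ, make_ts, random_stream

META = {"participant_id": "P01", "timezone": TZ,
        "enrollment_date": "2023-03-06"}


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


def test_parse_sorts_rows_and_counts_malformed(tmp_path):
    gps = _write(tmp_path, "g.csv",
                 "participant_id,timestamp,lat,lon\n"
                 f"P01,2023-03-06T12:00:00{TZ},40.0,-90.0\n"
                 f"P01,2023-03-06T09:00:00{TZ},40.1,-90.1\n"
                 f"P01,not-a-time,40.2,-90.2\n"
                 f"P01,2023-03-06T10:00:00{TZ},40.3,-90.3\n")
    rep = _write(tmp_path, "r.csv",
                 "participant_id,timestamp,place,reason\n"
                 f"P01,2023-03-06T11:00:00{TZ},home,habit\n")
    stream = parse_event_stream(gps, rep, META)
    assert len(stream.fixes) == 3
    assert stream.n_malformed == 1
    assert stream.fixes["timestamp"].is_monotonic_increasing


def test_parse_missing_column_names_it(tmp_path):
    gps = _write(tmp_path, "g.csv",
                 "participant_id,timestamp,lat\nP01,2023-03-06T09:00:00-06:00,40\n")
    rep = _write(tmp_path, "r.csv", "participant_id,timestamp\n")
    with pytest.raises(FormatError, match="lon"):
        parse_event_stream(gps, rep, META)


def test_parse_empty_gps_raises(tmp_path):
    gps = _write(tmp_path, "g.csv", "participant_id,timestamp,lat,lon\n")
    rep = _write(tmp_path, "r.csv", "participant_id,timestamp\n")
    with pytest.raises(EmptyStreamError):
        parse_event_stream(gps, rep, META)


# ---------------------------------------------------------------------------
# pre-quit restriction
# ---------------------------------------------------------------------------

def _stream(fixes, reports):
    return EventStream("P01", fixes, reports, timezone=TZ,
                       enrollment_date=pd.Timestamp("2023-03-06"))


def test_prequit_boundary_is_strict(rng):
    fixes, reports = random_stream(rng)
    quit_dt = reports["timestamp"].iloc[3]
    out = restrict_to_prequit(_stream(fixes, reports), quit_dt)
    # brute-force: strictly-before counts
    assert len(out.fixes) == int((fixes["timestamp"] < quit_dt).sum())
    assert len(out.reports) == int((reports["timestamp"] < quit_dt).sum())
    assert quit_dt not in set(out.reports["timestamp"])


def test_prequit_identity_when_all_before(rng):
    fixes, reports = random_stream(rng)
    out = restrict_to_prequit(_stream(fixes, reports),
                              make_ts("2024-01-01", 0, 0))
    assert len(out.fixes) == len(fixes)


def test_prequit_before_enrollment_rejected(rng):
    fixes, reports = random_stream(rng)
    with pytest.raises(ValidationError):
        restrict_to_prequit(_stream(fixes, reports), make_ts("2020-01-01", 0, 0))


# ---------------------------------------------------------------------------
# windows and labels
# ---------------------------------------------------------------------------

def test_window_expansion_matches_worked_example():
    start, end = expand_event_window(make_ts("2023-03-06", 9, 10), 15)
    assert start == make_ts("2023-03-06", 8, 55)
    assert end == make_ts("2023-03-06", 9, 25)


def test_window_spans_midnight():
    start, end = expand_event_window(make_ts("2023-03-06", 0, 5), 10)
    assert start == make_ts("2023-03-05", 23, 55)
    assert end == make_ts("2023-03-06", 0, 15)
    assert (end - start) == pd.Timedelta(minutes=20)


def test_nonpositive_half_time_rejected():
    with pytest.raises(ValidationError):
        expand_event_window(make_ts("2023-03-06", 9, 10), 0)


def test_label_membership_is_closed_at_boundaries():
    w = [expand_event_window(make_ts("2023-03-06", 9, 10), 15)]
    ts = [make_ts("2023-03-06", 9, 0),   # interior
          make_ts("2023-03-06", 9, 25),  # exact end, inclusive
          make_ts("2023-03-06", 8, 55),  # exact start, inclusive
          make_ts("2023-03-06", 9, 26)]  # outside
    assert list(label_samples(ts, w)) == [1, 1, 1, 0]


def _oracle_labels(fix_times, windows):
    out = []
    for t in fix_times:
        out.append(int(any(a <= t <= b for a, b in windows)))
    return out


def test_labels_match_bruteforce_oracle_on_random_streams(rng):
    for _ in range(20):
        fixes, reports = random_stream(rng, n_fixes=60, n_reports=10)
        for h in (5, 30):
            windows = [expand_event_window(t, h)
                       for t in reports["timestamp"]]
            got = list(label_samples(fixes["timestamp"], windows))
            assert got == _oracle_labels(fixes["timestamp"], windows)


def test_labeled_sets_nest_as_half_time_grows(rng):
    fixes, reports = random_stream(rng, n_fixes=120, n_reports=12)
    prev = None
    for h in (5, 10, 15, 20, 30):
        windows = [expand_event_window(t, h) for t in reports["timestamp"]]
        lbl = label_samples(fixes["timestamp"], windows)
        if prev is not None:
            assert np.all(lbl >= prev)  # smaller-H positives stay positive
        prev = lbl


# ---------------------------------------------------------------------------
# fallback samples
# ---------------------------------------------------------------------------

def _fixes_at(times):
    return pd.DataFrame({
        "timestamp": pd.DatetimeIndex(times),
        "lat": np.linspace(40, 40.001, len(times)),
        "lon": np.full(len(times), -90.0),
    })


def test_no_fallback_when_window_has_interior_fix():
    fixes = _fixes_at([make_ts("2023-03-06", 9, 0)])
    w = [(make_ts("2023-03-06", 8, 55), make_ts("2023-03-06", 9, 25))]
    assert len(attach_fallback_samples(w, fixes)) == 0


def test_fallback_copies_nearest_fix_by_time():
    fixes = _fixes_at([make_ts("2023-03-06", 8, 30),
                       make_ts("2023-03-06", 10, 0)])
    w = [(make_ts("2023-03-06", 8, 55), make_ts("2023-03-06", 9, 25))]
    fb = attach_fallback_samples(w, fixes)
    assert len(fb) == 1
    # 08:30 is 25 min before the window start; 10:00 is 35 min after end
    assert fb["lat"].iloc[0] == fixes["lat"].iloc[0]
    assert fb["source_fix_idx"].iloc[0] == 0
    assert fb["timestamp"].iloc[0] == make_ts("2023-03-06", 9, 10)


def test_fallback_tie_breaks_to_earlier_fix():
    fixes = _fixes_at([make_ts("2023-03-06", 8, 45),
                       make_ts("2023-03-06", 9, 35)])
    w = [(make_ts("2023-03-06", 8, 55), make_ts("2023-03-06", 9, 25))]
    fb = attach_fallback_samples(w, fixes)
    assert fb["source_fix_idx"].iloc[0] == 0


def test_fallback_without_any_fix_adds_nothing():
    fixes = _fixes_at([]).iloc[0:0]
    w = [(make_ts("2023-03-06", 8, 55), make_ts("2023-03-06", 9, 25))]
    assert len(attach_fallback_samples(w, fixes)) == 0


# ---------------------------------------------------------------------------
# temporal features
# ---------------------------------------------------------------------------

def test_quarter_hour_bin_of_worked_example_timestamp():
    f = temporal_featurize([make_ts("2023-03-06", 9, 10)], 15)
    assert f["time_bin"].iloc[0] == 36  # floor(550 / 15)


def test_weekend_and_season_rules():
    f = temporal_featurize([make_ts("2023-07-08", 12, 0),   # Saturday, July
                            make_ts("2023-03-06", 12, 0)], 15)  # Monday, March
    assert list(f["is_weekend"]) == [1, 0]
    assert list(f["season"]) == ["summer", "spring"]


def test_naive_timestamp_rejected():
    with pytest.raises(ValidationError):
        temporal_featurize([pd.Timestamp("2023-03-06 09:10:00")], 15)


@given(minutes=st.integers(0, 24 * 60 - 1))
@settings(max_examples=60, deadline=None)
def test_bin_onehot_has_exactly_one_active_bin(minutes):
    ts = make_ts("2023-03-06", minutes // 60, minutes % 60)
    f = temporal_featurize([ts], 15)
    oh = bin_onehot(f["time_bin"], 15)
    assert oh.shape == (1, 96)
    assert oh.sum() == 1
    assert oh[0, minutes // 15] == 1


@pytest.mark.parametrize("width,n_bins", [(15, 96), (30, 48)])
def test_day_partition_bin_counts(width, n_bins):
    labels = interval_overlap_labels([], "2023-03-06", width, tz=TZ)
    assert len(labels) == n_bins
    assert labels.sum() == 0


def test_interval_overlap_matches_worked_example():
    w = [expand_event_window(make_ts("2023-03-06", 9, 10), 15)]
    labels = interval_overlap_labels(w, make_ts("2023-03-06", 0, 0), 15)
    on = np.nonzero(labels)[0]
    assert list(on) == [35, 36, 37]  # 8:45-9:00, 9:00-9:15, 9:15-9:30


def test_zero_measure_overlap_leaves_bin_unset():
    # window ends exactly at the 09:15 bin start: no positive overlap
    w = [(make_ts("2023-03-06", 8, 45), make_ts("2023-03-06", 9, 15))]
    labels = interval_overlap_labels(w, make_ts("2023-03-06", 0, 0), 15)
    assert labels[37] == 0
    assert labels[35] == 1 and labels[36] == 1


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def test_table_with_no_reports_is_all_negative(rng):
    fixes, _ = random_stream(rng, n_reports=0)
    stream = _stream(fixes, pd.DataFrame({"timestamp":
                                          pd.DatetimeIndex([], tz=TZ)}))
    t = build_sample_table(stream, 15, 15)
    assert len(t) == len(fixes)
    assert t.data["label"].sum() == 0
    assert t.data["is_fallback"].sum() == 0


def _oracle_table(fixes, reports, h):
    """Independent per-row recomputation of labels and fallback rows."""
    windows = [(t - pd.Timedelta(minutes=h), t + pd.Timedelta(minutes=h))
               for t in reports["timestamp"]]
    rows = []
    for i in range(len(fixes)):
        t = fixes["timestamp"].iloc[i]
        lbl = int(any(a <= t <= b for a, b in windows))
        rows.append((t, float(fixes["lat"].iloc[i]), lbl, 0))
    for a, b in windows:
        if any(a <= fixes["timestamp"].iloc[i] <= b
               for i in range(len(fixes))):
            continue
        dists = [max((a - t).value, (t - b).value, 0)
                 for t in fixes["timestamp"]]
        j = int(np.argmin(dists))
        center = a + (b - a) / 2
        rows.append((center, float(fixes["lat"].iloc[j]), 1, 1))
    rows.sort(key=lambda r: r[0])
    return rows


def test_sample_table_matches_row_by_row_oracle(rng):
    for _ in range(10):
        fixes, reports = random_stream(rng, n_fixes=40, n_reports=8)
        stream = _stream(fixes, reports)
        t = build_sample_table(stream, 15, 15).data
        oracle = _oracle_table(fixes, reports, 15)
        assert len(t) == len(oracle)
        for (ts, lat, lbl, fb), row in zip(oracle, t.itertuples()):
            assert row.timestamp == ts
            assert row.lat == lat
            assert row.label == lbl
            assert row.is_fallback == fb


def test_literal_overlap_semantics_attach_day_vectors(rng):
    fixes, reports = random_stream(rng, n_fixes=30, n_reports=5)
    stream = _stream(fixes, reports)
    t = build_sample_table(stream, 15, 15, feature_semantics="literal_overlap")
    ov_cols = [c for c in t.data.columns if c.startswith("ov_")]
    assert len(ov_cols) == 96
    windows = [expand_event_window(ts, 15) for ts in reports["timestamp"]]
    row = t.data.iloc[0]
    expected = interval_overlap_labels(windows, row["timestamp"].normalize(),
                                       15)
    assert np.array_equal(row[ov_cols].to_numpy(dtype=int), expected)
    # rows sharing a calendar day share the vector
    days = t.data["timestamp"].dt.normalize()
    for _, grp in t.data.groupby(days):
        assert grp[ov_cols].drop_duplicates().shape[0] == 1


def test_row_count_is_fixes_plus_empty_windows(rng):
    fixes, reports = random_stream(rng, n_fixes=30, n_reports=10)
    stream = _stream(fixes, reports)
    t = build_sample_table(stream, 5, 15)
    assert len(t) >= len(fixes)
    n_fb = int(t.data["is_fallback"].sum())
    assert len(t) == len(fixes) + n_fb
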