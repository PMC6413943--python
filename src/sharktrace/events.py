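"""Residence-event segmentation of per-tag detection streams.

A residence event is a contiguous bout of detections of one tag at one
receiver. Following the V-track criteria used for VEMCO receiver arrays, an
event at station ``S``:

* opens once ``min_pings`` successive detections at ``S`` occur with
  inter-detection gaps no larger than ``timeout_s`` (event start is the
  first of those detections);
* is extended by further detections at ``S`` while open;
* closes when the gap since its last ``S`` detection exceeds ``timeout_s``
  (*timeout*), when ``other_station_pings`` detections at a *single* other
  station have accumulated since the last ``S`` detection (*other_station*
  — those detections then seed the candidate event at the new station), or
  when the stream ends (*stream_end*).

The defaults (2 pings, 900 s, cross-receiver termination after 2 pings
elsewhere) are the thresholds used for scalloped hammerhead sharks at the
Cocos Island array. Events shorter than the time a shark cruising at
~0.5 m/s needs to cross a receiver's detection range (15 min) are classed
as transits rather than visits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EVENT_COLUMNS = [
    "tag_id",
    "station_id",
    "start",
    "end",
    "n_detections",
    "duration_s",
    "termination_reason",
]

#: Default segmentation thresholds (pings, seconds, pings).
MIN_PINGS = 2
TIMEOUT_S = 900.0
OTHER_STATION_PINGS = 2

#: Default transit threshold: minutes to swim across the detection range at 0.5 m/s.
TRANSIT_MIN = 15.0


class _Run:
    """A candidate run of detections at one station obeying the gap rule."""

    __slots__ = ("first", "last", "n")

    def __init__(self, t: float) -> None:
        self.first = t
        self.last = t
        self.n = 1

    def extend_or_reset(self, t: float, timeout_s: float) -> None:
        if t - self.last <= timeout_s:
            self.last = t
            self.n += 1
        else:
            self.first = t
            self.last = t
            self.n = 1


def segment_events(
    detections: pd.DataFrame,
    min_pings: int = MIN_PINGS,
    timeout_s: float = TIMEOUT_S,
    other_station_pings: int = OTHER_STATION_PINGS,
) -> pd.DataFrame:
    """Segment the detection stream of a single tag into residence events.

    Parameters
    ----------
    detections
        Canonical detections of one tag, sorted by ``(timestamp, station_id)``.
    min_pings
        Successive pings at a receiver (gaps <= ``timeout_s``) required
        before an event is recorded.
    timeout_s
        Maximum inter-detection gap, in seconds, inside an event.
    other_station_pings
        Detections at a single different receiver, since the last detection
        at the event's receiver, that terminate the event.

    Returns
    -------
    DataFrame with one row per event: ``tag_id, station_id, start, end,
    n_detections, duration_s, termination_reason``. Event end is the last
    detection at the event's station; duration is ``end - start`` seconds.

    Raises
    ------
    ValueError
        If the detections are unsorted or span more than one tag.
    """
    if detections.empty:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    tags = detections["tag_id"].unique()
    if len(tags) > 1:
        raise ValueError(f"segment_events expects one tag, got {sorted(tags)}")
    ts = detections["timestamp"].to_numpy()
    if np.any(np.diff(ts) < np.timedelta64(0, "ns")):
        raise ValueError("detections must be sorted by timestamp")
    # integer nanoseconds: exact gap arithmetic at epoch magnitudes
    t = ts.astype("datetime64[ns]").astype("int64")
    timeout_ns = 2**62 if np.isinf(timeout_s) else int(round(timeout_s * 1e9))
    stations = detections["station_id"].to_numpy()
    tag = str(tags[0])

    events: list[tuple] = []
    open_station: str | None = None
    open_first = open_last = 0
    open_n = 0
    runs: dict[str, _Run] = {}

    def close(reason: str) -> None:
        nonlocal open_station
        events.append((tag, open_station, open_first, open_last, open_n, reason))
        open_station = None

    for ti, si in zip(t, stations):
        if open_station is not None and ti - open_last > timeout_ns:
            close("timeout")
        if open_station is not None and si == open_station:
            open_last = ti
            open_n += 1
            # cross-station accumulation counts only detections since the
            # last detection at the event's own station
            runs.clear()
            continue
        run = runs.get(si)
        if run is None:
            runs[si] = run = _Run(ti)
        else:
            run.extend_or_reset(ti, timeout_ns)
        if open_station is not None:
            if run.n >= other_station_pings:
                close("other_station")
            else:
                continue
        if run.n >= min_pings:
            open_station = si
            open_first = run.first
            open_last = run.last
            open_n = run.n
            runs.clear()
    if open_station is not None:
        close("stream_end")

    if not events:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    out = pd.DataFrame(events, columns=["tag_id", "station_id", "_start", "_end", "n_detections", "termination_reason"])
    out["start"] = pd.to_datetime(out.pop("_start").astype("int64"))
    out["end"] = pd.to_datetime(out.pop("_end").astype("int64"))
    out["duration_s"] = (out["end"] - out["start"]).dt.total_seconds()
    return out[EVENT_COLUMNS]


def segment_all(
    detections: pd.DataFrame,
    min_pings: int = MIN_PINGS,
    timeout_s: float = TIMEOUT_S,
    other_station_pings: int = OTHER_STATION_PINGS,
) -> pd.DataFrame:
    """Segment every tag's stream; concatenation of per-tag :func:`segment_events`."""
    parts = [
        segment_events(grp, min_pings, timeout_s, other_station_pings)
        for _, grp in detections.groupby("tag_id", sort=True)
    ]
    if not parts:
        return pd.DataFrame(columns=EVENT_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def classify_visits(events: pd.DataFrame, transit_min: float = TRANSIT_MIN) -> pd.DataFrame:
    """Flag transit events: strictly shorter than ``transit_min`` minutes.

    An event whose duration equals the threshold exactly is a visit, not a
    transit. Returns the events with an added boolean ``is_transit`` column.
    """
    visits = events.copy()
    visits["is_transit"] = visits["duration_s"] < transit_min * 60.0
    return visits


def visit_counts(visits: pd.DataFrame) -> pd.DataFrame:
    """Per-station counts of visits (non-transit) and transits."""
    if visits.empty:
        return pd.DataFrame(columns=["station_id", "n_visits", "n_transits"])
    g = visits.groupby("station_id")["is_transit"]
    out = pd.DataFrame({"n_visits": (g.count() - g.sum()).astype(int), "n_transits": g.sum().astype(int)})
    return out.reset_index()
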