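"""Residency indices, daily presence matrices and tagging-bias correction.

The residency index (RI) of a tagged animal is the number of calendar days
on which it was detected anywhere on the monitored island, divided by the
number of days from its tagging date through its last detection date
(both inclusive). RI = 1 means the animal was detected every day of its
monitoring period; values near 0 mean detections were sparse relative to
the track length. Days are behavioural (local-time) days, controlled by a
UTC offset (default −6 h, Cocos Island time).

Because the first visit at the tagging location is confounded by the
tagging operation itself (the animal was already there when tagged), site
preference analyses discard the start of each track until the animal is
first seen at another site, or has been absent from its tagging site for
at least 24 h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: Local-time offset applied when converting UTC instants to behavioural days.
DEFAULT_UTC_OFFSET_H = -6.0


def local_dates(timestamps: pd.Series, utc_offset_hours: float = DEFAULT_UTC_OFFSET_H) -> pd.Series:
    """Calendar date of each UTC instant in the local frame of the island."""
    return (timestamps + pd.to_timedelta(utc_offset_hours, unit="h")).dt.date


def monitoring_duration(
    tag_date, detections: pd.DataFrame, utc_offset_hours: float = DEFAULT_UTC_OFFSET_H
) -> int:
    """Days from tagging through the last detection, inclusive of both dates.

    An animal tagged and last detected on the same date has a monitoring
    duration of 1 day. Raises ``ValueError`` when the tag has no detections
    (such tags are excluded from RI summaries) or when detections precede
    the tagging date.
    """
    if detections.empty:
        raise ValueError("tag has no detections; monitoring duration undefined")
    tag_date = pd.Timestamp(tag_date).date()
    last = max(local_dates(detections["timestamp"], utc_offset_hours))
    days = (last - tag_date).days + 1
    if days < 1:
        raise ValueError(f"last detection {last} precedes tagging date {tag_date}")
    return days


def residency_index(n_detected_days: int, monitoring_days: int) -> float:
    """Detected days over monitoring days; in (0, 1] for any detected tag."""
    if monitoring_days < 1:
        raise ValueError("monitoring_days must be >= 1")
    return n_detected_days / monitoring_days


def track_summaries(
    detections: pd.DataFrame,
    tags: pd.DataFrame,
    utc_offset_hours: float = DEFAULT_UTC_OFFSET_H,
    stations: pd.DataFrame | None = None,
    island_id: str | None = None,
) -> pd.DataFrame:
    """Per-tag monitoring duration, detected-day count and residency index.

    When ``island_id`` is given (with the station table), only detections at
    that island's receivers count as presence. Tags without detections are
    returned with ``n_detections = 0`` and NaN summaries so callers can
    report them as excluded.
    """
    det = detections
    if island_id is not None:
        if stations is None:
            raise ValueError("stations table required to filter by island_id")
        keep = set(stations.loc[stations["island_id"] == island_id, "station_id"])
        det = det[det["station_id"].isin(keep)]
    rows = []
    for _, trow in tags.iterrows():
        tid = str(trow["tag_id"])
        d = det[det["tag_id"] == tid]
        if d.empty:
            rows.append((tid, trow["tag_date"], pd.NaT, 0, np.nan, np.nan, np.nan))
            continue
        dates = local_dates(d["timestamp"], utc_offset_hours)
        mon = monitoring_duration(trow["tag_date"], d, utc_offset_hours)
        ndays = int(dates.nunique())
        rows.append((tid, trow["tag_date"], max(dates), len(d), mon, ndays, ndays / mon))
    return pd.DataFrame(
        rows,
        columns=[
            "tag_id",
            "tag_date",
            "last_detection_date",
            "n_detections",
            "monitoring_days",
            "n_detected_days",
            "residency_index",
        ],
    )


def daily_presence_matrix(
    detections: pd.DataFrame,
    tags: pd.DataFrame,
    utc_offset_hours: float = DEFAULT_UTC_OFFSET_H,
    season_start: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Binary tag x date presence matrix (1 = detected that local day).

    With ``season_start=(month, day)`` — e.g. ``(7, 1)`` to standardise
    tracks to July 1st — columns become integer day-of-season offsets from
    the most recent season start on or before each date, pooling years.
    """
    if detections.empty:
        return pd.DataFrame(index=tags["tag_id"].astype(str))
    dates = pd.Series(local_dates(detections["timestamp"], utc_offset_hours), name="date")
    frame = pd.DataFrame({"tag_id": detections["tag_id"].to_numpy(), "date": dates.to_numpy()})
    if season_start is not None:
        month, day = season_start

        def day_of_season(d) -> int:
            anchor = d.replace(month=month, day=day)
            if d < anchor:
                anchor = anchor.replace(year=d.year - 1)
            return (d - anchor).days

        frame["date"] = frame["date"].map(day_of_season)
    mat = pd.crosstab(frame["tag_id"], frame["date"])
    mat = (mat > 0).astype(int)
    mat = mat.reindex(tags["tag_id"].astype(str), fill_value=0)
    if season_start is None:
        full = pd.date_range(min(mat.columns), max(mat.columns), freq="D").date
        mat = mat.reindex(columns=full, fill_value=0)
    else:
        mat = mat.reindex(columns=range(0, max(mat.columns) + 1), fill_value=0)
    mat.index.name = "tag_id"
    return mat


@dataclass
class CorrectedTrack:
    """Outcome of the tagging-bias correction for one tag's visit sequence."""

    tag_id: str
    correction_rule_applied: str  # other_site_first | absent_24h | none_applicable
    analysis_start: pd.Timestamp | None
    visits_retained: pd.DataFrame = field(repr=False)


def correct_tagging_bias(
    visits: pd.DataFrame | CorrectedTrack,
    tag_station: str | None = None,
    absence_h: float = 24.0,
) -> CorrectedTrack:
    """Drop the confounded initial portion of a track at the tagging site.

    The analysis window starts at the earlier of

    a) the start of the first visit at any station other than the tagging
       station (``other_site_first``), and
    b) the start of the first visit at the tagging station that follows an
       absence of at least ``absence_h`` hours from that station
       (``absent_24h``).

    Visits starting before the analysis start are dropped. If neither rule
    ever fires (all visits at the tagging station, never absent long
    enough), the whole track is dropped with rule ``none_applicable``.

    The corrected state is explicit in the return type: passing a
    :class:`CorrectedTrack` back in returns it unchanged, which makes the
    correction idempotent.
    """
    if isinstance(visits, CorrectedTrack):
        return visits
    if tag_station is None:
        raise ValueError("tag_station is required when correcting raw visits")
    tag_station = str(tag_station)
    v = visits.sort_values("start", kind="stable").reset_index(drop=True)
    tag_id = str(v["tag_id"].iloc[0]) if len(v) else ""

    trigger_a = None
    other = v[v["station_id"] != tag_station]
    if len(other):
        trigger_a = other["start"].iloc[0]

    trigger_b = None
    at_tag = v[v["station_id"] == tag_station]
    if len(at_tag) >= 2:
        gaps = (at_tag["start"].iloc[1:].to_numpy() - at_tag["end"].iloc[:-1].to_numpy())
        hits = np.flatnonzero(gaps >= np.timedelta64(int(absence_h * 3600), "s"))
        if hits.size:
            trigger_b = at_tag["start"].iloc[int(hits[0]) + 1]

    triggers = [t for t in (trigger_a, trigger_b) if t is not None]
    if not triggers:
        return CorrectedTrack(tag_id, "none_applicable", None, v.iloc[0:0])
    start = min(triggers)
    rule = "other_site_first" if trigger_a is not None and trigger_a <= start else "absent_24h"
    return CorrectedTrack(tag_id, rule, start, v[v["start"] >= start].reset_index(drop=True))


def correct_cohort(
    visits: pd.DataFrame, tags: pd.DataFrame, absence_h: float = 24.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the tagging-bias correction per tag and pool retained visits.

    Returns ``(retained_visits, per_tag_rules)``.
    """
    tag_station = dict(zip(tags["tag_id"].astype(str), tags["tag_station"].astype(str)))
    kept, rules = [], []
    for tid, grp in visits.groupby("tag_id", sort=True):
        tid = str(tid)
        if tid not in tag_station:
            raise ValueError(f"no tag metadata for tag {tid}")
        track = correct_tagging_bias(grp, tag_station[tid], absence_h)
        rules.append((tid, track.correction_rule_applied, track.analysis_start))
        kept.append(track.visits_retained)
    kept_df = pd.concat(kept, ignore_index=True) if kept else visits.iloc[0:0]
    rules_df = pd.DataFrame(rules, columns=["tag_id", "rule", "analysis_start"])
    return kept_df, rules_df


def summarize_ri(summaries: pd.DataFrame, min_monitoring_days: int = 0) -> dict:
    """Cohort mean ± sample SD of RI over tags monitored at least ``min_monitoring_days``.

    With a single tag the SD is undefined and reported as 0.0 alongside
    ``n = 1``; an empty cohort yields a NaN sentinel summary.
    """
    sel = summaries.dropna(subset=["residency_index"])
    sel = sel[sel["monitoring_days"] >= min_monitoring_days]
    n = len(sel)
    if n == 0:
        return {"mean_ri": np.nan, "sd_ri": np.nan, "n": 0}
    ri = sel["residency_index"].to_numpy(float)
    return {
        "mean_ri": float(ri.mean()),
        "sd_ri": float(ri.std(ddof=1)) if n > 1 else 0.0,
        "n": n,
    }


def ri_duration_correlation(summaries: pd.DataFrame, min_monitoring_days: int = 0) -> dict:
    """Pearson correlation between monitoring duration and RI (r, df = n−2, p)."""
    sel = summaries.dropna(subset=["residency_index"])
    sel = sel[sel["monitoring_days"] >= min_monitoring_days]
    if len(sel) < 3:
        return {"r": np.nan, "df": max(len(sel) - 2, 0), "p": np.nan}
    r, p = stats.pearsonr(sel["monitoring_days"], sel["residency_index"])
    return {"r": float(r), "df": len(sel) - 2, "p": float(p)}
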