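"""Read, validate and write the tabular inputs and outputs of the pipeline.

Canonical in-memory representations are plain pandas DataFrames:

detections
    columns ``tag_id`` (str), ``station_id`` (str), ``timestamp``
    (tz-naive ``datetime64[ns]`` interpreted as UTC), sorted by
    ``(tag_id, timestamp, station_id)`` with exact duplicates collapsed.
stations
    columns ``station_id``, ``name``, ``latitude``, ``longitude``,
    ``depth_m``, ``island_id``.
deployments
    columns ``station_id``, ``start``, ``end`` — half-open ``[start, end)``
    windows during which a receiver was in the water and recording.
tags
    columns ``tag_id``, ``tag_date`` (date), ``tag_station``, ``sex``
    (``F``/``M``/``ND``), ``island_id``, ``battery_days``.

All intervals in the package are half-open ``[start, end)``; timestamps are
stored in UTC and converted to local time only where behaviour (days at the
island, diel statistics) requires it.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

DETECTION_COLUMNS = ["tag_id", "station_id", "timestamp"]

#: Default mapping from canonical column name to the column name in the file.
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "tag_id": "tag_id",
    "station_id": "station_id",
    "timestamp": "timestamp",
}


class TelemetryIOError(ValueError):
    """Raised for malformed or referentially inconsistent input files."""


def _parse_timestamps(raw: pd.Series) -> pd.Series:
    ts = pd.to_datetime(raw, utc=True, errors="coerce", format="mixed")
    bad = ts.isna() & raw.notna()
    if bad.any():
        # +2: 1-based line numbers and a header row
        lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())[:5]]
        raise TelemetryIOError(
            f"unparseable timestamp(s) at file line(s) {lines}: "
            f"{raw[bad].head().tolist()}"
        )
    return ts.dt.tz_convert("UTC").dt.tz_localize(None)


def canonicalize_detections(det: pd.DataFrame, stations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Sort, deduplicate and referentially validate a detection frame.

    Sorting is total: ``(tag_id, timestamp, station_id)`` with a stable sort,
    so same-instant detections at two receivers (overlapping ranges) are
    ordered by station identifier. Rows identical in all three fields are
    collapsed to one.
    """
    det = det.loc[:, DETECTION_COLUMNS].copy()
    det["tag_id"] = det["tag_id"].astype(str)
    det["station_id"] = det["station_id"].astype(str)
    if not np.issubdtype(det["timestamp"].dtype, np.datetime64):
        det["timestamp"] = _parse_timestamps(det["timestamp"])
    if stations is not None:
        known = set(stations["station_id"].astype(str))
        unknown = sorted(set(det["station_id"]) - known)
        if unknown:
            raise TelemetryIOError(f"detections reference unknown station_id(s): {unknown}")
    det = det.sort_values(["tag_id", "timestamp", "station_id"], kind="stable")
    det = det.drop_duplicates(DETECTION_COLUMNS, keep="first")
    return det.reset_index(drop=True)


def read_detections(
    path,
    stations: pd.DataFrame | None = None,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> pd.DataFrame:
    """Read a detection log (one row per received ping) into canonical form.

    Parameters
    ----------
    path
        Delimited text file with a header row naming tag, station and
        timestamp columns.
    stations
        Station table used for referential validation; unknown station
        identifiers are a hard error listing the offenders.
    column_map
        Mapping canonical name -> file column name, for receiver-export
        headers that differ from the canonical ones.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=delimiter, dtype=str)
    missing = [v for v in cmap.values() if v not in raw.columns]
    if missing:
        raise TelemetryIOError(f"missing column(s) {missing} in {path}; found {list(raw.columns)}")
    det = pd.DataFrame({canon: raw[src] for canon, src in cmap.items()})
    return canonicalize_detections(det, stations)


def write_detections(det: pd.DataFrame, path) -> None:
    """Write canonical detections as CSV with ISO-8601 UTC timestamps."""
    out = det.copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_stations(path, delimiter: str = ",") -> pd.DataFrame:
    st = pd.read_csv(path, sep=delimiter)
    required = {"station_id", "latitude", "longitude", "island_id"}
    missing = required - set(st.columns)
    if missing:
        raise TelemetryIOError(f"station table missing column(s) {sorted(missing)}")
    st["station_id"] = st["station_id"].astype(str)
    if "name" not in st.columns:
        st["name"] = st["station_id"]
    if "depth_m" not in st.columns:
        st["depth_m"] = np.nan
    return st.reset_index(drop=True)


def read_deployments(path, delimiter: str = ",") -> pd.DataFrame:
    dep = pd.read_csv(path, sep=delimiter)
    dep["station_id"] = dep["station_id"].astype(str)
    dep["start"] = _parse_timestamps(dep["start"])
    dep["end"] = _parse_timestamps(dep["end"])
    validate_deployment_windows(dep)
    return dep.reset_index(drop=True)


def validate_deployment_windows(dep: pd.DataFrame) -> None:
    """Check windows are well formed: start < end, non-overlapping per station."""
    if (dep["start"] >= dep["end"]).any():
        bad = dep.loc[dep["start"] >= dep["end"]]
        raise TelemetryIOError(f"deployment window(s) with start >= end:\n{bad}")
    for sid, grp in dep.groupby("station_id"):
        g = grp.sort_values("start")
        if (g["start"].iloc[1:].to_numpy() < g["end"].iloc[:-1].to_numpy()).any():
            raise TelemetryIOError(f"overlapping deployment windows for station {sid}")


def read_tags(path, delimiter: str = ",") -> pd.DataFrame:
    tags = pd.read_csv(path, sep=delimiter)
    tags["tag_id"] = tags["tag_id"].astype(str)
    tags["tag_date"] = pd.to_datetime(tags["tag_date"]).dt.date
    if "sex" in tags.columns:
        bad = set(tags["sex"].dropna()) - {"F", "M", "ND"}
        if bad:
            raise TelemetryIOError(f"invalid sex code(s) {sorted(bad)}; expected F, M or ND")
    else:
        tags["sex"] = "ND"
    if "battery_days" not in tags.columns:
        tags["battery_days"] = 1350  # V16 nominal battery life
    return tags.reset_index(drop=True)


def filter_to_deployment_windows(
    det: pd.DataFrame, deployments: pd.DataFrame
) -> tuple[pd.DataFrame, int]:
    """Keep detections whose timestamp falls in a deployment window of their station.

    Windows are half-open ``[start, end)``: a detection at the exact end
    instant is dropped. Stations with no windows listed contribute no kept
    detections. Returns ``(kept, n_dropped)``.
    """
    validate_deployment_windows(deployments)
    keep = np.zeros(len(det), dtype=bool)
    ts = det["timestamp"].to_numpy()
    sid = det["station_id"].to_numpy()
    for station, grp in deployments.groupby("station_id"):
        mask = sid == station
        if not mask.any():
            continue
        t = ts[mask]
        ok = np.zeros(t.shape, dtype=bool)
        for start, end in zip(grp["start"].to_numpy(), grp["end"].to_numpy()):
            ok |= (t >= start) & (t < end)
        keep[mask] = ok
    kept = det.loc[keep].reset_index(drop=True)
    return kept, int((~keep).sum())
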