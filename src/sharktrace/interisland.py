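"""Inter-island transfers: travel times and straight-line speeds.

A transfer is a change of island in a tag's time-ordered detection
sequence: departure is the last detection at the origin island, arrival
the first detection at the destination. Travel time is therefore a lower
bound on the at-sea duration, and the straight-line speed
``distance / travel time`` a lower bound on realised speed. Inter-island
distances default to the published great-circle values for the Eastern
Tropical Pacific triangle (Cocos–Galapagos 710 km, Cocos–Malpelo 627 km);
a haversine fallback from station coordinates is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Default island-pair great-circle distances (km), symmetric lookup.
DEFAULT_DISTANCES_KM: dict[frozenset, float] = {
    frozenset({"Cocos", "Galapagos"}): 710.0,
    frozenset({"Cocos", "Malpelo"}): 627.0,
    frozenset({"Galapagos", "Malpelo"}): 1160.0,
}

TRANSFER_COLUMNS = [
    "tag_id",
    "from_island",
    "to_island",
    "departure",
    "arrival",
    "travel_days",
]


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance between two coordinates, km (R = 6371 km)."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlam = np.deg2rad(lon2 - lon1)
    a = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2) ** 2
    return float(2 * 6371.0 * np.arcsin(np.sqrt(a)))


def route_speed(distance_km: float, travel_days: float) -> float:
    """Straight-line speed in m/s from a distance (km) and travel time (days)."""
    if distance_km <= 0 or travel_days <= 0:
        raise ValueError("distance_km and travel_days must be positive")
    return distance_km * 1000.0 / (travel_days * 86400.0)


def detect_transfers(detections: pd.DataFrame, stations: pd.DataFrame) -> pd.DataFrame:
    """Scan each tag's island-labelled detections and emit one record per island change."""
    island_of = dict(
        zip(stations["station_id"].astype(str), stations["island_id"].astype(str))
    )
    unknown = sorted(set(detections["station_id"].astype(str)) - set(island_of))
    if unknown:
        raise ValueError(f"detections at stations with no island metadata: {unknown}")
    rows = []
    for tag, grp in detections.groupby("tag_id", sort=True):
        islands = grp["station_id"].astype(str).map(island_of).to_numpy()
        ts = grp["timestamp"].to_numpy()
        change = np.flatnonzero(islands[1:] != islands[:-1])
        for i in change:
            dep, arr = pd.Timestamp(ts[i]), pd.Timestamp(ts[i + 1])
            rows.append(
                (
                    str(tag),
                    islands[i],
                    islands[i + 1],
                    dep,
                    arr,
                    (arr - dep).total_seconds() / 86400.0,
                )
            )
    return pd.DataFrame(rows, columns=TRANSFER_COLUMNS)


def _route_distance(
    from_island: str,
    to_island: str,
    distances_km: dict[frozenset, float] | None,
    stations: pd.DataFrame | None,
) -> float:
    table = DEFAULT_DISTANCES_KM if distances_km is None else distances_km
    key = frozenset({from_island, to_island})
    if key in table:
        return table[key]
    if stations is not None:
        cent = stations.groupby("island_id")[["latitude", "longitude"]].mean()
        if from_island in cent.index and to_island in cent.index:
            a, b = cent.loc[from_island], cent.loc[to_island]
            return haversine_km(a["latitude"], a["longitude"], b["latitude"], b["longitude"])
    raise KeyError(f"no distance available for route {from_island} -> {to_island}")


def summarize_routes(
    transfers: pd.DataFrame,
    distances_km: dict[frozenset, float] | None = None,
    stations: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per ordered route: trip count, median/max/min travel days, max speed.

    The maximum straight-line speed corresponds to the minimum travel time;
    the median of an even trip count is the midpoint of the central pair.
    Speeds are rounded to 2 decimals in the summary.
    """
    rows = []
    for (fr, to), grp in transfers.groupby(["from_island", "to_island"], sort=True):
        days = grp["travel_days"].to_numpy(float)
        dist = _route_distance(fr, to, distances_km, stations)
        rows.append(
            (
                fr,
                to,
                len(days),
                float(np.median(days)),
                float(days.max()),
                float(days.min()),
                dist,
                round(route_speed(dist, float(days.min())), 2),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "from_island",
            "to_island",
            "n_trips",
            "median_travel_days",
            "max_travel_days",
            "min_travel_days",
            "distance_km",
            "max_speed_ms",
        ],
    )
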