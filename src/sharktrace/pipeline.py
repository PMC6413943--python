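"""End-to-end orchestration: io -> events -> residency -> models -> reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from sharktrace import diel as diel_mod
from sharktrace import events as events_mod
from sharktrace import interisland as inter_mod
from sharktrace import network as net_mod
from sharktrace import residency as res_mod
from sharktrace import site_model as model_mod
from sharktrace.io_telemetry import filter_to_deployment_windows, write_detections


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, pd.Timestamp):
        return o.isoformat()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_pipeline(
    detections: pd.DataFrame,
    stations: pd.DataFrame,
    tags: pd.DataFrame,
    out_dir,
    deployments: pd.DataFrame | None = None,
    focal_island: str = "Cocos",
    min_pings: int = events_mod.MIN_PINGS,
    timeout_s: float = events_mod.TIMEOUT_S,
    other_station_pings: int = events_mod.OTHER_STATION_PINGS,
    transit_min: float = events_mod.TRANSIT_MIN,
    absence_h: float = 24.0,
    response: str = "log-hours",
    include_transits: bool = True,
    min_monitoring_days: int = 120,
    utc_offset_hours: float = res_mod.DEFAULT_UTC_OFFSET_H,
    rao_reps: int = 1000,
    seed: int = 0,
    distances_km: dict | None = None,
) -> dict:
    """Run every analysis stage and write all artifacts under ``out_dir``.

    Returns a summary dictionary (also written as ``summary.json``):
    cohort residency (mean ± SD, overall and long-monitoring subset), the
    site mixed-model report and likelihood-ratio test, diel statistics,
    network node summaries and the inter-island route table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    if deployments is not None and len(deployments):
        detections, n_dropped = filter_to_deployment_windows(detections, deployments)
        summary["n_dropped_outside_deployment"] = n_dropped
    write_detections(detections, out / "detections_clean.csv")

    # --- events ---------------------------------------------------------
    events = events_mod.segment_all(detections, min_pings, timeout_s, other_station_pings)
    visits = events_mod.classify_visits(events, transit_min)
    _write_events(visits, out / "events.csv")
    summary["n_events"] = int(len(events))
    summary["n_transits"] = int(visits["is_transit"].sum()) if len(visits) else 0

    # --- residency ------------------------------------------------------
    summaries = res_mod.track_summaries(
        detections, tags, utc_offset_hours, stations=stations, island_id=focal_island
    )
    summaries.to_csv(out / "track_summaries.csv", index=False)
    matrix = res_mod.daily_presence_matrix(detections, tags, utc_offset_hours)
    matrix.to_csv(out / "presence_matrix.csv")
    summary["ri_all"] = res_mod.summarize_ri(summaries)
    summary["ri_long_monitoring"] = res_mod.summarize_ri(summaries, min_monitoring_days)
    summary["ri_duration_correlation"] = res_mod.ri_duration_correlation(summaries)

    corrected, rules = res_mod.correct_cohort(visits, tags, absence_h)
    _write_events(corrected, out / "corrected_visits.csv")
    rules.to_csv(out / "correction_rules.csv", index=False)
    summary["n_corrected_visits"] = int(len(corrected))

    # --- site model -----------------------------------------------------
    focal_station_ids = set(stations.loc[stations["island_id"] == focal_island, "station_id"])
    model_visits = corrected[corrected["station_id"].isin(focal_station_ids)]
    records = model_mod.visits_to_records(model_visits, response, include_transits)
    if records["site"].nunique() >= 2 and records["tag_id"].nunique() >= 2:
        fit = model_mod.fit_lmm(records, criterion="REML")
        fit.summary_frame().to_csv(out / "site_model_fixed_effects.csv")
        null_ml = model_mod.fit_lmm(records, criterion="ML", intercept_only=True)
        full_ml = model_mod.fit_lmm(records, criterion="ML")
        lrt = model_mod.lrt_site_effect(null_ml, full_ml)
        contrasts = model_mod.pairwise_site_contrasts(fit)
        contrasts.to_csv(out / "site_contrasts.csv", index=False)
        summary["site_model"] = {
            "sigma2_group": fit.sigma2_group,
            "sigma2_resid": fit.sigma2_resid,
            "sd_group": float(np.sqrt(fit.sigma2_group)),
            "sd_resid": float(np.sqrt(fit.sigma2_resid)),
            "reference": fit.reference,
            "beta": {k: float(v) for k, v in fit.beta.items()},
            "lrt": lrt,
        }
    else:
        summary["site_model"] = None

    # --- diel -----------------------------------------------------------
    focal_det = detections[detections["station_id"].isin(focal_station_ids)]
    if len(focal_det):
        series = diel_mod.hourly_counts(focal_det, utc_offset_hours, distinct_tags=True)
        if series.n_hours >= 48:
            period, spectrum = diel_mod.periodogram_peak(series)
            spectrum.to_csv(out / "spectrum.csv", index=False)
        else:
            period = None
        angles = diel_mod.detection_angles(focal_det, utc_offset_hours)
        circ = diel_mod.circular_stats(angles, rao_reps=rao_reps, seed=seed)
        summary["diel"] = {
            "dominant_period_h": period,
            "n": circ.n,
            "mean_hour": circ.mean_hour,
            "r": circ.r,
            "rayleigh_Z": circ.rayleigh_Z,
            "rayleigh_p": circ.rayleigh_p,
            "rao_U": circ.rao_U,
            "rao_p": circ.rao_p,
        }
    else:
        summary["diel"] = None

    # --- network --------------------------------------------------------
    focal_events = events[events["station_id"].isin(focal_station_ids)]
    network = net_mod.movement_matrix(focal_events)
    net_mod.export_network(network, out / "network_edges.csv", out / "network.graphml")
    summary["network"] = {
        "nodes": network.nodes,
        "degree": network.node_degree().to_dict(),
        "total_movements": network.total_movements(),
    }

    # --- inter-island ---------------------------------------------------
    if stations["island_id"].nunique() > 1:
        transfers = inter_mod.detect_transfers(detections, stations)
        transfers.to_csv(out / "transfers.csv", index=False)
        routes = inter_mod.summarize_routes(transfers, distances_km, stations) if len(transfers) else pd.DataFrame()
        routes.to_csv(out / "routes.csv", index=False)
        summary["n_transfers"] = int(len(transfers))
    else:
        summary["n_transfers"] = 0

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
    return summary


def _write_events(events: pd.DataFrame, path) -> None:
    out = events.copy()
    for col in ("start", "end"):
        if col in out.columns and len(out):
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)
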