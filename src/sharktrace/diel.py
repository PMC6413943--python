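"""Diel statistics: hourly binning, periodogram, and circular tests.

Detections are mapped to local time (UTC offset, default −6 h) and either
binned per hour for spectral analysis of the ~24 h presence rhythm, or
treated as angles on the 24-hour clock (15° per hour) for circular
statistics: the mean resultant length r, the Rayleigh test of uniformity
against a unimodal alternative (Z = n r²), and Rao's spacing test, which is
sensitive to multimodal departures, with a seeded Monte-Carlo p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from sharktrace.residency import DEFAULT_UTC_OFFSET_H


@dataclass
class HourlySeries:
    """Detection (or distinct-animal) counts per consecutive local hour."""

    start: pd.Timestamp          # first hour bin (local time)
    counts: np.ndarray           # one entry per hour, contiguous
    hour_of_day: np.ndarray      # 24-bin aggregate, index = local hour 0..23

    @property
    def n_hours(self) -> int:
        return len(self.counts)


def _local_times(detections: pd.DataFrame, utc_offset_hours: float) -> pd.Series:
    return detections["timestamp"] + pd.to_timedelta(utc_offset_hours, unit="h")


def hourly_counts(
    detections: pd.DataFrame,
    utc_offset_hours: float = DEFAULT_UTC_OFFSET_H,
    distinct_tags: bool = False,
) -> HourlySeries:
    """Counts per local-time hour over the contiguous span of the data.

    With ``distinct_tags=True`` each hour counts the number of different
    tagged animals detected (animals present per hour) rather than raw
    detections — the appropriate series for presence periodograms, since
    one resident animal can contribute thousands of pings.
    """
    if detections.empty:
        raise ValueError("no detections to bin")
    local = _local_times(detections, utc_offset_hours)
    hours = local.dt.floor("h")
    if distinct_tags:
        per_hour = detections.groupby(hours.to_numpy())["tag_id"].nunique()
    else:
        per_hour = pd.Series(1, index=hours.to_numpy()).groupby(level=0).sum()
    span = pd.date_range(per_hour.index.min(), per_hour.index.max(), freq="h")
    counts = per_hour.reindex(span, fill_value=0).to_numpy(float)
    hod = np.zeros(24)
    hod_series = per_hour.groupby(pd.DatetimeIndex(per_hour.index).hour).sum()
    hod[hod_series.index] = hod_series.to_numpy(float)
    return HourlySeries(start=span[0], counts=counts, hour_of_day=hod)


def periodogram_peak(series: HourlySeries | np.ndarray) -> tuple[float | None, pd.DataFrame]:
    """Dominant period (hours) of the mean-removed hourly series.

    Returns ``(period_hours, spectrum)`` where the spectrum holds
    frequencies (cycles/hour) and periodogram power; the dominant period is
    the reciprocal of the frequency with maximal power. A constant series
    has no peak and yields ``None``.
    """
    x = series.counts if isinstance(series, HourlySeries) else np.asarray(series, float)
    if len(x) < 48:
        raise ValueError("need at least 48 hourly bins to resolve a 24 h period")
    x = x - x.mean()
    freqs, power = signal.periodogram(x, fs=1.0, detrend=False)
    spectrum = pd.DataFrame({"frequency_per_hour": freqs[1:], "power": power[1:]})
    if not np.any(power[1:] > 0):
        return None, spectrum
    k = int(np.argmax(power[1:]))
    return float(1.0 / freqs[1 + k]), spectrum


def detection_angles(
    detections: pd.DataFrame, utc_offset_hours: float = DEFAULT_UTC_OFFSET_H
) -> np.ndarray:
    """Angle of each detection on the 24 h clock, degrees in [0, 360).

    Minute/second resolution is kept: angle = (hour + minute/60 + second/3600) x 15.
    """
    local = _local_times(detections, utc_offset_hours)
    frac_hours = (
        local.dt.hour + local.dt.minute / 60.0 + local.dt.second / 3600.0
    ).to_numpy(float)
    return frac_hours * 15.0


@dataclass
class CircularSummary:
    n: int
    mean_angle: float        # degrees in [0, 360); NaN when r = 0
    r: float                 # mean resultant length
    rayleigh_Z: float
    rayleigh_p: float
    rao_U: float             # degrees
    rao_p: float

    @property
    def mean_hour(self) -> float:
        """Mean angle converted back to local clock hours."""
        return self.mean_angle / 15.0


def rao_spacing_U(angles_deg: np.ndarray) -> float:
    """Rao's spacing statistic U = 1/2 sum |T_i − 360/n| over circular gaps."""
    a = np.sort(np.asarray(angles_deg, float) % 360.0)
    n = len(a)
    spacings = np.diff(a, append=a[0] + 360.0)
    return float(0.5 * np.abs(spacings - 360.0 / n).sum())


def _rayleigh_p(n: int, r: float) -> float:
    # standard large-n approximation with second-order correction
    Z = n * r * r
    arg = 1.0 + 4.0 * n + 4.0 * (n * n - n * Z)
    p = np.exp(np.sqrt(max(arg, 0.0)) - (1.0 + 2.0 * n))
    return float(min(max(p, 0.0), 1.0))


def circular_stats(
    angles_deg: np.ndarray,
    rao_reps: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> CircularSummary:
    """Circular summary of angles on the 24 h clock.

    ``rao_reps`` Monte-Carlo draws of circular-uniform samples of the same
    size calibrate Rao's spacing p-value: ``p = (1 + #{U_sim >= U_obs}) /
    (reps + 1)``. Pass a seed for reproducibility.
    """
    a = np.asarray(angles_deg, float) % 360.0
    n = len(a)
    if n == 0:
        raise ValueError("no angles supplied")
    rad = np.deg2rad(a)
    C, S = np.cos(rad).sum(), np.sin(rad).sum()
    R = float(np.hypot(C, S))
    r = R / n
    mean_angle = float(np.rad2deg(np.arctan2(S, C)) % 360.0) if r > 1e-12 else float("nan")
    Z = n * r * r
    U = rao_spacing_U(a)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = 0
    # chunk the null simulation to bound memory at large n
    chunk = max(1, min(rao_reps, int(2e7 // max(n, 1)) or 1))
    done = 0
    lam = 360.0 / n
    while done < rao_reps:
        m = min(chunk, rao_reps - done)
        sims = np.sort(rng.uniform(0.0, 360.0, size=(m, n)), axis=1)
        sp = np.diff(sims, axis=1)
        wrap = (sims[:, 0] + 360.0 - sims[:, -1])[:, None]
        u_sim = 0.5 * (
            np.abs(sp - lam).sum(axis=1) + np.abs(wrap - lam).ravel()
        )
        exceed += int((u_sim >= U - 1e-12).sum())
        done += m
    rao_p = (1 + exceed) / (rao_reps + 1)
    return CircularSummary(
        n=n,
        mean_angle=mean_angle,
        r=r,
        rayleigh_Z=float(Z),
        rayleigh_p=_rayleigh_p(n, r),
        rao_U=U,
        rao_p=float(rao_p),
    )
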