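"""Alarm-burden statistics.

Metrics mirror how alarm burden is reported in neonatal monitoring
studies: alarm densities (events per monitored hour, per neonate),
duration distributions and buckets (a 30 s bucket boundary is
inclusive: "30 seconds or less"), fractions of readings outside the
configured thresholds, and cohort summaries where the median/IQR are
taken over per-neonate values — never over pooled cells — so long
recordings do not dominate.

Conventions fixed here (documented assumptions):

* strict inequalities at thresholds: a reading equal to a limit is in
  range, matching a device that alarms on excursions *beyond* limits;
* IQR is reported as a single width (Q3 − Q1), quartiles by linear
  interpolation;
* hourly/daily maxima use windows aligned to each neonate's first
  sample (reproducible without wall-clock metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .event_segmentation import (
    AlarmEvent,
    MODALITY_AUDIBLE,
    MODALITY_AUDIO_VISUAL,
    MODALITY_VISUAL,
)
from .io_trace import CLINICAL_CATEGORIES, Trace


class UndefinedDensityError(ValueError):
    """Raised when a per-hour rate is requested over zero hours."""


def alarm_density(events, hours: float) -> float:
    """Alarm events per monitored hour."""
    if hours <= 0:
        raise UndefinedDensityError("monitored hours must be > 0")
    return len(list(events)) / hours


def _durations(events) -> np.ndarray:
    return np.array([e.duration_s for e in events], dtype=float)


def duration_bucket_percentages(events, edges) -> dict[str, float]:
    """Percentage of events per duration bucket.

    Buckets are left-open right-closed, ``(e_{i-1}, e_i]``, so the
    "30 s or less" bucket includes events of exactly 30 s; one final
    open bucket catches everything above the last edge.
    """
    edges = list(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    d = _durations(events)
    if d.size == 0:
        raise ValueError("no events: duration distribution undefined")
    bounds = [-np.inf] + edges + [np.inf]
    out = {}
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        frac = float(np.mean((d > lo) & (d <= hi)))
        label = f"<={hi:g}s" if np.isinf(lo) else (
            f">{lo:g}s" if np.isinf(hi) else f"{lo:g}-{hi:g}s"
        )
        out[label] = 100.0 * frac
    return out


def valid_values(trace: Trace, parameter: str) -> np.ndarray:
    """Non-null, quality-passing readings of ``parameter`` ("spo2"|"pr")."""
    if parameter not in ("spo2", "pr"):
        raise ValueError("parameter must be 'spo2' or 'pr'")
    v = trace.df[parameter].to_numpy(dtype=float)
    v = v[~trace.excluded]
    return v[~np.isnan(v)]


def pooled_values(traces, parameter: str) -> np.ndarray:
    """Valid readings pooled over a cohort of (filtered) traces."""
    parts = [valid_values(tr, parameter) for tr in traces]
    return np.concatenate(parts) if parts else np.array([], dtype=float)


def fraction_out_of_range(values, low=None, high=None) -> dict[str, float]:
    """Fractions strictly below ``low`` / strictly above ``high``.

    A ``None`` threshold (disabled limit) contributes fraction 0.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("no valid samples")
    below = float(np.mean(values < low)) if low is not None else 0.0
    above = float(np.mean(values > high)) if high is not None else 0.0
    return {"below": below, "above": above}


def out_of_range_fraction(trace: Trace, low, high, parameter: str) -> dict[str, float]:
    """Out-of-range fractions for one trace's valid readings."""
    return fraction_out_of_range(valid_values(trace, parameter), low, high)


def _median_iqr(x) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return float("nan"), float("nan")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return float(med), float(q3 - q1)


def max_window_count(events, window_s: float, origin_t: float = 0.0) -> int:
    """Largest number of events starting within any aligned window.

    Windows tile the timeline from ``origin_t`` (the neonate's first
    sample) in steps of ``window_s``; events are assigned by start time.
    """
    starts = np.array([e.start_t for e in events], dtype=float)
    if starts.size == 0:
        return 0
    win = np.floor((starts - origin_t) / window_s).astype(int)
    return int(np.bincount(win - win.min()).max())


def _has_modality(e: AlarmEvent, modality: str) -> bool:
    # an audio-visual event belongs to both the audible and the visual stream
    return e.modality == modality or e.modality == MODALITY_AUDIO_VISUAL


def per_neonate_summary(
    neonate_id: str, events, hours: float, origin_t: float = 0.0
) -> dict:
    """Burden statistics for one neonate.

    ``events`` are the neonate's segmented clinical alarm events;
    ``hours`` the quality-passing monitored hours (the density
    denominator).
    """
    events = list(events)
    clin = [e for e in events if e.category in CLINICAL_CATEGORIES]
    med, iqr = _median_iqr(_durations(clin))
    row = {
        "neonate_id": neonate_id,
        "hours": hours,
        "n_alarms": len(clin),
        "alarms_per_hour": len(clin) / hours if hours > 0 else np.nan,
        "median_duration_s": med,
        "iqr_duration_s": iqr,
        "max_hourly_count": max_window_count(clin, 3600.0, origin_t),
        "max_daily_count": max_window_count(clin, 86400.0, origin_t),
    }
    for cat in CLINICAL_CATEGORIES:
        sub = [e for e in clin if e.category == cat]
        row[f"n_{cat}"] = len(sub)
        row[f"{cat}_per_hour"] = len(sub) / hours if hours > 0 else np.nan
    for modality in (MODALITY_AUDIBLE, MODALITY_VISUAL):
        sub = [e for e in clin if _has_modality(e, modality)]
        row[f"n_{modality}"] = len(sub)
        row[f"{modality}_per_hour"] = len(sub) / hours if hours > 0 else np.nan
    return row


@dataclass
class BurdenSummary:
    """Per-neonate table plus cohort-level medians/IQRs and maxima."""

    per_neonate: pd.DataFrame
    cohort: dict = field(default_factory=dict)

    def to_text(self) -> str:
        c = self.cohort
        lines = [
            "Cohort alarm burden",
            f"  neonates                      : {c['n_neonates']}",
            f"  total clinical alarms         : {c['total_alarms']}",
            f"  alarms per neonate, median    : {c['n_alarms_median']:.0f} "
            f"(IQR, {c['n_alarms_iqr']:.0f})",
            f"  density/h, median             : {c['alarms_per_hour_median']:.1f} "
            f"(IQR, {c['alarms_per_hour_iqr']:.1f})",
            f"  visual density/h, median      : {c['visual_per_hour_median']:.1f} "
            f"(IQR, {c['visual_per_hour_iqr']:.1f})",
            f"  audible density/h, median     : {c['audible_per_hour_median']:.1f} "
            f"(IQR, {c['audible_per_hour_iqr']:.1f})",
            f"  max alarms in one hour        : {c['max_hourly_count']}",
            f"  max alarms in one day         : {c['max_daily_count']}",
        ]
        if "duration_buckets_pct" in c:
            lines.append("  event duration buckets (% of events):")
            for k, v in c["duration_buckets_pct"].items():
                lines.append(f"    {k:<10} : {v:.1f}%")
        return "\n".join(lines) + "\n"


def cohort_summary(per_neonate_rows, all_events=None,
                   bucket_edges=(30, 60, 300)) -> BurdenSummary:
    """Aggregate per-neonate summaries into a cohort summary.

    Medians/IQRs are computed over per-neonate values. ``all_events``
    (optional) supplies the pooled event list used for duration buckets.
    """
    rows = list(per_neonate_rows)
    if not rows:
        raise ValueError("cohort must contain at least one neonate")
    df = pd.DataFrame(rows)
    cohort: dict = {
        "n_neonates": len(df),
        "total_alarms": int(df["n_alarms"].sum()),
        "total_hours": float(df["hours"].sum()),
        "max_hourly_count": int(df["max_hourly_count"].max()),
        "max_daily_count": int(df["max_daily_count"].max()),
    }
    stat_cols = [
        "n_alarms",
        "alarms_per_hour",
        "median_duration_s",
        "audible_per_hour",
        "visual_per_hour",
    ] + [f"n_{c}" for c in CLINICAL_CATEGORIES] + [
        f"{c}_per_hour" for c in CLINICAL_CATEGORIES
    ]
    for col in stat_cols:
        med, iqr = _median_iqr(df[col].to_numpy(dtype=float))
        cohort[f"{col}_median"] = med
        cohort[f"{col}_iqr"] = iqr
    if all_events:
        clin = [e for e in all_events if e.category in CLINICAL_CATEGORIES]
        if clin:
            cohort["duration_buckets_pct"] = duration_bucket_percentages(
                clin, bucket_edges
            )
            med, iqr = _median_iqr(_durations(clin))
            cohort["pooled_duration_median_s"] = med
            cohort["pooled_duration_iqr_s"] = iqr
    return BurdenSummary(per_neonate=df, cohort=cohort)
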