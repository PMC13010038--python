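"""Re-implementation of the monitor's alarm generation.

The bedside oximeter does not alarm on raw readings: it averages the
signal (trailing boxcar, 8 s default), checks the averaged value
against the configured limits with strict inequalities, and annunciates
only once the violation has persisted for the alarm delay (15 s
default). A rapid-desaturation feature bypasses the delay when the
averaged SpO2 falls a configured number of points (10 by default)
*below* the low limit. Re-deriving alarm streams from raw SpO2/PR under
alternative settings enables threshold/delay what-if sweeps.

Timing semantics on the 2 s sampled grid: "continuously violating for
at least ``delay_s``" is measured in whole cells, so a 15 s delay
asserts at the 8th consecutive violating cell (16 s). The delay applies
to upper- and lower-limit alarms alike. The exact internal clocking of
the vendor device is unpublished; these are documented interpretations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .burden_metrics import fraction_out_of_range, _median_iqr
from .event_segmentation import (
    AlarmEvent,
    DEFAULT_SEGMENTATION,
    SegmentationConfig,
    events_from_mask,
)
from .io_trace import (
    CATEGORY_PR_HIGH,
    CATEGORY_PR_LOW,
    CATEGORY_SPO2_HIGH,
    CATEGORY_SPO2_LOW,
    Trace,
)


@dataclass(frozen=True)
class AlarmSettings:
    """Monitor configuration driving the simulator.

    Defaults are the device-default neonatal thresholds: SpO2 85–96%,
    PR 90–200 bpm, 8 s averaging, 15 s delay, 10-point rapid
    desaturation. ``spo2_high``/``pr_high`` may be None (alarm
    disabled). ``sensitivity`` and ``fast_sat`` are metadata with no
    computational effect (fast sat is off in the modelled
    configuration).
    """

    spo2_low: float = 85.0
    spo2_high: float | None = 96.0
    pr_low: float = 90.0
    pr_high: float | None = 200.0
    delay_s: float = 15.0
    averaging_s: float = 8.0
    rapid_desat_pct: float = 10.0
    sensitivity: str = "normal"
    fast_sat: bool = False

    def __post_init__(self):
        if self.spo2_high is not None and self.spo2_low >= self.spo2_high:
            raise ValueError("spo2_low must be < spo2_high")
        if self.pr_high is not None and self.pr_low >= self.pr_high:
            raise ValueError("pr_low must be < pr_high")
        if self.delay_s < 0:
            raise ValueError("delay_s must be >= 0")
        if self.averaging_s <= 0 or self.averaging_s % 2 != 0:
            raise ValueError("averaging_s must be a positive multiple of 2 s")
        if self.rapid_desat_pct < 0:
            raise ValueError("rapid_desat_pct must be >= 0")


DEFAULT_SETTINGS = AlarmSettings()


def moving_average(values, window_s: float, interval_s: int = 2) -> np.ndarray:
    """Trailing boxcar mean over ``window_s / interval_s`` samples.

    Null (NaN) samples are excluded from the window; a fully-null
    window yields NaN. Partial windows at the start of the series
    average the samples available so far, so there is no dead time.
    """
    if window_s <= 0 or window_s % interval_s != 0:
        raise ValueError("window_s must be a positive multiple of the interval")
    k = int(window_s // interval_s)
    v = np.asarray(values, dtype=float)
    if k == 1 or v.size == 0:
        return v.copy()
    finite = ~np.isnan(v)
    filled = np.where(finite, v, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(filled)))
    ccnt = np.concatenate(([0], np.cumsum(finite)))
    idx = np.arange(v.size) + 1
    lo = np.maximum(idx - k, 0)
    sums = csum[idx] - csum[lo]
    cnts = ccnt[idx] - ccnt[lo]
    with np.errstate(invalid="ignore"):
        out = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return out


def _delay_cells(delay_s: float, interval_s: int) -> int:
    """Cells of continuous violation needed before the alarm asserts."""
    return max(1, math.ceil(delay_s / interval_s))


def _alarm_from_violation(
    viol: np.ndarray,
    t: np.ndarray,
    delay_s: float,
    interval_s: int,
    bypass: np.ndarray | None = None,
) -> np.ndarray:
    """Apply delay semantics to a per-cell violation indicator.

    A run of consecutive violating cells (broken by non-violation, a
    null average, or a gap in the time grid) asserts at cell
    ``ceil(delay_s / 2)`` of the run; ``bypass`` cells (rapid
    desaturation) assert immediately. The alarm stays active until the
    violation clears.
    """
    n = viol.size
    out = np.zeros(n, dtype=bool)
    vi = np.flatnonzero(viol)
    if vi.size == 0:
        return out
    # run starts: non-consecutive index, or a time-grid discontinuity
    contiguous = np.empty(vi.size, dtype=bool)
    contiguous[0] = False
    if vi.size > 1:
        contiguous[1:] = (np.diff(vi) == 1) & (
            np.diff(t[vi]) == interval_s
        )
    run_start_pos = np.flatnonzero(~contiguous)
    run_len = np.diff(np.concatenate((run_start_pos, [vi.size])))
    pos_in_run = np.arange(vi.size) - np.repeat(run_start_pos, run_len)

    offset = _delay_cells(delay_s, interval_s) - 1
    start_rel = np.full(run_start_pos.size, offset, dtype=np.int64)
    if bypass is not None:
        byp = bypass[vi]
        cand = np.where(byp, pos_in_run, np.iinfo(np.int64).max)
        first_byp = np.minimum.reduceat(cand, run_start_pos)
        start_rel = np.minimum(start_rel, first_byp)

    active_len = run_len - start_rel
    sel = active_len > 0
    if not np.any(sel):
        return out
    starts = vi[run_start_pos[sel]] + start_rel[sel]
    lens = active_len[sel]
    # expand [start, start+len) ranges into flat indices
    flat = np.repeat(starts, lens) + (
        np.arange(lens.sum()) - np.repeat(np.cumsum(lens) - lens, lens)
    )
    out[flat] = True
    return out


def alarm_masks(trace: Trace, settings: AlarmSettings = DEFAULT_SETTINGS) -> dict:
    """Per-cell alarm-active masks for the four clinical streams."""
    interval = trace.sample_interval_s
    t = trace.t
    keep = ~trace.excluded
    spo2 = np.where(keep, trace.df["spo2"].to_numpy(dtype=float), np.nan)
    pr = np.where(keep, trace.df["pr"].to_numpy(dtype=float), np.nan)
    avg_spo2 = moving_average(spo2, settings.averaging_s, interval)
    avg_pr = moving_average(pr, settings.averaging_s, interval)

    def _viol(avg, threshold, direction):
        if threshold is None:
            return np.zeros(avg.size, dtype=bool)
        with np.errstate(invalid="ignore"):
            return (avg < threshold) if direction == "low" else (avg > threshold)

    rapid = None
    if settings.rapid_desat_pct > 0:
        with np.errstate(invalid="ignore"):
            rapid = avg_spo2 <= settings.spo2_low - settings.rapid_desat_pct

    masks = {
        CATEGORY_SPO2_LOW: _alarm_from_violation(
            _viol(avg_spo2, settings.spo2_low, "low"), t, settings.delay_s,
            interval, bypass=rapid,
        ),
        CATEGORY_SPO2_HIGH: _alarm_from_violation(
            _viol(avg_spo2, settings.spo2_high, "high"), t, settings.delay_s,
            interval,
        ),
        CATEGORY_PR_LOW: _alarm_from_violation(
            _viol(avg_pr, settings.pr_low, "low"), t, settings.delay_s, interval,
        ),
        CATEGORY_PR_HIGH: _alarm_from_violation(
            _viol(avg_pr, settings.pr_high, "high"), t, settings.delay_s, interval,
        ),
    }
    return masks


def simulate_alarm_stream(
    trace: Trace,
    settings: AlarmSettings = DEFAULT_SETTINGS,
    config: SegmentationConfig = DEFAULT_SEGMENTATION,
) -> list[AlarmEvent]:
    """Re-derive the alarm event stream from raw values under ``settings``.

    The per-cell alarm masks are segmented with the same grouping rule
    as recorded annotations, so simulated and recorded streams are
    directly comparable. Clinical alarms are announced on both
    channels, so events carry the audio_visual modality.
    """
    events: list[AlarmEvent] = []
    for cat, mask in alarm_masks(trace, settings).items():
        events.extend(
            events_from_mask(trace.t, mask, cat, trace.neonate_id, config)
        )
    events.sort(key=lambda e: (e.start_t, e.category))
    return events


@dataclass
class WhatIfResult:
    """Cohort-level outcome of one alarm-settings point."""

    settings: AlarmSettings
    n_alarms: dict = field(default_factory=dict)  # per category
    total_alarms: int = 0
    hours: float = 0.0
    alarms_per_hour: float = 0.0
    out_of_range: dict = field(default_factory=dict)
    duration_median_s: float = float("nan")
    duration_iqr_s: float = float("nan")


def what_if_sweep(
    traces,
    grid,
    config: SegmentationConfig = DEFAULT_SEGMENTATION,
) -> list[WhatIfResult]:
    """Evaluate a grid of alarm settings over a cohort of traces.

    Deterministic: one :class:`WhatIfResult` per settings point, event
    counts summed over traces, densities per quality-passing hour, and
    the out-of-range fractions of pooled valid readings at each
    threshold pair.
    """
    from .burden_metrics import pooled_values
    from .quality_filter import monitored_hours

    traces = list(traces)
    grid = list(grid)
    if not grid:
        raise ValueError("settings grid must be non-empty")
    hours = sum(monitored_hours(tr, include_excluded=False) for tr in traces)
    spo2 = pooled_values(traces, "spo2")
    pr = pooled_values(traces, "pr")

    results = []
    for settings in grid:
        res = WhatIfResult(settings=settings, hours=hours)
        durations: list[float] = []
        counts = {c: 0 for c in (
            CATEGORY_SPO2_LOW, CATEGORY_SPO2_HIGH, CATEGORY_PR_LOW, CATEGORY_PR_HIGH
        )}
        for tr in traces:
            for e in simulate_alarm_stream(tr, settings, config):
                counts[e.category] += 1
                durations.append(e.duration_s)
        res.n_alarms = counts
        res.total_alarms = sum(counts.values())
        res.alarms_per_hour = res.total_alarms / hours if hours > 0 else float("nan")
        res.duration_median_s, res.duration_iqr_s = _median_iqr(durations)
        res.out_of_range = {
            "spo2": fraction_out_of_range(spo2, settings.spo2_low, settings.spo2_high),
            "pr": fraction_out_of_range(pr, settings.pr_low, settings.pr_high),
        }
        results.append(res)
    return results


def expand_grid(base: AlarmSettings = DEFAULT_SETTINGS, **axes) -> list[AlarmSettings]:
    """Cross-product of settings axes, e.g. ``delay_s=[0, 10, 15]``."""
    points = [base]
    for name, values in axes.items():
        points = [replace(p, **{name: v}) for p in points for v in values]
    return points


def sweep_to_frame(results):
    """One tabular row per settings point."""
    import pandas as pd

    rows = []
    for r in results:
        s = r.settings
        row = {
            "spo2_low": s.spo2_low,
            "spo2_high": s.spo2_high,
            "pr_low": s.pr_low,
            "pr_high": s.pr_high,
            "delay_s": s.delay_s,
            "averaging_s": s.averaging_s,
            "rapid_desat_pct": s.rapid_desat_pct,
            "total_alarms": r.total_alarms,
            "alarms_per_hour": r.alarms_per_hour,
            "duration_median_s": r.duration_median_s,
            "duration_iqr_s": r.duration_iqr_s,
            "spo2_below_frac": r.out_of_range["spo2"]["below"],
            "spo2_above_frac": r.out_of_range["spo2"]["above"],
            "pr_below_frac": r.out_of_range["pr"]["below"],
            "pr_above_frac": r.out_of_range["pr"]["above"],
        }
        for cat, n in r.n_alarms.items():
            row[f"n_{cat}"] = n
        rows.append(row)
    return pd.DataFrame(rows)
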