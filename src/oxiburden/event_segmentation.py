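"""Grouping per-cell alarm annotations into discrete alarm events.

The monitor records alarm state every 2 seconds, so one clinical
episode appears as a run of annotated cells. An *alarm event* is a
maximal group of same-category alarm cells in which no silent gap
exceeds ``gap_s`` (default 30 s): a category change always starts a new
event, a silence of exactly ``gap_s`` still merges, and anything longer
splits. Event duration counts active cells only (2 s each); gap cells
do not add duration.

Each clinical category (spo2_low, spo2_high, pr_low, pr_high) is its
own stream, so SpO2 and PR alarms overlapping in time are distinct
simultaneous events. System alarms form a fifth stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_trace import (
    ALL_CATEGORIES,
    CLINICAL_CATEGORIES,
    CATEGORY_SYSTEM,
    SAMPLE_INTERVAL_S,
    Trace,
    label_flag_arrays,
)

EVENT_CATEGORIES = CLINICAL_CATEGORIES + (CATEGORY_SYSTEM,)

MODALITY_AUDIBLE = "audible"
MODALITY_VISUAL = "visual"
MODALITY_AUDIO_VISUAL = "audio_visual"


@dataclass(frozen=True)
class SegmentationConfig:
    """Grouping rule parameters.

    ``gap_s``: longest silent separation (seconds, boundary inclusive)
    still merged into one event. ``sample_interval_s`` is the 2 s cell
    width of the export.
    """

    gap_s: float = 30.0
    sample_interval_s: int = SAMPLE_INTERVAL_S

    def __post_init__(self):
        if self.gap_s < 0:
            raise ValueError("gap_s must be >= 0")
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be positive")


DEFAULT_SEGMENTATION = SegmentationConfig()


@dataclass(frozen=True)
class AlarmEvent:
    """One segmented alarm episode."""

    neonate_id: str
    category: str
    modality: str
    start_t: int
    end_t: int
    active_cell_count: int
    duration_s: int
    merged_across_gap: bool = False

    def __post_init__(self):
        if self.active_cell_count < 1:
            raise ValueError("event must contain at least one active cell")
        if self.duration_s != SAMPLE_INTERVAL_S * self.active_cell_count:
            raise ValueError("duration_s must equal 2 x active_cell_count")
        if self.start_t > self.end_t:
            raise ValueError("start_t must be <= end_t")


def classify_event(labels, modality_flags) -> tuple[str, str]:
    """Classify one contiguous run from its labels and modality flags.

    ``labels`` is a non-empty set of :class:`EventLabel`;
    ``modality_flags`` an iterable of per-cell ``(audible, visual)``
    booleans. Raises ValueError if the run mixes clinical categories —
    that is a segmentation bug upstream, never a data condition.
    """
    labels = set(labels)
    if not labels:
        raise ValueError("labels must be non-empty")
    clinical = {l.category for l in labels if l.category in CLINICAL_CATEGORIES}
    if len(clinical) > 1:
        raise ValueError(f"conflicting clinical categories in one run: {clinical}")
    if clinical:
        category = clinical.pop()
    else:
        category = CATEGORY_SYSTEM
    aud = any(a for a, _ in modality_flags)
    vis = any(v for _, v in modality_flags)
    if not (aud or vis):  # fall back to the label table
        aud = any("audible" in l.modality for l in labels)
        vis = any("visual" in l.modality for l in labels)
    return category, _modality_name(aud, vis)


def _modality_name(aud: bool, vis: bool) -> str:
    if aud and vis:
        return MODALITY_AUDIO_VISUAL
    if aud:
        return MODALITY_AUDIBLE
    return MODALITY_VISUAL


def events_from_mask(
    t: np.ndarray,
    mask: np.ndarray,
    category: str,
    neonate_id: str,
    config: SegmentationConfig = DEFAULT_SEGMENTATION,
    audible: np.ndarray | None = None,
    visual: np.ndarray | None = None,
) -> list[AlarmEvent]:
    """Segment a boolean per-cell alarm mask into events.

    Two active cells belong to the same event when the silence between
    them (time between cell starts minus one cell width) is at most
    ``gap_s``; i.e. a split requires *strictly more* than ``gap_s`` of
    silence.
    """
    idx = np.flatnonzero(np.asarray(mask, dtype=bool))
    if idx.size == 0:
        return []
    interval = config.sample_interval_s
    times = np.asarray(t)[idx]
    dt = np.diff(times)
    split = dt > config.gap_s + interval
    starts = np.concatenate(([0], np.flatnonzero(split) + 1))
    ends = np.concatenate((np.flatnonzero(split), [len(idx) - 1]))

    if audible is not None:
        aud_cells = np.asarray(audible, dtype=bool)[idx]
    if visual is not None:
        vis_cells = np.asarray(visual, dtype=bool)[idx]

    events = []
    for s, e in zip(starts, ends):
        count = int(e - s + 1)
        merged = bool(np.any(dt[s:e] > interval)) if e > s else False
        if audible is not None or visual is not None:
            aud = bool(aud_cells[s : e + 1].any()) if audible is not None else False
            vis = bool(vis_cells[s : e + 1].any()) if visual is not None else False
            if not (aud or vis):
                aud = vis = True  # unannotated modality: device default is both
            modality = _modality_name(aud, vis)
        else:
            modality = MODALITY_AUDIO_VISUAL
        events.append(
            AlarmEvent(
                neonate_id=neonate_id,
                category=category,
                modality=modality,
                start_t=int(times[s]),
                end_t=int(times[e]) + interval,
                active_cell_count=count,
                duration_s=count * interval,
                merged_across_gap=merged,
            )
        )
    return events


def segment_events(
    trace: Trace,
    config: SegmentationConfig = DEFAULT_SEGMENTATION,
    mapping=None,
    categories=EVENT_CATEGORIES,
) -> list[AlarmEvent]:
    """Segment a (quality-filtered) trace's annotations into events.

    Cells flagged as excluded by the quality filter never contribute;
    events are returned sorted by start time, then category.
    """
    if len(trace) == 0:
        return []
    events_col = trace.df["events"].to_numpy(dtype=object)
    flags = label_flag_arrays(events_col, mapping)
    keep = ~trace.excluded
    t = trace.t
    out: list[AlarmEvent] = []
    for cat in categories:
        d = flags[cat]
        out.extend(
            events_from_mask(
                t,
                d["flag"] & keep,
                cat,
                trace.neonate_id,
                config,
                audible=d["audible"],
                visual=d["visual"],
            )
        )
    out.sort(key=lambda e: (e.start_t, e.category))
    return out


def events_to_frame(events) -> pd.DataFrame:
    """One row per event, stable column order, seconds as integers."""
    cols = [
        "neonate_id",
        "category",
        "modality",
        "start_t",
        "end_t",
        "active_cell_count",
        "duration_s",
        "merged_across_gap",
    ]
    rows = [[getattr(e, c) for c in cols] for e in events]
    return pd.DataFrame(rows, columns=cols)
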