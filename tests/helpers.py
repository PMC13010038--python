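"""Shared test utilities: trace builders and the independent
brute-force segmentation oracle."""

from __future__ import annotations

import numpy as np
import pandas as pd

from oxiburden import Trace
from oxiburden.io_trace import CLINICAL_CATEGORIES

TOKEN = {
    "spo2_low": "SpO2 Low Alarm",
    "spo2_high": "SpO2 High Alarm",
    "pr_low": "PR Low Alarm",
    "pr_high": "PR High Alarm",
    "system": "Sensor Off",
}


def build_trace(
    spo2,
    pr=None,
    events=None,
    siq_low=None,
    t=None,
    pi=None,
    neonate_id="T1",
) -> Trace:
    """Assemble a Trace from plain lists (None -> NaN values)."""
    n = len(spo2)
    spo2 = np.array([np.nan if v is None else float(v) for v in spo2])
    pr = (
        np.full(n, 150.0)
        if pr is None
        else np.array([np.nan if v is None else float(v) for v in pr])
    )
    pi = np.full(n, 1.5) if pi is None else np.asarray(pi, dtype=float)
    t = np.arange(n) * 2 if t is None else np.asarray(t)
    events = np.array(["" if e is None else e for e in (events or [""] * n)], dtype=object)
    siq_low = np.zeros(n, dtype=bool) if siq_low is None else np.asarray(siq_low, bool)
    # keep the null<->token bijection that Trace.validate checks
    for vals, token in ((spo2, "Invalid functional SpO2"), (pr, "Invalid PR")):
        for i in np.flatnonzero(np.isnan(vals)):
            toks = [x for x in events[i].split(";") if x]
            if token not in toks:
                events[i] = ";".join(toks + [token])
    df = pd.DataFrame(
        {"t": t, "spo2": spo2, "pr": pr, "pi": pi, "siq_low": siq_low, "events": events}
    )
    return Trace(neonate_id=neonate_id, device_id="D1", df=df)


def trace_from_flags(t, flags_by_cat, neonate_id="T1") -> Trace:
    """Trace whose events column carries the given per-cell category flags."""
    n = len(t)
    events = []
    for i in range(n):
        toks = [TOKEN[c] for c, m in flags_by_cat.items() if m[i]]
        events.append(";".join(toks))
    return build_trace([95] * n, events=events, t=t, neonate_id=neonate_id)


def brute_force_segment(t, flags_by_cat, gap_s=30.0, interval=2):
    """Independent run-merging oracle.

    Scans each category's flagged cells in time order and starts a new
    event exactly when the silent separation (time since the previous
    flagged cell's end) strictly exceeds ``gap_s``. Returns tuples
    (category, start_t, end_t, active_cells, merged_across_gap) sorted
    like segment_events output.
    """
    out = []
    for cat, mask in flags_by_cat.items():
        cur = None
        for ti, on in zip(t, mask):
            if not on:
                continue
            if cur is not None and (ti - (cur["last"] + interval)) > gap_s:
                out.append(cur)
                cur = None
            if cur is None:
                cur = {"cat": cat, "start": ti, "last": ti, "n": 1, "merged": False}
            else:
                if ti - cur["last"] > interval:
                    cur["merged"] = True
                cur["last"] = ti
                cur["n"] += 1
        if cur is not None:
            out.append(cur)
    tuples = [
        (c["cat"], int(c["start"]), int(c["last"]) + interval, c["n"], c["merged"])
        for c in out
    ]
    tuples.sort(key=lambda x: (x[1], x[0]))
    return tuples


def event_tuples(events):
    return [
        (e.category, e.start_t, e.end_t, e.active_cell_count, e.merged_across_gap)
        for e in events
    ]


def random_flag_trace(rng, max_cells=200, categories=CLINICAL_CATEGORIES):
    """Random short trace with sparse bursty flags and grid gaps."""
    n = int(rng.integers(1, max_cells + 1))
    # time grid with occasional gaps of up to 40 s
    steps = np.where(rng.random(n) < 0.1, rng.integers(2, 21, n), 1) * 2
    t = np.cumsum(steps) - steps[0]
    flags = {}
    for cat in categories:
        base = rng.random(n) < 0.25
        # make runs bursty so merges actually occur
        for _ in range(2):
            base |= np.roll(base, 1) & (rng.random(n) < 0.7)
        flags[cat] = base
    return t, flags
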