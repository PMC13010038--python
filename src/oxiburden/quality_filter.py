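"""Data-integrity exclusions and quality accounting.

Monitoring exports contain stretches that cannot support burden
analysis: sensor detachment, low perfusion, cable disconnects, and
invalid-measurement rows. This module applies the exclusion rules and
produces a :class:`QualityReport` quantifying what was removed.

Rules applied by :func:`apply_quality_rules`:

* rows carrying a system event or an invalid SpO2/PR sentinel are
  marked *excluded* (union of rules, counted once); their values are
  nulled so nothing downstream can consume artifact readings;
* clinical alarm annotations on low-SIQ cells are removed from the
  alarm stream (the sample values stay, when themselves valid — low
  signal quality discredits the *alarm entry*, not the cell);
* clinical alarm annotations inside excluded segments are removed and
  counted (they are artifact alarms, not patient alarms).

Per-hour burden metrics downstream use quality-passing hours as the
denominator; the report carries both totals so the alternative reading
can always be recovered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .io_trace import (
    CLINICAL_CATEGORIES,
    CATEGORY_SYSTEM,
    DEFAULT_LABEL_MAPPING,
    INVALID_PR_TOKEN,
    INVALID_SPO2_TOKEN,
    Trace,
    label_flag_arrays,
    parse_event_labels,
)


@dataclass
class QualityReport:
    """Summary of the exclusions applied to one trace (or a cohort)."""

    total_duration_h: float = 0.0
    excluded_duration_h: float = 0.0
    excluded_fraction: float = 0.0
    n_invalid_spo2: int = 0
    n_invalid_pr: int = 0
    n_low_siq_alarm_entries_removed: int = 0
    n_alarm_entries_in_excluded: int = 0
    system_event_breakdown: dict = field(default_factory=dict)
    spo2_null_fraction_in_excluded: float = 0.0
    pr_null_fraction_in_excluded: float = 0.0

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    def to_text(self) -> str:
        lines = [
            "Quality report",
            f"  total monitored            : {self.total_duration_h:.2f} h",
            f"  excluded (poor quality)    : {self.excluded_duration_h:.2f} h "
            f"({100 * self.excluded_fraction:.2f}%)",
            f"  invalid SpO2 cells         : {self.n_invalid_spo2}",
            f"  invalid PR cells           : {self.n_invalid_pr}",
            f"  low-SIQ alarm entries cut  : {self.n_low_siq_alarm_entries_removed}",
            f"  alarm entries in excluded  : {self.n_alarm_entries_in_excluded}",
            f"  SpO2 null in excluded      : {100 * self.spo2_null_fraction_in_excluded:.1f}%",
            f"  PR null in excluded        : {100 * self.pr_null_fraction_in_excluded:.1f}%",
            "  system events:",
        ]
        for k in sorted(self.system_event_breakdown):
            lines.append(f"    {k:<24} : {self.system_event_breakdown[k]}")
        return "\n".join(lines) + "\n"


def _strip_tokens(events: np.ndarray, where: np.ndarray, tokens: set,
                  delimiter: str = ";") -> tuple[np.ndarray, int]:
    """Remove ``tokens`` from event strings at ``where``; count removals."""
    events = events.copy()
    n_removed = 0
    idx = np.flatnonzero(where)
    # cache per unique string: (new_string, n_tokens_removed)
    cache: dict[str, tuple[str, int]] = {}
    for i in idx:
        s = events[i]
        if s == "":
            continue
        if s not in cache:
            parts = s.split(delimiter)
            kept = [p for p in parts if p not in tokens]
            cache[s] = (delimiter.join(kept), len(parts) - len(kept))
        events[i], k = cache[s]
        n_removed += k
    return events, n_removed


def apply_quality_rules(trace: Trace, mapping=None) -> tuple[Trace, QualityReport]:
    """Apply the exclusion rules; return (filtered trace, report).

    Idempotent: running twice equals running once. The filtered trace
    keeps every row (so the time axis is untouched) and gains an
    ``excluded`` boolean column; excluded rows have null SpO2/PR.
    """
    mapping = DEFAULT_LABEL_MAPPING if mapping is None else mapping
    df = trace.df.copy()
    n = len(df)
    interval = trace.sample_interval_s
    report = QualityReport()
    report.total_duration_h = n * interval / 3600.0
    if n == 0:
        out = trace.copy()
        out.df["excluded"] = np.zeros(0, dtype=bool)
        return out, report

    events = df["events"].to_numpy(dtype=object)
    flags = label_flag_arrays(events, mapping)
    invalid_spo2 = df["spo2"].isna().to_numpy()
    invalid_pr = df["pr"].isna().to_numpy()
    system = flags[CATEGORY_SYSTEM]["flag"]

    excluded = invalid_spo2 | invalid_pr | system
    report.n_invalid_spo2 = int(invalid_spo2.sum())
    report.n_invalid_pr = int(invalid_pr.sum())
    report.excluded_duration_h = float(excluded.sum()) * interval / 3600.0
    report.excluded_fraction = float(excluded.mean())
    n_excl = int(excluded.sum())
    if n_excl:
        report.spo2_null_fraction_in_excluded = float(
            invalid_spo2[excluded].mean()
        )
        report.pr_null_fraction_in_excluded = float(invalid_pr[excluded].mean())

    # system-event census (per raw token, counted in cells)
    breakdown: dict[str, int] = {}
    uniq, inv = np.unique(events, return_inverse=True)
    counts = np.bincount(inv)
    for i, u in enumerate(uniq):
        for lab in parse_event_labels(u, mapping):
            if lab.category == CATEGORY_SYSTEM:
                breakdown[lab.raw] = breakdown.get(lab.raw, 0) + int(counts[i])
    report.system_event_breakdown = breakdown

    clinical_tokens = {
        raw for raw, lab in mapping.items() if lab.category in CLINICAL_CATEGORIES
    }
    siq_low = df["siq_low"].to_numpy()
    events, n_siq = _strip_tokens(events, siq_low & ~excluded, clinical_tokens)
    report.n_low_siq_alarm_entries_removed = n_siq
    events, n_art = _strip_tokens(events, excluded, clinical_tokens)
    report.n_alarm_entries_in_excluded = n_art

    # Null values in excluded rows; keep the null↔token bijection intact.
    spo2 = df["spo2"].to_numpy(dtype=float).copy()
    pr = df["pr"].to_numpy(dtype=float).copy()
    spo2[excluded] = np.nan
    pr[excluded] = np.nan
    for colvals, token in ((spo2, INVALID_SPO2_TOKEN), (pr, INVALID_PR_TOKEN)):
        need = np.isnan(colvals)
        uniq2, inv2 = np.unique(events, return_inverse=True)
        has = np.array([token in u.split(";") for u in uniq2], dtype=bool)[inv2]
        idx = np.flatnonzero(need & ~has)
        events[idx] = np.where(events[idx] == "", token, events[idx] + ";" + token)

    df["spo2"] = spo2
    df["pr"] = pr
    df["events"] = events
    df["excluded"] = excluded
    out = Trace(
        neonate_id=trace.neonate_id,
        device_id=trace.device_id,
        df=df,
        sample_interval_s=trace.sample_interval_s,
    )
    return out, report


def monitored_hours(trace: Trace, include_excluded: bool = True) -> float:
    """Monitored time in hours: 2 s per counted cell.

    With ``include_excluded=False`` only quality-passing cells count
    (the denominator used for per-hour burden metrics).
    """
    n = len(trace)
    if n == 0:
        return 0.0
    if not include_excluded:
        n = int((~trace.excluded).sum())
    return n * trace.sample_interval_s / 3600.0


def combine_reports(reports) -> QualityReport:
    """Pool per-trace reports into one cohort-level report."""
    out = QualityReport()
    tot_excl_cells_spo2 = 0.0
    tot_excl_cells_pr = 0.0
    tot_excl = 0.0
    for r in reports:
        out.total_duration_h += r.total_duration_h
        out.excluded_duration_h += r.excluded_duration_h
        out.n_invalid_spo2 += r.n_invalid_spo2
        out.n_invalid_pr += r.n_invalid_pr
        out.n_low_siq_alarm_entries_removed += r.n_low_siq_alarm_entries_removed
        out.n_alarm_entries_in_excluded += r.n_alarm_entries_in_excluded
        for k, v in r.system_event_breakdown.items():
            out.system_event_breakdown[k] = out.system_event_breakdown.get(k, 0) + v
        tot_excl += r.excluded_duration_h
        tot_excl_cells_spo2 += r.spo2_null_fraction_in_excluded * r.excluded_duration_h
        tot_excl_cells_pr += r.pr_null_fraction_in_excluded * r.excluded_duration_h
    if out.total_duration_h > 0:
        out.excluded_fraction = out.excluded_duration_h / out.total_duration_h
    if tot_excl > 0:
        out.spo2_null_fraction_in_excluded = tot_excl_cells_spo2 / tot_excl
        out.pr_null_fraction_in_excluded = tot_excl_cells_pr / tot_excl
    return out
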