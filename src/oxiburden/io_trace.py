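"""Reading and writing 0.5 Hz pulse-oximeter trace CSVs.

A trace is the per-neonate time series exported by a bedside pulse
oximeter: one row every 2 seconds carrying SpO2 (%), pulse rate (bpm),
perfusion index (%), a signal-quality flag (SIQ), and a free-text event
column listing the alarm/system annotations active in that cell.

Vendors do not publish a common export schema, so this module defines a
documented dialect (see :class:`TraceDialect`) plus a column-mapping
config so real exports can be adapted without touching downstream code.
Invalid-measurement rows are represented *in the file* by sentinel
tokens in the event column ("Invalid functional SpO2", "Invalid PR")
with an empty value cell; in memory they become NaN with the token
retained as a label, so write(read(f)) round-trips losslessly.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SAMPLE_INTERVAL_S = 2

# Alarm categories. SpO2 and PR each alarm in two directions; everything
# raised by the device itself (sensor off, low perfusion, disconnects,
# invalid-measurement sentinels) is "system"; unrecognised tokens are
# "other" and are never dropped silently.
CATEGORY_SPO2_LOW = "spo2_low"
CATEGORY_SPO2_HIGH = "spo2_high"
CATEGORY_PR_LOW = "pr_low"
CATEGORY_PR_HIGH = "pr_high"
CATEGORY_SYSTEM = "system"
CATEGORY_OTHER = "other"

CLINICAL_CATEGORIES = (
    CATEGORY_SPO2_LOW,
    CATEGORY_SPO2_HIGH,
    CATEGORY_PR_LOW,
    CATEGORY_PR_HIGH,
)
ALL_CATEGORIES = CLINICAL_CATEGORIES + (CATEGORY_SYSTEM, CATEGORY_OTHER)

INVALID_SPO2_TOKEN = "Invalid functional SpO2"
INVALID_PR_TOKEN = "Invalid PR"


class TraceFormatError(ValueError):
    """Raised when a trace file violates the dialect contract."""


class DialectConfigError(ValueError):
    """Raised when the column mapping does not match the file."""


@dataclass(frozen=True)
class EventLabel:
    """One parsed event annotation.

    ``category`` is the alarm stream the token belongs to; ``modality``
    is the subset of {"audible", "visual"} channels the device uses to
    announce it; ``raw`` is the original token so nothing is lost.
    """

    raw: str
    category: str
    modality: frozenset = frozenset()

    def __post_init__(self):
        if self.category not in ALL_CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


def _label(raw: str, category: str, *modality: str) -> EventLabel:
    return EventLabel(raw=raw, category=category, modality=frozenset(modality))


#: Shipped token table. The six clinical alarm columns of the source
#: export are modelled as the four threshold streams plus system and
#: other; the mapping is a documented assumption, not a vendor schema.
DEFAULT_LABEL_MAPPING: dict[str, EventLabel] = {
    lab.raw: lab
    for lab in [
        _label("SpO2 Low Alarm", CATEGORY_SPO2_LOW, "audible", "visual"),
        _label("SpO2 High Alarm", CATEGORY_SPO2_HIGH, "audible", "visual"),
        _label("PR Low Alarm", CATEGORY_PR_LOW, "audible", "visual"),
        _label("PR High Alarm", CATEGORY_PR_HIGH, "audible", "visual"),
        _label("Sensor Off", CATEGORY_SYSTEM, "audible", "visual"),
        _label("Low Perfusion Index", CATEGORY_SYSTEM, "visual"),
        _label("Cable Disconnect", CATEGORY_SYSTEM, "visual"),
        _label("Low SIQ", CATEGORY_SYSTEM, "visual"),
        _label(INVALID_SPO2_TOKEN, CATEGORY_SYSTEM),
        _label(INVALID_PR_TOKEN, CATEGORY_SYSTEM),
    ]
}


@dataclass(frozen=True)
class TraceDialect:
    """Column mapping and token conventions for trace CSV files.

    ``timestamp_format`` is ``"seconds"`` (numeric seconds; normalised
    to seconds-from-start on read) or ``"iso8601"``. The events column
    holds ``event_delimiter``-separated tokens; the empty string means
    no annotation.
    """

    timestamp: str = "t"
    spo2: str = "spo2"
    pr: str = "pr"
    pi: str = "pi"
    siq: str = "siq"
    events: str = "events"
    timestamp_format: str = "seconds"
    event_delimiter: str = ";"
    siq_low_value: str = "low"
    siq_ok_value: str = "ok"
    invalid_spo2_token: str = INVALID_SPO2_TOKEN
    invalid_pr_token: str = INVALID_PR_TOKEN

    @property
    def required_columns(self) -> tuple[str, ...]:
        return (self.timestamp, self.spo2, self.pr, self.pi, self.siq, self.events)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "TraceDialect":
        """Build a dialect from a flat key→value config (e.g. YAML)."""
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise DialectConfigError(f"unknown dialect keys: {sorted(unknown)}")
        return cls(**dict(mapping))


DEFAULT_DIALECT = TraceDialect()


class SampleRecord(NamedTuple):
    """One 2-second cell of a trace (row view, mainly for small data)."""

    t: int
    spo2: float  # NaN when invalid/missing
    pr: float
    pi: float
    siq: str  # "ok" | "low"
    labels: frozenset  # of raw token strings


@dataclass
class Trace:
    """A per-neonate 0.5 Hz monitoring record.

    ``df`` columns: ``t`` (int seconds from trace start, strictly
    increasing on a 2 s grid with gaps allowed), ``spo2``/``pr``/``pi``
    (float, NaN = null), ``siq_low`` (bool) and ``events`` (string of
    delimiter-joined raw tokens, "" when none). After quality filtering
    an ``excluded`` bool column is added.
    """

    neonate_id: str
    device_id: str
    df: pd.DataFrame
    sample_interval_s: int = SAMPLE_INTERVAL_S

    def __len__(self) -> int:
        return len(self.df)

    @property
    def t(self) -> np.ndarray:
        return self.df["t"].to_numpy()

    @property
    def excluded(self) -> np.ndarray:
        """Quality-exclusion mask (all False before filtering)."""
        if "excluded" in self.df.columns:
            return self.df["excluded"].to_numpy()
        return np.zeros(len(self.df), dtype=bool)

    def records(self, delimiter: str = ";") -> Iterator[SampleRecord]:
        for row in self.df.itertuples(index=False):
            tokens = frozenset(tok for tok in row.events.split(delimiter) if tok)
            yield SampleRecord(
                t=int(row.t),
                spo2=float(row.spo2),
                pr=float(row.pr),
                pi=float(row.pi),
                siq="low" if row.siq_low else "ok",
                labels=tokens,
            )

    def copy(self) -> "Trace":
        return replace(self, df=self.df.copy())

    def equals(self, other: "Trace") -> bool:
        if (self.neonate_id, self.device_id) != (other.neonate_id, other.device_id):
            return False
        return self.df.reset_index(drop=True).equals(other.df.reset_index(drop=True))

    def validate(self) -> None:
        """Check the Trace invariants, raising TraceFormatError."""
        if len(self.df) == 0:
            raise TraceFormatError("trace is empty")
        t = self.t
        dt = np.diff(t)
        if np.any(dt <= 0):
            k = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise TraceFormatError(f"timestamps not strictly increasing at row {k}")
        if np.any(dt % self.sample_interval_s != 0):
            k = int(np.flatnonzero(dt % self.sample_interval_s != 0)[0]) + 1
            raise TraceFormatError(
                f"timestamp spacing not a multiple of {self.sample_interval_s} s at row {k}"
            )
        for col, token in (("spo2", INVALID_SPO2_TOKEN), ("pr", INVALID_PR_TOKEN)):
            has_token = _events_contain(self.df["events"].to_numpy(), token)
            isnan = self.df[col].isna().to_numpy()
            if np.any(has_token & ~isnan):
                raise TraceFormatError(f"{col} value present despite {token!r} token")
            if np.any(isnan & ~has_token):
                raise TraceFormatError(f"null {col} without {token!r} token")


def parse_event_labels(
    raw: str,
    mapping: Mapping[str, EventLabel] | None = None,
    delimiter: str = ";",
) -> frozenset:
    """Parse a delimited event string into a set of :class:`EventLabel`.

    Idempotent and order-independent: duplicated tokens collapse by set
    semantics. Unknown tokens map to category ``other`` (with a logged
    warning) rather than being dropped.
    """
    mapping = DEFAULT_LABEL_MAPPING if mapping is None else mapping
    out = set()
    for tok in raw.split(delimiter):
        tok = tok.strip()
        if not tok:
            continue
        lab = mapping.get(tok)
        if lab is None:
            logger.warning("unknown event token %r mapped to category 'other'", tok)
            lab = EventLabel(raw=tok, category=CATEGORY_OTHER)
        out.add(lab)
    return frozenset(out)


def _events_contain(events: np.ndarray, token: str, delimiter: str = ";") -> np.ndarray:
    """Boolean mask of cells whose event string contains ``token``.

    Unique-string caching keeps this fast on multi-million-cell traces,
    where the number of distinct annotation combinations is small.
    """
    uniq, inv = np.unique(events, return_inverse=True)
    hit = np.array([token in u.split(delimiter) for u in uniq], dtype=bool)
    return hit[inv]


def label_flag_arrays(
    events: np.ndarray,
    mapping: Mapping[str, EventLabel] | None = None,
    delimiter: str = ";",
) -> dict[str, dict[str, np.ndarray]]:
    """Per-cell boolean flags for every category.

    Returns ``{category: {"flag": cell-has-category, "audible": ...,
    "visual": ...}}`` where the modality masks mark cells carrying a
    token of that category announced on that channel.
    """
    mapping = DEFAULT_LABEL_MAPPING if mapping is None else mapping
    uniq, inv = np.unique(events, return_inverse=True)
    per_cat = {
        cat: {
            "flag": np.zeros(len(uniq), dtype=bool),
            "audible": np.zeros(len(uniq), dtype=bool),
            "visual": np.zeros(len(uniq), dtype=bool),
        }
        for cat in ALL_CATEGORIES
    }
    for i, u in enumerate(uniq):
        for lab in parse_event_labels(u, mapping, delimiter):
            d = per_cat[lab.category]
            d["flag"][i] = True
            if "audible" in lab.modality:
                d["audible"][i] = True
            if "visual" in lab.modality:
                d["visual"][i] = True
    return {
        cat: {k: v[inv] for k, v in d.items()} for cat, d in per_cat.items()
    }


def _parse_timestamps(raw: pd.Series, dialect: TraceDialect) -> np.ndarray:
    if dialect.timestamp_format == "iso8601":
        ts = pd.to_datetime(raw, utc=True, errors="coerce")
        if ts.isna().any():
            k = int(np.flatnonzero(ts.isna().to_numpy())[0]) + 1
            raise TraceFormatError(f"unparsable timestamp at row {k}")
        sec = ts.astype("int64").to_numpy() // 10**9
    elif dialect.timestamp_format == "seconds":
        num = pd.to_numeric(raw, errors="coerce")
        if num.isna().any():
            k = int(np.flatnonzero(num.isna().to_numpy())[0]) + 1
            raise TraceFormatError(f"unparsable timestamp at row {k}")
        sec = num.to_numpy()
        if np.any(sec != np.round(sec)):
            k = int(np.flatnonzero(sec != np.round(sec))[0]) + 1
            raise TraceFormatError(f"non-integer timestamp at row {k}")
        sec = sec.astype(np.int64)
    else:
        raise DialectConfigError(
            f"unknown timestamp_format {dialect.timestamp_format!r}"
        )
    return (sec - sec[0]).astype(np.int64)


def read_trace_csv(
    path,
    dialect: TraceDialect | None = None,
    neonate_id: str | None = None,
    device_id: str | None = None,
) -> Trace:
    """Read a trace CSV in the documented dialect.

    Invalid-entry tokens become NaN values with the token retained as a
    label; a NaN value without its token (plain missing cell) gains the
    token on read so the null↔token bijection holds in memory and the
    file round-trips.
    """
    dialect = dialect or DEFAULT_DIALECT
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in dialect.required_columns if c not in raw.columns]
    if missing:
        raise DialectConfigError(
            f"{path.name}: missing required column(s) {missing}; "
            f"present: {list(raw.columns)}"
        )
    if len(raw) == 0:
        raise TraceFormatError(f"{path.name}: no data rows")

    t = _parse_timestamps(raw[dialect.timestamp], dialect)
    events = raw[dialect.events].to_numpy(dtype=object)

    def _numeric(col: str, name: str) -> np.ndarray:
        s = raw[col].replace("", np.nan)
        num = pd.to_numeric(s, errors="coerce")
        bad = num.isna() & (s.notna())
        if bad.any():
            k = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise TraceFormatError(f"{path.name}: unparsable {name} at row {k}")
        return num.to_numpy(dtype=float)

    spo2 = _numeric(dialect.spo2, "spo2")
    pr = _numeric(dialect.pr, "pr")
    pi = _numeric(dialect.pi, "pi")

    siq_raw = raw[dialect.siq].to_numpy(dtype=object)
    known = {dialect.siq_low_value, dialect.siq_ok_value}
    bad = ~np.isin(siq_raw, list(known))
    if bad.any():
        k = int(np.flatnonzero(bad)[0]) + 1
        raise TraceFormatError(f"{path.name}: unknown SIQ value at row {k}")
    siq_low = siq_raw == dialect.siq_low_value

    # Enforce the null↔token bijection in both directions.
    for col_vals, token in (
        (spo2, dialect.invalid_spo2_token),
        (pr, dialect.invalid_pr_token),
    ):
        has_token = _events_contain(events, token, dialect.event_delimiter)
        col_vals[has_token] = np.nan
        need_token = np.isnan(col_vals) & ~has_token
        if need_token.any():
            idx = np.flatnonzero(need_token)
            events[idx] = np.where(
                events[idx] == "",
                token,
                events[idx] + dialect.event_delimiter + token,
            )

    df = pd.DataFrame(
        {
            "t": t,
            "spo2": spo2,
            "pr": pr,
            "pi": pi,
            "siq_low": siq_low,
            "events": events,
        }
    )
    trace = Trace(
        neonate_id=neonate_id or path.stem,
        device_id=device_id or path.stem,
        df=df,
    )
    trace.validate()
    return trace


def write_trace_csv(trace: Trace, path, dialect: TraceDialect | None = None):
    """Write a trace in the documented dialect (bit-deterministic).

    Null values are rendered as an empty value cell plus the invalid
    token in the events column, the inverse of the read rule.
    """
    dialect = dialect or DEFAULT_DIALECT
    path = Path(path)
    df = trace.df

    def _fmt(col: str) -> list[str]:
        vals = df[col].to_numpy()
        out = []
        for v in vals:
            if np.isnan(v):
                out.append("")
            elif float(v).is_integer():
                out.append(str(int(v)))
            else:
                out.append(f"{v:.2f}")
        return out

    events = df["events"].to_numpy(dtype=object).copy()
    # Guarantee the invalid tokens are present wherever the value is null,
    # even if the caller assembled the frame by hand.
    for col, token in (("spo2", dialect.invalid_spo2_token), ("pr", dialect.invalid_pr_token)):
        has_token = _events_contain(events, token, dialect.event_delimiter)
        need = df[col].isna().to_numpy() & ~has_token
        idx = np.flatnonzero(need)
        events[idx] = np.where(
            events[idx] == "", token, events[idx] + dialect.event_delimiter + token
        )

    out = pd.DataFrame(
        {
            dialect.timestamp: df["t"].astype(int),
            dialect.spo2: _fmt("spo2"),
            dialect.pr: _fmt("pr"),
            dialect.pi: _fmt("pi"),
            dialect.siq: np.where(
                df["siq_low"].to_numpy(), dialect.siq_low_value, dialect.siq_ok_value
            ),
            dialect.events: events,
        }
    )
    buf = io.StringIO()
    out.to_csv(buf, index=False, lineterminator="\n")
    path.write_text(buf.getvalue())
    return path
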