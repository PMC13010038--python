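"""Synthetic neonatal SpO2/PR trace generator with planted ground truth.

Stands in for raw bedside-monitor exports, which are rarely shareable.
The generator emulates the signal features that drive alarm burden in a
preterm cohort on supplemental oxygen:

* an integer-valued SpO2 process that alternates between an in-range
  band (85–96%) and long hyperoxic stretches at 97–100% (point masses
  concentrated at the top of the scale), interrupted by desaturation
  episodes — many brief shallow dips plus rarer deep, prolonged ones;
* a mean-reverting pulse-rate baseline confined to 90–200 bpm with
  bradycardia/tachycardia episode overlays, bradycardia weakly coupled
  to deep desaturations;
* artifact segments (sensor off, low perfusion, cable disconnect) that
  produce invalid entries, junk readings and low SIQ;
* device alarm annotations computed by running the monitor alarm logic
  (averaging, delay, rapid desaturation) over the generated values, so
  annotations are self-consistent with the simulator by construction.

The default spec is calibrated so the cohort's pooled marginal
statistics (SpO2 median and tail masses, PR mean/SD and out-of-range
fractions, simulated alarm mix and durations) land on the summary
values typical of a heavily monitored neonatal unit. The calibrated
quantities are emergent from episode/baseline dynamics, not set
directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .alarm_logic import AlarmSettings, DEFAULT_SETTINGS, alarm_masks
from .event_segmentation import (
    DEFAULT_SEGMENTATION,
    SegmentationConfig,
    events_from_mask,
)
from .io_trace import (
    CATEGORY_PR_HIGH,
    CATEGORY_PR_LOW,
    CATEGORY_SPO2_HIGH,
    CATEGORY_SPO2_LOW,
    INVALID_PR_TOKEN,
    INVALID_SPO2_TOKEN,
    SAMPLE_INTERVAL_S,
    Trace,
)

CELLS_PER_DAY = 86400 // SAMPLE_INTERVAL_S

ALARM_TOKEN = {
    CATEGORY_SPO2_LOW: "SpO2 Low Alarm",
    CATEGORY_SPO2_HIGH: "SpO2 High Alarm",
    CATEGORY_PR_LOW: "PR Low Alarm",
    CATEGORY_PR_HIGH: "PR High Alarm",
}
ARTIFACT_TOKEN = {
    "sensor_off": "Sensor Off",
    "low_pi": "Low Perfusion Index",
    "cable": "Cable Disconnect",
}


class SpecValidationError(ValueError):
    """Raised when a cohort spec is internally inconsistent."""


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of the synthetic cohort.

    Dwell times are in 2 s cells; rates are dimensionless probabilities
    per renewal step. The dataclass defaults are the calibrated,
    desk-scale study conditions (49 neonates, a few simulated days
    each); :func:`default_calibration` returns them, optionally at the
    full multi-week monitoring durations.
    """

    n_neonates: int = 49
    seed: int = 20211001

    # per-neonate monitoring duration (days, lognormal, clipped)
    duration_median_d: float = 2.0
    duration_log_sigma: float = 0.895
    duration_min_d: float = 0.35
    duration_max_d: float = 6.0

    # SpO2 in-range band (85..96): sticky value chain + dwell between excursions
    spo2_mid_values: tuple = tuple(range(85, 97))
    spo2_mid_weights: tuple = (0.5, 0.5, 0.7, 0.8, 1.0, 1.2, 1.5, 2.0, 3.0, 5.0, 7.0, 9.5)
    spo2_mid_stay: float = 0.85
    spo2_mid_dwell_mean: float = 42.0

    # hyperoxic stretches (97..100)
    spo2_high_values: tuple = (97, 98, 99, 100)
    spo2_high_weights: tuple = (0.22, 0.22, 0.20, 0.36)
    spo2_high_stay: float = 0.85
    p_excursion_low: float = 0.7955  # excursion from the band is a desat (else hyperoxic)
    high_dwell_long_prob: float = 0.15
    high_dwell_short_median: float = 9.0
    high_dwell_short_sigma: float = 0.5
    high_dwell_long_median: float = 950.0
    high_dwell_long_sigma: float = 0.7

    # desaturation episodes
    desat_deep_prob: float = 0.21
    desat_deep_depth: tuple = (62, 78)
    desat_deep_dwell_median: float = 7.8
    desat_deep_dwell_sigma: float = 0.45
    desat_deep_long_prob: float = 0.25
    desat_deep_long_median: float = 28.0
    desat_deep_long_sigma: float = 0.8
    desat_shallow_depth: tuple = (81, 84)
    desat_shallow_dwell_mean: float = 4.35
    desat_shallow_dwell_cap: int = 8

    # pulse-rate baseline (AR(1), clipped to the in-range band)
    pr_base_mean: float = 158.13
    pr_base_sd: float = 17.5
    pr_base_phi: float = 0.98
    pr_clip: tuple = (90, 200)

    # pulse-rate episodes
    pr_gap_mean: float = 380.0
    pr_brady_prob: float = 0.306
    brady_level: tuple = (68, 88)
    tachy_level: tuple = (202, 222)
    pr_dwell_short_prob: float = 0.6
    pr_dwell_short_mean: float = 3.5
    pr_dwell_long_median: float = 8.5
    pr_dwell_long_sigma: float = 0.6
    brady_coupling_prob: float = 0.15

    # artifact model
    artifact_gap_mean: float = 447.0
    artifact_dwell_median: float = 30.0
    artifact_dwell_sigma: float = 1.0
    artifact_type_probs: tuple = (0.5, 0.3, 0.2)  # sensor_off, low_pi, cable
    artifact_spo2_null_frac: float = 0.748
    artifact_pr_null_frac: float = 0.736
    stray_null_rate: float = 2e-4
    stray_low_siq_rate: float = 1e-3

    # per-neonate heterogeneity (lognormal sigmas on episode odds/dwells)
    het_desat_sigma: float = 0.15
    het_high_sigma: float = 0.12
    het_brady_sigma: float = 0.10
    het_tachy_sigma: float = 0.10
    het_pr_shift_sd: float = 3.0

    # settings used to write device alarm annotations into the traces
    annotation_settings: AlarmSettings = DEFAULT_SETTINGS

    def validate(self) -> None:
        if self.n_neonates < 1:
            raise SpecValidationError("n_neonates must be >= 1")
        if not (0 < self.duration_min_d <= self.duration_median_d <= self.duration_max_d):
            raise SpecValidationError("duration clip must bracket the median")
        for name in (
            "spo2_mid_dwell_mean", "high_dwell_short_median", "high_dwell_long_median",
            "desat_deep_dwell_median", "desat_shallow_dwell_mean", "pr_gap_mean",
            "artifact_gap_mean", "artifact_dwell_median",
        ):
            if getattr(self, name) <= 0:
                raise SpecValidationError(f"{name} must be > 0")
        for name in (
            "p_excursion_low", "desat_deep_prob", "pr_brady_prob",
            "high_dwell_long_prob", "pr_dwell_short_prob", "brady_coupling_prob",
            "artifact_spo2_null_frac", "artifact_pr_null_frac",
        ):
            if not 0 <= getattr(self, name) <= 1:
                raise SpecValidationError(f"{name} must be in [0, 1]")
        if len(self.spo2_mid_weights) != len(self.spo2_mid_values):
            raise SpecValidationError("spo2_mid_weights length mismatch")
        if len(self.spo2_high_weights) != len(self.spo2_high_values):
            raise SpecValidationError("spo2_high_weights length mismatch")
        if not (self.desat_deep_depth[0] <= self.desat_deep_depth[1] < 85):
            raise SpecValidationError("deep desat depths must stay below 85")
        if not (self.desat_shallow_depth[0] <= self.desat_shallow_depth[1] < 85):
            raise SpecValidationError("shallow desat depths must stay below 85")
        n_cells_min = int(self.duration_min_d * CELLS_PER_DAY)
        art_mean = self.artifact_dwell_median * float(
            np.exp(self.artifact_dwell_sigma**2 / 2)
        )
        if art_mean >= n_cells_min:
            raise SpecValidationError(
                "mean artifact segment longer than the shortest monitoring time"
            )

    def to_json(self, path=None) -> str:
        d = asdict(self)
        d["annotation_settings"] = asdict(self.annotation_settings)
        s = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def default_calibration(full_scale: bool = False) -> SyntheticCohortSpec:
    """The shipped, calibrated cohort spec.

    The desk-scale default monitors each neonate for a few days;
    ``full_scale=True`` restores the multi-week duration model (median
    11.2 days, 16 hours to 41 days) with the same signal dynamics.
    """
    spec = SyntheticCohortSpec()
    if full_scale:
        spec = replace(
            spec,
            duration_median_d=11.2,
            duration_min_d=16 / 24,
            duration_max_d=41.0,
        )
    return spec


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass(frozen=True)
class PlantedEvent:
    kind: str  # desat | hyper | brady | tachy
    onset_t: int
    duration_s: int
    level: int  # depth (desat/brady) or plateau level (hyper/tachy); -1 = varies


@dataclass(frozen=True)
class ArtifactSegment:
    kind: str  # sensor_off | low_pi | cable
    onset_t: int
    duration_s: int


@dataclass
class NeonateTruth:
    neonate_id: str
    planted: list = field(default_factory=list)
    artifacts: list = field(default_factory=list)
    alarm_events: list = field(default_factory=list)  # under annotation settings


@dataclass
class GroundTruth:
    per_neonate: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        d = {
            nid: {
                "planted": [asdict(p) for p in t.planted],
                "artifacts": [asdict(a) for a in t.artifacts],
                "alarm_events": [asdict(e) for e in t.alarm_events],
            }
            for nid, t in self.per_neonate.items()
        }
        s = json.dumps(d, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


# ---------------------------------------------------------------------------
# generation internals


def _sticky_values(rng, n, values, probs, stay) -> np.ndarray:
    """Sticky resampling chain: keep the value w.p. ``stay``, else
    redraw from the stationary distribution (which it therefore has)."""
    if n == 0:
        return np.empty(0, dtype=np.int64)
    new = rng.random(n) >= stay
    new[0] = True
    seg = np.cumsum(new) - 1
    draws = rng.choice(np.asarray(values), size=int(new.sum()), p=np.asarray(probs))
    return draws[seg].astype(np.int64)


def _lognormal_cells(rng, median, sigma, size) -> np.ndarray:
    d = rng.lognormal(mean=np.log(median), sigma=sigma, size=size)
    return np.maximum(1, np.round(d)).astype(np.int64)


def _geometric_cells(rng, mean, size) -> np.ndarray:
    return rng.geometric(1.0 / max(mean, 1.0), size=size).astype(np.int64)


def _odds_scale(p, m) -> float:
    """Scale the odds of probability ``p`` by multiplier ``m``."""
    return float(p * m / (p * m + (1 - p)))


def _gen_spo2(rng, n, spec, p_low_eff, m_high):
    """In-range band / hyperoxia / desaturation regime process.

    Returns (integer SpO2 array, regime code array, planted episodes)
    with codes 0=band, 1=hyper, 2=desat.
    """
    segs_state, segs_len, segs_depth = [], [], []
    total = 0
    while total < n:
        B = 1024
        mid = _geometric_cells(rng, spec.spo2_mid_dwell_mean, B)
        is_low = rng.random(B) < p_low_eff
        long_high = rng.random(B) < spec.high_dwell_long_prob
        high_dwell = np.where(
            long_high,
            _lognormal_cells(
                rng, spec.high_dwell_long_median * m_high,
                spec.high_dwell_long_sigma, B,
            ),
            _lognormal_cells(
                rng, spec.high_dwell_short_median, spec.high_dwell_short_sigma, B
            ),
        )
        deep = rng.random(B) < spec.desat_deep_prob
        # deep desat dwells are a short/long mixture (many brief events,
        # rare prolonged ones); shallow dips are capped below the
        # alarm-delay horizon, adding sub-alarm tail mass without events
        deep_long = rng.random(B) < spec.desat_deep_long_prob
        deep_dwell = np.where(
            deep_long,
            _lognormal_cells(
                rng, spec.desat_deep_long_median, spec.desat_deep_long_sigma, B
            ),
            _lognormal_cells(
                rng, spec.desat_deep_dwell_median, spec.desat_deep_dwell_sigma, B
            ),
        )
        low_dwell = np.where(
            deep,
            deep_dwell,
            np.minimum(
                _geometric_cells(rng, spec.desat_shallow_dwell_mean, B),
                spec.desat_shallow_dwell_cap,
            ),
        )
        depth = np.where(
            deep,
            rng.integers(spec.desat_deep_depth[0], spec.desat_deep_depth[1] + 1, B),
            rng.integers(
                spec.desat_shallow_depth[0], spec.desat_shallow_depth[1] + 1, B
            ),
        )
        for i in range(B):
            segs_state.append(0)
            segs_len.append(int(mid[i]))
            segs_depth.append(-1)
            if is_low[i]:
                segs_state.append(2)
                segs_len.append(int(low_dwell[i]))
                segs_depth.append(int(depth[i]))
            else:
                segs_state.append(1)
                segs_len.append(int(high_dwell[i]))
                segs_depth.append(-1)
            total += int(mid[i]) + int(low_dwell[i] if is_low[i] else high_dwell[i])
            if total >= n:
                break

    lens = np.array(segs_len, dtype=np.int64)
    states = np.array(segs_state, dtype=np.int64)
    depths = np.array(segs_depth, dtype=np.int64)
    ends = np.cumsum(lens)
    keep = ends - lens < n  # segment starts inside the trace
    lens, states, depths = lens[keep], states[keep], depths[keep]
    ends = np.cumsum(lens)
    lens[-1] -= ends[-1] - n  # truncate the final segment
    starts = np.cumsum(lens) - lens

    code = np.repeat(states, lens)
    spo2 = np.empty(n, dtype=np.int64)
    mid_mask = code == 0
    spo2[mid_mask] = _sticky_values(
        rng, int(mid_mask.sum()), spec.spo2_mid_values,
        np.asarray(spec.spo2_mid_weights) / np.sum(spec.spo2_mid_weights),
        spec.spo2_mid_stay,
    )
    high_mask = code == 1
    spo2[high_mask] = _sticky_values(
        rng, int(high_mask.sum()), spec.spo2_high_values,
        np.asarray(spec.spo2_high_weights) / np.sum(spec.spo2_high_weights),
        spec.spo2_high_stay,
    )
    low_mask = code == 2
    n_low = int(low_mask.sum())
    depth_cells = np.repeat(depths, lens)[low_mask]
    jitter = rng.integers(-1, 2, n_low)
    spo2[low_mask] = np.clip(depth_cells + jitter, 40, 84)

    planted = []
    for s, ln, st, dp in zip(starts, lens, states, depths):
        if st == 0 or ln <= 0:
            continue
        planted.append(
            PlantedEvent(
                kind="desat" if st == 2 else "hyper",
                onset_t=int(s) * SAMPLE_INTERVAL_S,
                duration_s=int(ln) * SAMPLE_INTERVAL_S,
                level=int(dp),
            )
        )
    return spo2, code, planted


def _episode_renewal(rng, n, gap_mean, kind_probs, dwell_fn, level_fn):
    """Generic gap/episode renewal overlay; returns episode tuples."""
    episodes = []
    pos = 0
    kinds = list(kind_probs)
    probs = np.array([kind_probs[k] for k in kinds])
    while pos < n:
        pos += int(rng.exponential(gap_mean)) + 1
        if pos >= n:
            break
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        dwell = int(dwell_fn(rng, kind))
        dwell = min(dwell, n - pos)
        if dwell >= 1:
            episodes.append((kind, pos, dwell, int(level_fn(rng, kind))))
        pos += dwell
    return episodes


def _gen_pr(rng, n, spec, p_brady_eff, p_tachy_odds_m, pr_shift, coupled_bradys):
    """Pulse-rate baseline plus bradycardia/tachycardia overlays."""
    burn = 256
    eps = rng.standard_normal(n + burn)
    sigma_e = spec.pr_base_sd * np.sqrt(1 - spec.pr_base_phi**2)
    dev = lfilter([1.0], [1.0, -spec.pr_base_phi], eps * sigma_e)[burn:]
    base = np.round(spec.pr_base_mean + pr_shift + dev)
    pr = np.clip(base, spec.pr_clip[0], spec.pr_clip[1]).astype(np.int64)

    def dwell_fn(rng, kind):
        if rng.random() < spec.pr_dwell_short_prob:
            return _geometric_cells(rng, spec.pr_dwell_short_mean, 1)[0]
        return _lognormal_cells(
            rng, spec.pr_dwell_long_median, spec.pr_dwell_long_sigma, 1
        )[0]

    def level_fn(rng, kind):
        lo, hi = spec.brady_level if kind == "brady" else spec.tachy_level
        return rng.integers(lo, hi + 1)

    # per-neonate odds multipliers reweight the brady/tachy episode mix
    p = spec.pr_brady_prob
    q = p * p_brady_eff / (p * p_brady_eff + (1 - p) * p_tachy_odds_m)
    kind_probs = {"brady": q, "tachy": 1 - q}

    episodes = _episode_renewal(
        rng, n, spec.pr_gap_mean, kind_probs, dwell_fn, level_fn
    )
    episodes.extend(coupled_bradys)
    episodes.sort(key=lambda e: e[1])

    planted = []
    for kind, pos, dwell, level in episodes:
        jit = rng.integers(-2, 3, dwell)
        vals = level + jit
        if kind == "brady":
            vals = np.clip(vals, 40, spec.pr_clip[0] - 1)
        else:
            vals = np.clip(vals, spec.pr_clip[1] + 1, 245)
        pr[pos : pos + dwell] = vals
        planted.append(
            PlantedEvent(
                kind=kind,
                onset_t=pos * SAMPLE_INTERVAL_S,
                duration_s=dwell * SAMPLE_INTERVAL_S,
                level=int(level),
            )
        )
    return pr, planted


def _gen_artifacts(rng, n, spec):
    """Artifact segments: (kind, start_cell, dwell_cells)."""
    if spec.artifact_gap_mean <= 0 or spec.artifact_dwell_median <= 0:
        return []
    kinds = ("sensor_off", "low_pi", "cable")
    probs = np.asarray(spec.artifact_type_probs, dtype=float)
    probs = probs / probs.sum()
    out = []
    pos = 0
    while pos < n:
        pos += int(rng.exponential(spec.artifact_gap_mean)) + 1
        if pos >= n:
            break
        dwell = int(
            _lognormal_cells(rng, spec.artifact_dwell_median,
                             spec.artifact_dwell_sigma, 1)[0]
        )
        dwell = min(dwell, n - pos)
        if dwell >= 1:
            kind = kinds[int(rng.choice(3, p=probs))]
            out.append((kind, pos, dwell))
        pos += dwell
    return out


def _append_token(events: np.ndarray, mask: np.ndarray, token: str) -> None:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    cur = events[idx]
    events[idx] = np.where(cur == "", token, cur + ";" + token)


def generate_trace(
    spec: SyntheticCohortSpec,
    rng: np.random.Generator,
    neonate_id: str,
    config: SegmentationConfig = DEFAULT_SEGMENTATION,
) -> tuple[Trace, NeonateTruth]:
    """Generate one neonate's trace plus its ground truth."""
    days = float(
        np.clip(
            rng.lognormal(np.log(spec.duration_median_d), spec.duration_log_sigma),
            spec.duration_min_d,
            spec.duration_max_d,
        )
    )
    n = max(64, int(round(days * CELLS_PER_DAY)))

    # neonate-level heterogeneity (unit-mean lognormal odds multipliers)
    def _mult(sigma):
        return float(rng.lognormal(-sigma**2 / 2, sigma)) if sigma > 0 else 1.0

    m_desat = _mult(spec.het_desat_sigma)
    m_high = _mult(spec.het_high_sigma)
    m_brady = _mult(spec.het_brady_sigma)
    m_tachy = _mult(spec.het_tachy_sigma)
    pr_shift = rng.normal(0.0, spec.het_pr_shift_sd) if spec.het_pr_shift_sd else 0.0

    p_low_eff = _odds_scale(spec.p_excursion_low, m_desat)
    spo2, code, planted_spo2 = _gen_spo2(rng, n, spec, p_low_eff, m_high)

    # bradycardic response coupled to deep desaturations
    coupled = []
    if spec.brady_coupling_prob > 0:
        for ev in planted_spo2:
            if ev.kind == "desat" and ev.level >= 0 and ev.level <= 78:
                if rng.random() < spec.brady_coupling_prob:
                    pos = ev.onset_t // SAMPLE_INTERVAL_S
                    dwell = min(ev.duration_s // SAMPLE_INTERVAL_S, n - pos)
                    if dwell >= 1:
                        coupled.append(
                            ("brady", pos, dwell, int(rng.integers(70, 89)))
                        )
    pr, planted_pr = _gen_pr(rng, n, spec, m_brady, m_tachy, pr_shift, coupled)

    pi = np.round(np.exp(rng.normal(np.log(1.5), 0.45, n)), 2)
    siq_low = rng.random(n) < spec.stray_low_siq_rate

    spo2_f = spo2.astype(float)
    pr_f = pr.astype(float)

    artifacts = _gen_artifacts(rng, n, spec)
    art_mask = np.zeros(n, dtype=bool)
    events = np.full(n, "", dtype=object)
    for kind, pos, dwell in artifacts:
        sl = slice(pos, pos + dwell)
        art_mask[sl] = True
        null_spo2 = rng.random(dwell) < spec.artifact_spo2_null_frac
        null_pr = rng.random(dwell) < spec.artifact_pr_null_frac
        junk_spo2 = rng.integers(40, 100, dwell).astype(float)
        junk_pr = rng.integers(60, 221, dwell).astype(float)
        spo2_f[sl] = np.where(null_spo2, np.nan, junk_spo2)
        pr_f[sl] = np.where(null_pr, np.nan, junk_pr)
        if kind == "low_pi":
            pi[sl] = np.round(np.exp(rng.normal(np.log(0.15), 0.3, dwell)), 2)
        m = np.zeros(n, dtype=bool)
        m[sl] = True
        _append_token(events, m, ARTIFACT_TOKEN[kind])
    siq_low |= art_mask

    stray = (rng.random(n) < spec.stray_null_rate) & ~art_mask
    spo2_f[stray] = np.nan
    pr_f[stray] = np.nan

    t = np.arange(n, dtype=np.int64) * SAMPLE_INTERVAL_S
    df = pd.DataFrame(
        {"t": t, "spo2": spo2_f, "pr": pr_f, "pi": pi,
         "siq_low": siq_low, "events": events}
    )
    trace = Trace(neonate_id=neonate_id, device_id=f"dev-{neonate_id}", df=df)

    # device alarm annotations: run the monitor logic over the raw trace
    masks = alarm_masks(trace, spec.annotation_settings)
    alarm_events = []
    for cat in (CATEGORY_SPO2_LOW, CATEGORY_SPO2_HIGH, CATEGORY_PR_LOW, CATEGORY_PR_HIGH):
        _append_token(events, masks[cat], ALARM_TOKEN[cat])
        alarm_events.extend(
            events_from_mask(t, masks[cat], cat, neonate_id, config)
        )
    alarm_events.sort(key=lambda e: (e.start_t, e.category))

    _append_token(events, np.isnan(spo2_f), INVALID_SPO2_TOKEN)
    _append_token(events, np.isnan(pr_f), INVALID_PR_TOKEN)
    df["events"] = events

    truth = NeonateTruth(
        neonate_id=neonate_id,
        planted=sorted(planted_spo2 + planted_pr, key=lambda e: e.onset_t),
        artifacts=[
            ArtifactSegment(
                kind=k,
                onset_t=pos * SAMPLE_INTERVAL_S,
                duration_s=dwell * SAMPLE_INTERVAL_S,
            )
            for k, pos, dwell in artifacts
        ],
        alarm_events=alarm_events,
    )
    trace.validate()
    return trace, truth


def generate_cohort(
    spec: SyntheticCohortSpec,
    config: SegmentationConfig = DEFAULT_SEGMENTATION,
) -> tuple[list[Trace], GroundTruth]:
    """Generate the full cohort deterministically from ``spec.seed``."""
    spec.validate()
    seeds = np.random.SeedSequence(spec.seed).spawn(spec.n_neonates)
    traces = []
    truth = GroundTruth()
    for i, ss in enumerate(seeds):
        nid = f"N{i + 1:03d}"
        rng = np.random.Generator(np.random.PCG64(ss))
        tr, tt = generate_trace(spec, rng, nid, config)
        traces.append(tr)
        truth.per_neonate[nid] = tt
    return traces, truth
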