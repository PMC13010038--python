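import numpy as np
import pytest

from oxiburden import (
    alarm_density,
    cohort_summary,
    duration_bucket_percentages,
    fraction_out_of_range,
    out_of_range_fraction,
    per_neonate_summary,
)
from oxiburden.burden_metrics import UndefinedDensityError, max_window_count
from oxiburden.event_segmentation import AlarmEvent

from helpers import build_trace


def ev(duration_s, start_t=0, category="spo2_low", modality="audio_visual"):
    return AlarmEvent(
        neonate_id="T1",
        category=category,
        modality=modality,
        start_t=start_t,
        end_t=start_t + duration_s,
        active_cell_count=duration_s // 2,
        duration_s=duration_s,
    )


class TestAlarmDensity:
    def test_simple_ratio(self):
        assert alarm_density([ev(10)] * 8, 2.0) == pytest.approx(4.0)

    def test_zero_events(self):
        assert alarm_density([], 5.0) == 0.0

    def test_zero_hours_raises(self):
        with pytest.raises(UndefinedDensityError):
            alarm_density([ev(10)], 0.0)


class TestDurationBuckets:
    def test_hand_counted_split(self):
        out = duration_bucket_percentages([ev(10), ev(20), ev(40)], [30])
        assert out["<=30s"] == pytest.approx(66.6667, abs=1e-3)
        assert out[">30s"] == pytest.approx(33.3333, abs=1e-3)

    def test_boundary_is_inclusive(self):
        out = duration_bucket_percentages([ev(30)] * 4, [30])
        assert out["<=30s"] == 100.0

    def test_single_event(self):
        out = duration_bucket_percentages([ev(50)], [30, 60])
        assert out["30-60s"] == 100.0

    def test_percentages_sum_to_100(self, rng):
        events = [ev(int(d) * 2) for d in rng.integers(1, 200, 60)]
        out = duration_bucket_percentages(events, [30, 60, 300])
        assert sum(out.values()) == pytest.approx(100.0)

    def test_reordering_invariance(self, rng):
        events = [ev(int(d) * 2) for d in rng.integers(1, 100, 40)]
        a = duration_bucket_percentages(events, [30, 60])
        b = duration_bucket_percentages(events[::-1], [30, 60])
        assert a == b

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            duration_bucket_percentages([], [30])


class TestOutOfRange:
    def test_all_in_range(self):
        tr = build_trace([90] * 10)
        out = out_of_range_fraction(tr, 85, 96, "spo2")
        assert out == {"below": 0.0, "above": 0.0}

    def test_strict_inequalities_at_thresholds(self):
        tr = build_trace([84, 85, 96, 97])
        out = out_of_range_fraction(tr, 85, 96, "spo2")
        assert out["below"] == pytest.approx(0.25)
        assert out["above"] == pytest.approx(0.25)

    def test_disabled_threshold_counts_nothing(self):
        tr = build_trace([100] * 5)
        assert out_of_range_fraction(tr, 85, None, "spo2")["above"] == 0.0

    def test_no_valid_samples_raises(self):
        tr = build_trace([None, None])
        with pytest.raises(ValueError):
            out_of_range_fraction(tr, 85, 96, "spo2")

    def test_monotone_in_thresholds(self, rng):
        vals = rng.integers(60, 101, 500).astype(float)
        lows = [70, 80, 85, 90]
        belows = [fraction_out_of_range(vals, lo, None)["below"] for lo in lows]
        assert all(a <= b for a, b in zip(belows, belows[1:]))
        highs = [90, 94, 96, None]
        aboves = [fraction_out_of_range(vals, None, hi)["above"] for hi in highs]
        assert all(a >= b for a, b in zip(aboves, aboves[1:]))
        assert aboves[-1] == 0.0


class TestCohortSummary:
    def _row(self, nid, n, hours):
        events = [ev(20, start_t=600 * i) for i in range(n)]
        return per_neonate_summary(nid, events, hours)

    def test_single_neonate_iqr_zero(self):
        s = cohort_summary([self._row("a", 6, 2.0)])
        assert s.cohort["alarms_per_hour_median"] == pytest.approx(3.0)
        assert s.cohort["alarms_per_hour_iqr"] == 0.0

    def test_hand_median(self):
        rows = [self._row("a", 4, 2.0), self._row("b", 8, 2.0), self._row("c", 18, 2.0)]
        s = cohort_summary(rows)
        assert s.cohort["alarms_per_hour_median"] == pytest.approx(4.0)

    def test_quantiles_match_independent_oracle(self, rng):
        dens = rng.uniform(0, 30, 11)
        rows = [self._row(str(i), 1, 1 / d) for i, d in enumerate(dens)]
        s = cohort_summary(rows)
        srt = np.sort(dens)
        # linear-interpolation quartiles, computed by hand
        def q(p):
            pos = p * (len(srt) - 1)
            lo = int(np.floor(pos))
            frac = pos - lo
            hi = min(lo + 1, len(srt) - 1)
            return srt[lo] * (1 - frac) + srt[hi] * frac

        assert s.cohort["alarms_per_hour_median"] == pytest.approx(q(0.5))
        assert s.cohort["alarms_per_hour_iqr"] == pytest.approx(q(0.75) - q(0.25))

    def test_pooled_count_conservation(self):
        rows = [self._row("a", 4, 2.0), self._row("b", 9, 3.0)]
        s = cohort_summary(rows)
        assert s.cohort["total_alarms"] == 13

    def test_empty_cohort_raises(self):
        with pytest.raises(ValueError):
            cohort_summary([])


def test_max_window_count_aligned_windows():
    events = [ev(10, start_t=s) for s in (0, 100, 3599, 3600, 7300)]
    assert max_window_count(events, 3600.0) == 3
    assert max_window_count(events, 86400.0) == 5
    assert max_window_count([], 3600.0) == 0


def test_audio_visual_counts_in_both_modality_streams():
    events = [ev(10, modality="audio_visual"), ev(10, modality="visual")]
    row = per_neonate_summary("a", events, 1.0)
    assert row["n_visual"] == 2
    assert row["n_audible"] == 1
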