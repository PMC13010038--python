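import numpy as np
import pytest
from dataclasses import replace

from oxiburden import (
    AlarmSettings,
    DEFAULT_SETTINGS,
    expand_grid,
    moving_average,
    simulate_alarm_stream,
    what_if_sweep,
)
from oxiburden.alarm_logic import alarm_masks

from helpers import build_trace


class TestMovingAverage:
    def test_constant_series(self):
        out = moving_average([95.0] * 10, 8)
        assert np.allclose(out, 95.0)

    def test_window_2s_is_identity(self):
        v = np.array([99.0, 80.0, np.nan, 90.0])
        out = moving_average(v, 2)
        assert np.array_equal(out, v, equal_nan=True)

    def test_hand_computed_trailing_means(self):
        out = moving_average([100.0, 100.0, 90.0, 90.0], 8)
        assert out == pytest.approx([100.0, 100.0, 96.6667, 95.0], abs=1e-3)

    def test_nulls_excluded_from_window(self):
        out = moving_average([100.0, np.nan, 90.0, 90.0], 8)
        assert out == pytest.approx([100.0, 100.0, 95.0, 280 / 3], abs=1e-3)

    def test_fully_null_window_is_null(self):
        out = moving_average([np.nan, np.nan, 90.0], 4)
        assert np.isnan(out[0]) and np.isnan(out[1]) and out[2] == 90.0

    def test_output_within_window_bounds(self, rng):
        v = rng.uniform(60, 100, 300)
        v[rng.random(300) < 0.2] = np.nan
        out = moving_average(v, 16)
        lo, hi = np.nanmin(v), np.nanmax(v)
        finite = ~np.isnan(out)
        assert (out[finite] >= lo - 1e-9).all() and (out[finite] <= hi + 1e-9).all()

    def test_bad_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average([1.0], 3)


class TestSimulator:
    def test_in_range_trace_never_alarms(self):
        tr = build_trace([90] * 100, pr=[150] * 100)
        assert simulate_alarm_stream(tr) == []

    def test_delay_asserts_at_eighth_violating_cell(self):
        # SpO2 80 throughout: violation from the first cell, 15 s delay
        # asserts once 8 cells (16 s) have violated, i.e. at t=14.
        n = 50
        tr = build_trace([80] * n)
        (event,) = simulate_alarm_stream(tr)
        assert event.category == "spo2_low"
        assert event.start_t == 14
        assert event.active_cell_count == n - 7

    def test_rapid_desaturation_bypasses_delay(self):
        # 70 <= 85 - 10: the low alarm asserts at the first violating cell
        tr = build_trace([70] * 50)
        (event,) = simulate_alarm_stream(tr)
        assert event.start_t == 0
        assert event.active_cell_count == 50

    def test_degenerate_settings_reproduce_raw_crossings(self, rng):
        """delay 0 + averaging 2 s: the alarm mask equals the per-cell
        threshold-crossing indicator exactly (independent comparison)."""
        settings = replace(DEFAULT_SETTINGS, delay_s=0.0, averaging_s=2.0,
                           rapid_desat_pct=0.0)
        for _ in range(25):
            n = int(rng.integers(5, 200))
            spo2 = rng.integers(70, 101, n).astype(float)
            pr = rng.integers(60, 230, n).astype(float)
            spo2[rng.random(n) < 0.1] = np.nan
            tr = build_trace(spo2, pr=pr)
            masks = alarm_masks(tr, settings)
            with np.errstate(invalid="ignore"):
                assert np.array_equal(masks["spo2_low"], spo2 < 85)
                assert np.array_equal(masks["spo2_high"], spo2 > 96)
                assert np.array_equal(masks["pr_low"], pr < 90)
                assert np.array_equal(masks["pr_high"], pr > 200)

    def test_null_average_never_violates(self):
        tr = build_trace([None] * 30)
        assert simulate_alarm_stream(tr) == []

    def test_grid_gap_breaks_violation_continuity(self):
        # 6 violating cells, a 60 s recording gap, 6 more: neither run
        # reaches the 8-cell delay horizon, so no alarm asserts
        t = np.concatenate([np.arange(6) * 2, 60 + np.arange(6) * 2])
        tr = build_trace([80] * 12, t=t)
        tr = build_trace([80] * 12, t=t)
        assert simulate_alarm_stream(tr) == []


def _mixed_trace(rng, n=2000):
    """Trace wandering across both SpO2 thresholds and PR excursions."""
    spo2 = np.clip(np.round(93 + np.cumsum(rng.normal(0, 1.2, n))), 60, 100)
    pr = np.clip(np.round(150 + np.cumsum(rng.normal(0, 3, n))), 50, 240)
    return build_trace(spo2, pr=pr)


class TestMonotonicity:
    def test_counts_non_increasing_in_delay(self, rng):
        # counted at the annunciation level (gap_s=0): the 30 s merge can
        # re-split a merged pair when a longer delay widens their gap
        from oxiburden import SegmentationConfig

        tr = _mixed_trace(rng)
        grid = expand_grid(DEFAULT_SETTINGS, delay_s=[0, 10, 15, 30])
        counts = [
            r.total_alarms
            for r in what_if_sweep([tr], grid, SegmentationConfig(gap_s=0))
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_low_alarms_non_increasing_as_low_threshold_drops(self, rng):
        tr = _mixed_trace(rng)
        grid = expand_grid(DEFAULT_SETTINGS, spo2_low=[88, 85, 80, 75])
        res = what_if_sweep([tr], grid)
        low_counts = [r.n_alarms["spo2_low"] for r in res]
        assert all(a >= b for a, b in zip(low_counts, low_counts[1:]))
        belows = [r.out_of_range["spo2"]["below"] for r in res]
        assert all(a >= b for a, b in zip(belows, belows[1:]))

    def test_high_alarms_non_increasing_as_upper_threshold_rises(self, rng):
        tr = _mixed_trace(rng)
        grid = expand_grid(DEFAULT_SETTINGS, spo2_high=[94, 96, 98, None])
        res = what_if_sweep([tr], grid)
        high_counts = [r.n_alarms["spo2_high"] for r in res]
        assert all(a >= b for a, b in zip(high_counts, high_counts[1:]))

    def test_disabled_upper_threshold_gives_zero_high_alarms(self, rng):
        tr = _mixed_trace(rng)
        settings = replace(DEFAULT_SETTINGS, spo2_high=None, pr_high=None)
        ev = simulate_alarm_stream(tr, settings)
        assert not any(e.category in ("spo2_high", "pr_high") for e in ev)


class TestWhatIfSweep:
    def test_defaults_grid_matches_direct_simulation(self, rng):
        tr = _mixed_trace(rng, n=1000)
        (res,) = what_if_sweep([tr], [DEFAULT_SETTINGS])
        direct = simulate_alarm_stream(tr, DEFAULT_SETTINGS)
        assert res.total_alarms == len(direct)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            what_if_sweep([_mixed_trace(rng, 100)], [])

    def test_expand_grid_cross_product(self):
        grid = expand_grid(DEFAULT_SETTINGS, delay_s=[0, 10], spo2_low=[80, 85, 88])
        assert len(grid) == 6


class TestAlarmSettings:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"spo2_low": 96, "spo2_high": 96},
            {"delay_s": -1},
            {"averaging_s": 5},
            {"rapid_desat_pct": -2},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AlarmSettings(**kwargs)

    def test_disabled_upper_thresholds_allowed(self):
        s = AlarmSettings(spo2_high=None, pr_high=None)
        assert s.spo2_high is None
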