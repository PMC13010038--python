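import numpy as np
import pytest
from dataclasses import replace

import oxiburden as ox
from oxiburden.alarm_logic import AlarmSettings
from oxiburden.synthetic_data import (
    SpecValidationError,
    SyntheticCohortSpec,
    default_calibration,
    generate_cohort,
)

from helpers import event_tuples


def small_spec(**over):
    base = dict(
        n_neonates=2,
        seed=99,
        duration_median_d=0.3,
        duration_min_d=0.2,
        duration_max_d=0.4,
    )
    base.update(over)
    return replace(default_calibration(), **base)


def test_same_seed_reproduces_byte_identical_traces():
    t1, g1 = generate_cohort(small_spec())
    t2, g2 = generate_cohort(small_spec())
    for a, b in zip(t1, t2):
        assert a.equals(b)
    assert g1.to_json() == g2.to_json()


def test_different_seeds_differ():
    t1, _ = generate_cohort(small_spec())
    t2, _ = generate_cohort(small_spec(seed=100))
    assert not t1[0].equals(t2[0])


def test_annotations_self_consistent_with_simulator():
    """Alarm annotations written into the traces are exactly what the
    monitor-logic simulator produces from the raw values."""
    traces, truth = generate_cohort(small_spec())
    for tr in traces:
        sim = ox.simulate_alarm_stream(tr)
        seg = [
            e for e in ox.segment_events(tr)
            if e.category in ox.CLINICAL_CATEGORIES
        ]
        assert event_tuples(seg) == event_tuples(sim)
        assert event_tuples(sim) == event_tuples(
            truth.per_neonate[tr.neonate_id].alarm_events
        )


def test_planted_truth_recovery_without_artifacts():
    """With artifacts off, segmenting the generated annotations recovers
    the ground-truth alarm events exactly (counts and durations)."""
    spec = small_spec(artifact_gap_mean=1e12, stray_null_rate=0.0,
                      stray_low_siq_rate=0.0)
    traces, truth = generate_cohort(spec)
    n_events = 0
    for tr in traces:
        ftr, rep = ox.apply_quality_rules(tr)
        assert rep.excluded_fraction == 0.0
        got = [
            e for e in ox.segment_events(ftr)
            if e.category in ox.CLINICAL_CATEGORIES
        ]
        want = truth.per_neonate[tr.neonate_id].alarm_events
        assert event_tuples(got) == event_tuples(want)
        n_events += len(want)
    assert n_events > 0


def test_single_planted_desat_recovered_at_exact_dwell():
    """One deep desaturation, annotated without averaging or delay,
    comes back as a single low alarm spanning exactly the planted dwell."""
    ann = AlarmSettings(delay_s=0.0, averaging_s=2.0, rapid_desat_pct=0.0)
    spec = small_spec(
        n_neonates=1,
        annotation_settings=ann,
        artifact_gap_mean=1e12,
        stray_null_rate=0.0,
        stray_low_siq_rate=0.0,
        # exactly one excursion type: deep desats, far apart
        p_excursion_low=1.0,
        desat_deep_prob=1.0,
        desat_deep_long_prob=0.0,
        desat_deep_dwell_median=20.0,
        desat_deep_dwell_sigma=0.0,
        desat_deep_depth=(70, 70),
        spo2_mid_dwell_mean=2000.0,
        brady_coupling_prob=0.0,
        pr_gap_mean=1e12,
    )
    traces, truth = generate_cohort(spec)
    (tr,) = traces
    desats = [p for p in truth.per_neonate[tr.neonate_id].planted
              if p.kind == "desat"]
    events = [e for e in ox.segment_events(tr) if e.category == "spo2_low"]
    # drop a possible truncated final episode at the trace end
    full = [p for p in desats if p.onset_t + p.duration_s < len(tr) * 2]
    assert len(full) >= 1
    by_onset = {e.start_t: e for e in events}
    for p in full:
        e = by_onset[p.onset_t]
        assert e.duration_s == p.duration_s == 40


def test_desat_free_in_band_spec_never_alarms():
    spec = small_spec(
        p_excursion_low=0.0,
        high_dwell_long_prob=0.0,
        high_dwell_short_median=1.0,
        spo2_high_values=(96,),
        spo2_high_weights=(1.0,),
        artifact_gap_mean=1e12,
        stray_null_rate=0.0,
        pr_gap_mean=1e12,
        brady_coupling_prob=0.0,
    )
    traces, truth = generate_cohort(spec)
    for tr in traces:
        spo2 = tr.df["spo2"].to_numpy()
        assert np.nanmin(spo2) >= 85 and np.nanmax(spo2) <= 96
        assert [e for e in ox.segment_events(tr)
                if e.category.startswith("spo2")] == []


def test_desat_rate_monotonically_raises_tail_mass():
    """More desaturation excursions -> strictly more mass below 85%."""
    tails = []
    for p_low in (0.4, 0.7955, 0.95):
        spec = small_spec(n_neonates=3, p_excursion_low=p_low,
                          het_desat_sigma=0.0)
        traces, _ = generate_cohort(spec)
        vals = ox.pooled_values([ox.apply_quality_rules(t)[0] for t in traces],
                                "spo2")
        tails.append(float(np.mean(vals < 85)))
    assert tails[0] < tails[1] < tails[2]


def test_point_mass_at_96_supports_median(small_cohort):
    """Median 96 with half the values out of [85, 96] needs a sizeable
    point mass at exactly 96%; the generator provides it."""
    _, traces, _ = small_cohort
    vals = ox.pooled_values([ox.apply_quality_rules(t)[0] for t in traces], "spo2")
    assert np.mean(vals == 96) >= 0.058


def test_pr_values_out_of_band_only_during_episodes(small_cohort):
    _, traces, truth = small_cohort
    tr = traces[0]
    pr = tr.df["pr"].to_numpy()
    planted = truth.per_neonate[tr.neonate_id].planted
    episode = np.zeros(len(tr), dtype=bool)
    for p in planted:
        if p.kind in ("brady", "tachy"):
            episode[p.onset_t // 2 : (p.onset_t + p.duration_s) // 2] = True
    art = np.zeros(len(tr), dtype=bool)
    for a in truth.per_neonate[tr.neonate_id].artifacts:
        art[a.onset_t // 2 : (a.onset_t + a.duration_s) // 2] = True
    outside = ~episode & ~art & ~np.isnan(pr)
    assert (pr[outside] >= 90).all() and (pr[outside] <= 200).all()


def test_infeasible_spec_rejected():
    with pytest.raises(SpecValidationError):
        generate_cohort(small_spec(artifact_dwell_median=1e9))
    with pytest.raises(SpecValidationError):
        generate_cohort(small_spec(n_neonates=0))
    with pytest.raises(SpecValidationError):
        generate_cohort(small_spec(desat_deep_depth=(80, 90)))


def test_default_calibration_scales():
    desk = default_calibration()
    full = default_calibration(full_scale=True)
    assert desk.n_neonates == full.n_neonates == 49
    assert full.duration_median_d == pytest.approx(11.2)
    assert full.duration_max_d == pytest.approx(41.0)
    assert desk.duration_median_d < full.duration_median_d
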