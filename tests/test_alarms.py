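import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oxialarm import (
    AlarmStrategy,
    ConfigError,
    TargetRange,
    alarm_rate,
    audible_fraction,
    detect_alarms,
    strategy_from_target,
)

from conftest import make_series, random_series
from _oracles import naive_alarm_scan


def events_as_tuples(events):
    return [(e.kind, e.start, e.end) for e in events]


@pytest.mark.parametrize(
    "range_lo,range_hi,kind,low,high,delay",
    [
        (88, 95, "tight", 87, 96, 30),
        (88, 95, "loose", 85, 98, 90),
        (90, 94, "tight", 89, 95, 30),
        (90, 94, "loose", 87, 97, 90),
    ],
)
def test_strategy_thresholds_offset_from_target_range(range_lo, range_hi, kind, low, high, delay):
    s = strategy_from_target(TargetRange(range_lo, range_hi), kind)
    assert (s.low_alarm, s.high_alarm, s.delay_s) == (low, high, delay)


def test_strategy_outside_physiologic_bounds_rejected():
    with pytest.raises(ConfigError):
        strategy_from_target(TargetRange(1.5, 95.0), "loose")  # low alarm < 1
    with pytest.raises(ConfigError):
        AlarmStrategy("x", low_alarm=90, high_alarm=85, delay_s=30)
    with pytest.raises(ConfigError):
        AlarmStrategy("x", low_alarm=85, high_alarm=95, delay_s=17)


def test_in_range_series_never_alarms(target):
    s = make_series(np.full(720, 92.0))
    for kind in ("tight", "loose"):
        assert detect_alarms(s, strategy_from_target(target, kind)) == []


def test_forty_second_desaturation_alarms_tight_only(target):
    """A 40-s run at SpO2 82 outlasts the 30-s tight delay but not 90 s."""
    spo2 = np.full(100, 92.0)
    spo2[20:28] = 82.0  # 8 samples = 40 s
    s = make_series(spo2)
    tight = detect_alarms(s, strategy_from_target(target, "tight"))
    # annunciates at the 6th violating sample, sounds until back in range
    assert events_as_tuples(tight) == [("low", 25, 28)]
    assert audible_fraction(tight, s) == pytest.approx(100.0 * 3 / 100)
    assert detect_alarms(s, strategy_from_target(target, "loose")) == []


def test_violation_run_equal_to_delay_gives_one_sample_residue(target):
    spo2 = np.full(60, 92.0)
    spo2[10:16] = 80.0  # exactly 30 s
    events = detect_alarms(make_series(spo2), strategy_from_target(target, "tight"))
    assert events_as_tuples(events) == [("low", 15, 16)]
    spo2[10:15] = 92.0  # now only 5 s of violation: under the delay
    assert detect_alarms(make_series(spo2), strategy_from_target(target, "tight")) == []


def test_single_in_range_sample_resets_the_timer(target):
    spo2 = np.full(40, 92.0)
    spo2[5:10] = 82.0
    spo2[11:16] = 82.0  # two 25-s runs split by one good sample
    s = make_series(spo2)
    assert detect_alarms(s, strategy_from_target(target, "tight")) == []


def test_invalid_samples_pause_but_do_not_reset_by_default(target):
    spo2 = np.full(40, 82.0)
    spo2[:5] = 92.0
    valid = np.ones(40, dtype=bool)
    valid[8:12] = False  # dropout inside the violation run
    s = make_series(spo2, valid=valid)
    strat = strategy_from_target(target, "tight")
    events = detect_alarms(s, strat)
    # 3 violating samples, 4-sample pause, then 3 more -> annunciate at idx 14
    assert events_as_tuples(events) == [("low", 14, 40)]
    # with invalid_resets the run restarts after the dropout
    events = detect_alarms(s, strat, invalid_resets=True)
    assert events_as_tuples(events) == [("low", 17, 40)]


def test_high_alarm_detected_on_supplemental_hyperoxemia(target):
    spo2 = np.full(80, 92.0)
    spo2[10:40] = 99.0
    events = detect_alarms(make_series(spo2), strategy_from_target(target, "tight"))
    assert events_as_tuples(events) == [("high", 15, 40)]


def test_rate_and_fraction_arithmetic(target):
    n = 720  # one hour
    spo2 = np.full(n, 92.0)
    spo2[100:120] = 80.0  # 100 s -> one tight event, audible 70 s... (20-6+1)*5
    s = make_series(spo2)
    events = detect_alarms(s, strategy_from_target(target, "tight"))
    assert len(events) == 1
    assert alarm_rate(events, s) == pytest.approx(1.0)
    assert audible_fraction(events, s) == pytest.approx(100.0 * 75 / 3600)


def test_alarm_rate_uses_valid_monitored_hours(target):
    spo2 = np.full(1440, 92.0)
    spo2[100:120] = 80.0
    valid = np.ones(1440, dtype=bool)
    valid[720:] = False  # only one hour of valid monitoring
    s = make_series(spo2, valid=valid)
    events = detect_alarms(s, strategy_from_target(target, "tight"))
    assert alarm_rate(events, s) == pytest.approx(1.0)


def test_matches_naive_scan_on_random_series(rng, target):
    strategies = [
        strategy_from_target(target, "tight"),
        strategy_from_target(target, "loose"),
        AlarmStrategy("custom", 80.0, 97.0, 0.0),
        AlarmStrategy("custom", 90.0, 94.0, 15.0),
    ]
    for _ in range(150):
        s = random_series(rng)
        for strat in strategies:
            for resets in (False, True):
                got = events_as_tuples(detect_alarms(s, strat, invalid_resets=resets))
                want = naive_alarm_scan(
                    s.spo2, s.valid, strat.low_alarm, strat.high_alarm,
                    strat.delay_s, invalid_resets=resets,
                )
                assert got == want


@st.composite
def short_series(draw):
    n = draw(st.integers(20, 120))
    spo2 = draw(
        st.lists(st.integers(70, 100), min_size=n, max_size=n).map(np.array)
    )
    valid = draw(st.lists(st.booleans(), min_size=n, max_size=n).map(np.array))
    if not valid.any():
        valid[0] = True
    return make_series(spo2.astype(float), valid=valid)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(short_series(), st.integers(0, 6), st.integers(0, 6))
def test_event_count_monotone_in_delay(s, d1, d2):
    """Lengthening the persistence delay never adds alarm events."""
    lo, hi = min(d1, d2) * 5.0, max(d1, d2) * 5.0
    short = detect_alarms(s, AlarmStrategy("a", 85.0, 96.0, lo))
    long = detect_alarms(s, AlarmStrategy("b", 85.0, 96.0, hi))
    assert len(long) <= len(short)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(short_series(), st.integers(0, 4))
def test_event_count_monotone_in_threshold_width(s, widen):
    """Widening both thresholds never adds alarm events at fixed delay."""
    narrow = detect_alarms(s, AlarmStrategy("n", 87.0, 96.0, 15.0))
    wide = detect_alarms(s, AlarmStrategy("w", 87.0 - widen, 96.0 + widen, 15.0))
    assert len(wide) <= len(narrow)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(short_series())
def test_events_disjoint_and_false_outside(s):
    strat = AlarmStrategy("a", 87.0, 96.0, 10.0)
    events = detect_alarms(s, strat)
    by_kind = {}
    for e in events:
        by_kind.setdefault(e.kind, []).append(e)
        # no valid in-range sample strictly inside the audible interval
        inside = slice(e.start, e.end)
        viol = (
            s.spo2[inside] < strat.low_alarm
            if e.kind == "low"
            else s.spo2[inside] > strat.high_alarm
        )
        in_range_valid = s.valid[inside] & ~viol
        assert not in_range_valid.any()
    for evs in by_kind.values():
        for a, b in zip(evs, evs[1:]):
            assert a.end < b.start  # separated by at least one sample
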