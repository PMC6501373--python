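import numpy as np
import pytest

from oxialarm import (
    DataError,
    episode_rate,
    find_episodes,
    hourly_median_summary,
    in_range_suppl_o2_pct,
    manual_adjustment_count,
    normoxemia_pct,
    prevalence,
    spo2_histogram,
    summarize_day,
)
from oxialarm.metrics import HYPEROXEMIA, HYPOXEMIA

from conftest import make_series, random_series
from _oracles import naive_episodes


def test_quiet_series_has_no_episodes():
    s = make_series(np.full(720, 92.0))
    assert find_episodes(s, HYPOXEMIA) == []
    assert find_episodes(s, HYPEROXEMIA) == []
    with pytest.raises(ValueError):
        find_episodes(s, "apnoea")


def test_hyperoxemia_requires_supplemental_oxygen():
    """SpO2 99% on room air is not hyperoxemia; on O2 it is."""
    s = make_series(np.full(100, 99.0), fio2=0.21)
    assert find_episodes(s, HYPEROXEMIA) == []
    assert prevalence(s, HYPEROXEMIA) == 0.0
    s = make_series(np.full(100, 99.0), fio2=0.30)
    assert prevalence(s, HYPEROXEMIA) == 100.0


def test_65s_hypoxemic_run_counts_above_1min_not_3min():
    spo2 = np.full(200, 92.0)
    spo2[50:63] = 79.0  # 13 samples = 65 s
    s = make_series(spo2)
    eps = find_episodes(s, HYPOXEMIA)
    assert [(e.start, e.end) for e in eps] == [(50, 63)]
    assert eps[0].duration_s == 65.0
    assert episode_rate(eps, s, 60.0) == pytest.approx(1.0 / s.duration_days)
    assert episode_rate(eps, s, 180.0) == 0.0


def test_episode_split_or_bridged_across_dropout():
    spo2 = np.full(40, 79.0)
    valid = np.ones(40, dtype=bool)
    valid[10:14] = False
    s = make_series(spo2, valid=valid)
    split = find_episodes(s, HYPOXEMIA)
    assert [(e.start, e.end) for e in split] == [(0, 10), (14, 40)]
    bridged = find_episodes(s, HYPOXEMIA, split_on_invalid=False)
    assert [(e.start, e.end) for e in bridged] == [(0, 40)]


def test_prevalence_arithmetic_and_denominator():
    spo2 = np.full(17280, 92.0)
    spo2[:172] = 79.0
    s = make_series(spo2)
    assert prevalence(s, HYPOXEMIA) == pytest.approx(100.0 * 172 / 17280)
    # invalid samples leave the denominator
    valid = np.ones(17280, dtype=bool)
    valid[8640:] = False
    s2 = make_series(spo2, valid=valid)
    assert prevalence(s2, HYPOXEMIA) == pytest.approx(100.0 * 172 / 8640)
    with pytest.raises(DataError):
        prevalence(make_series([92.0], valid=[False]), HYPOXEMIA)


@pytest.mark.parametrize(
    "spo2,fio2,expected",
    [
        (92, 0.30, 100.0),  # inside 86-96
        (98, 0.21, 100.0),  # high but on room air
        (98, 0.30, 0.0),    # high on supplemental oxygen
        (84, 0.21, 0.0),    # low is never normoxemia
    ],
)
def test_normoxemia_definition(spo2, fio2, expected):
    s = make_series(np.full(50, float(spo2)), fio2=fio2)
    assert normoxemia_pct(s) == expected


def test_in_range_on_supplemental_oxygen_pct():
    spo2 = np.array([92.0] * 30 + [84.0] * 10 + [92.0] * 20)
    fio2 = np.array([0.30] * 40 + [0.21] * 20)  # last 20 samples on room air
    s = make_series(spo2, fio2=fio2)
    assert in_range_suppl_o2_pct(s) == pytest.approx(100.0 * 30 / 40)
    room_air_only = make_series(np.full(10, 92.0), fio2=0.21)
    assert np.isnan(in_range_suppl_o2_pct(room_air_only))


def test_hourly_median_summary_and_permutation_invariance(rng):
    spo2 = np.concatenate([np.full(720, 90.0), np.full(720, 94.0)])
    s = make_series(spo2)
    med_spo2, med_fio2 = hourly_median_summary(s)
    assert med_spo2 == pytest.approx(92.0)
    assert med_fio2 == pytest.approx(0.30)
    # permuting samples within each hour leaves the hourly medians unchanged
    perm = np.concatenate([rng.permutation(720), 720 + rng.permutation(720)])
    s2 = make_series(spo2[perm])
    assert hourly_median_summary(s2) == (med_spo2, med_fio2)


def test_histogram_restricted_to_supplemental_oxygen_and_normalized(rng):
    for _ in range(25):
        s = random_series(rng)
        hist = spo2_histogram(s)
        sel = s.valid & (s.fio2 > 0.215)
        if not sel.any():
            assert hist == {}
            continue
        assert sum(hist.values()) == pytest.approx(100.0, abs=1e-6)
        assert all(isinstance(b, int) for b in hist)


def test_manual_adjustment_rate():
    manual = np.zeros(17280, dtype=bool)
    manual[[10, 400, 9000]] = True
    s = make_series(np.full(17280, 92.0), manual=manual)
    assert manual_adjustment_count(s) == pytest.approx(3.0)


def test_episode_durations_conserve_prevalence(rng):
    """Sum of episode durations of a kind equals prevalence x valid time."""
    for _ in range(40):
        s = random_series(rng)
        for kind in (HYPOXEMIA, HYPOXEMIA, HYPEROXEMIA):
            eps = find_episodes(s, kind)
            total_s = sum(e.duration_s for e in eps)
            expected = prevalence(s, kind) / 100.0 * s.n_valid * 5.0
            assert total_s == pytest.approx(expected, abs=1e-9)


def test_episode_runs_match_naive_scan(rng):
    for _ in range(60):
        s = random_series(rng)
        for kind, mask in (
            (HYPOXEMIA, s.valid & (s.spo2 < 80)),
            (HYPEROXEMIA, s.valid & (s.spo2 > 98) & (s.fio2 > 0.215)),
        ):
            got = [(e.start, e.end) for e in find_episodes(s, kind)]
            assert got == naive_episodes(mask)


def test_summary_counts_nest_and_histogram_normalizes(rng):
    for _ in range(10):
        s = random_series(rng, n=1500)
        summ = summarize_day(s)
        assert summ.hypox_episodes_gt3min_per24h <= summ.hypox_episodes_gt1min_per24h
        assert summ.hyper_episodes_gt3min_per24h <= summ.hyper_episodes_gt1min_per24h
        if summ.spo2_histogram:
            assert sum(summ.spo2_histogram.values()) == pytest.approx(100.0, abs=1e-6)
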