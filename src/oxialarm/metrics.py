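"""Oxygenation-exposure outcomes on a 5-s SpO2/FiO2 log.

Definitions (device-resolution integer SpO2, exact comparisons):

* hypoxemia: valid sample with SpO2 < 80%.
* hyperoxemia: valid sample with SpO2 > 98% while on supplemental
  oxygen (FiO2 > 0.21; time on room air is excluded).
* normoxemia: SpO2 in 86-96%, or above 96% while breathing room air.
* prolonged episodes: maximal runs of the hypoxemia/hyperoxemia
  predicate longer than 1 min (or 3 min).
* hourly medians: median SpO2 and FiO2 per wall-clock hour from series
  start, summarised as the unweighted mean of the hourly medians.

All "% time" figures use valid monitored samples as the denominator.
An episode interrupted by a signal dropout is split by default (an
invalid sample never extends an episode); ``split_on_invalid=False``
bridges runs separated only by invalid samples instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alarms import AlarmEvent
from .config import SAMPLE_INTERVAL_S
from .series import DataError, OxiSeries, on_room_air, on_supplemental_o2

HYPOXEMIA = "hypoxemia"
HYPEROXEMIA = "hyperoxemia"

SAMPLES_PER_HOUR = int(round(3600 / SAMPLE_INTERVAL_S))


@dataclass(frozen=True)
class Episode:
    """Maximal run of an extreme-SpO2 predicate, half-open sample indices."""

    kind: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise DataError(f"episode must have start < end, got [{self.start}, {self.end})")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) * SAMPLE_INTERVAL_S


def _predicate(series: OxiSeries, kind: str) -> np.ndarray:
    if kind == HYPOXEMIA:
        return series.valid & (series.spo2 < 80)
    if kind == HYPEROXEMIA:
        return series.valid & (series.spo2 > 98) & on_supplemental_o2(series.fio2)
    raise ValueError(f"unknown episode kind {kind!r}; expected "
                     f"'{HYPOXEMIA}' or '{HYPEROXEMIA}'")


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2].tolist(), edges[1::2].tolist()))


def find_episodes(
    series: OxiSeries, kind: str, split_on_invalid: bool = True
) -> list[Episode]:
    """Maximal predicate runs; optionally bridged across dropouts."""
    mask = _predicate(series, kind)
    runs = _true_runs(mask)
    if not split_on_invalid and runs:
        # merge consecutive runs separated only by invalid samples
        merged = [runs[0]]
        for a, b in runs[1:]:
            pa, pb = merged[-1]
            if np.all(~series.valid[pb:a]):
                merged[-1] = (pa, b)
            else:
                merged.append((a, b))
        runs = merged
    return [Episode(kind=kind, start=a, end=b) for a, b in runs]


def prevalence(series: OxiSeries, kind: str) -> float:
    """Percent of valid monitored time with the predicate satisfied."""
    nv = series.n_valid
    if nv == 0:
        raise DataError("series has no valid samples")
    return 100.0 * float(_predicate(series, kind).sum()) / nv


def episode_rate(
    episodes: Sequence[Episode], series: OxiSeries, min_duration_s: float
) -> float:
    """Episodes strictly longer than ``min_duration_s``, per 24 h monitored."""
    days = series.duration_days
    if days == 0:
        raise DataError("empty series")
    count = sum(1 for e in episodes if e.duration_s > min_duration_s)
    return count / days


def normoxemia_pct(series: OxiSeries) -> float:
    """SpO2 86-96%, or > 96% on room air, as % of valid time."""
    nv = series.n_valid
    if nv == 0:
        raise DataError("series has no valid samples")
    sp = series.spo2
    ok = (sp >= 86) & (sp <= 96)
    ok |= (sp > 96) & on_room_air(series.fio2)
    return 100.0 * float((series.valid & ok).sum()) / nv


def in_range_suppl_o2_pct(series: OxiSeries) -> float:
    """SpO2 86-96% among valid samples on supplemental oxygen; NaN if none."""
    sel = series.valid & on_supplemental_o2(series.fio2)
    n = int(sel.sum())
    if n == 0:
        return float("nan")
    sp = series.spo2
    hit = sel & (sp >= 86) & (sp <= 96)
    return 100.0 * float(hit.sum()) / n


def hourly_medians(series: OxiSeries) -> pd.DataFrame:
    """Per-hour median SpO2 and FiO2 over valid samples.

    Hours are anchored at the series start. Hours without a single
    valid sample are omitted.
    """
    hour = np.arange(len(series)) // SAMPLES_PER_HOUR
    df = pd.DataFrame(
        {"hour": hour, "spo2": series.spo2, "fio2": series.fio2}
    )[series.valid]
    if df.empty:
        raise DataError("series has no valid samples")
    return df.groupby("hour").median()


def hourly_median_summary(series: OxiSeries) -> tuple[float, float]:
    """(mean of hourly median SpO2, mean of hourly median FiO2)."""
    med = hourly_medians(series)
    return float(med["spo2"].mean()), float(med["fio2"].mean())


def spo2_histogram(series: OxiSeries) -> dict[int, float]:
    """% of supplemental-oxygen time per integer SpO2 bin.

    Restricted to valid samples with FiO2 > 0.21; percentages sum to
    100 over that subset. Empty mapping if the subject never received
    supplemental oxygen.
    """
    sel = series.valid & on_supplemental_o2(series.fio2)
    n = int(sel.sum())
    if n == 0:
        return {}
    bins = np.round(series.spo2[sel]).astype(int)
    vals, counts = np.unique(bins, return_counts=True)
    return {int(v): 100.0 * int(c) / n for v, c in zip(vals, counts)}


def manual_adjustment_count(series: OxiSeries) -> float:
    """Caregiver FiO2 adjustments per monitored day."""
    days = series.duration_days
    if days == 0:
        raise DataError("empty series")
    return float(series.manual_adjustment.sum()) / days


@dataclass
class ExposureSummary:
    """All exposure outcomes over one subject-day (or pooled days)."""

    pct_hypoxemia: float
    pct_hyperoxemia: float
    hypox_episodes_gt1min_per24h: float
    hypox_episodes_gt3min_per24h: float
    hyper_episodes_gt1min_per24h: float
    hyper_episodes_gt3min_per24h: float
    pct_in_86_96_suppl_o2: float
    pct_normoxemia: float
    mean_of_hourly_median_spo2: float
    mean_of_hourly_median_fio2: float
    manual_adjustments_per_day: float
    pct_invalid: float
    alarm_rate_per_h: float = float("nan")
    audible_pct: float = float("nan")
    spo2_histogram: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "pct_hypoxemia", "pct_hyperoxemia", "pct_in_86_96_suppl_o2",
            "pct_normoxemia", "pct_invalid",
        ):
            v = getattr(self, name)
            if not np.isnan(v) and not 0.0 <= v <= 100.0 + 1e-9:
                raise DataError(f"{name} out of [0, 100]: {v}")
        if self.hypox_episodes_gt3min_per24h > self.hypox_episodes_gt1min_per24h + 1e-12:
            raise DataError("episodes > 3 min cannot outnumber episodes > 1 min")
        if self.hyper_episodes_gt3min_per24h > self.hyper_episodes_gt1min_per24h + 1e-12:
            raise DataError("episodes > 3 min cannot outnumber episodes > 1 min")

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("spo2_histogram")
        return d


class ExposureAccumulator:
    """Pools whole days of one subject under one strategy.

    Pooling recomputes each outcome over the concatenation of the
    contributed days (sums of numerators over sums of denominators;
    hourly medians pooled across all contributed hours) — not the mean
    of per-day values. Alarm events are detected per day (settings
    change daily) and their counts and audible time are pooled here.
    """

    def __init__(self) -> None:
        self.n_total = 0
        self.n_valid = 0
        self.n_suppl = 0
        self.n_in_range_suppl = 0
        self.n_hypox = 0
        self.n_hyper = 0
        self.n_norm = 0
        self.n_manual = 0
        self.episode_durations: dict[str, list[float]] = {HYPOXEMIA: [], HYPEROXEMIA: []}
        self.hourly_spo2: list[float] = []
        self.hourly_fio2: list[float] = []
        self.hist_counts: dict[int, int] = {}
        self.n_alarms = 0
        self.audible_s = 0.0
        self.days = 0

    def add_day(
        self,
        series: OxiSeries,
        alarm_events: Sequence[AlarmEvent] = (),
        split_on_invalid: bool = True,
    ) -> None:
        self.n_total += len(series)
        self.n_valid += series.n_valid
        sel = series.valid & on_supplemental_o2(series.fio2)
        self.n_suppl += int(sel.sum())
        sp = series.spo2
        self.n_in_range_suppl += int((sel & (sp >= 86) & (sp <= 96)).sum())
        self.n_hypox += int(_predicate(series, HYPOXEMIA).sum())
        self.n_hyper += int(_predicate(series, HYPEROXEMIA).sum())
        ok = (sp >= 86) & (sp <= 96)
        ok |= (sp > 96) & on_room_air(series.fio2)
        self.n_norm += int((series.valid & ok).sum())
        self.n_manual += int(series.manual_adjustment.sum())
        for kind in (HYPOXEMIA, HYPEROXEMIA):
            eps = find_episodes(series, kind, split_on_invalid=split_on_invalid)
            self.episode_durations[kind].extend(e.duration_s for e in eps)
        if series.n_valid:
            med = hourly_medians(series)
            self.hourly_spo2.extend(med["spo2"].tolist())
            self.hourly_fio2.extend(med["fio2"].tolist())
        if sel.any():
            bins = np.round(sp[sel]).astype(int)
            vals, counts = np.unique(bins, return_counts=True)
            for v, c in zip(vals, counts):
                self.hist_counts[int(v)] = self.hist_counts.get(int(v), 0) + int(c)
        self.n_alarms += len(alarm_events)
        self.audible_s += sum(e.duration_s for e in alarm_events)
        self.days += 1

    def summary(self) -> ExposureSummary:
        if self.n_valid == 0:
            raise DataError("no valid samples accumulated")
        total_days = self.n_total * SAMPLE_INTERVAL_S / 86400.0
        valid_hours = self.n_valid * SAMPLE_INTERVAL_S / 3600.0

        def _rate(kind: str, min_s: float) -> float:
            return sum(1 for d in self.episode_durations[kind] if d > min_s) / total_days

        hist = (
            {b: 100.0 * c / self.n_suppl for b, c in sorted(self.hist_counts.items())}
            if self.n_suppl
            else {}
        )
        return ExposureSummary(
            pct_hypoxemia=100.0 * self.n_hypox / self.n_valid,
            pct_hyperoxemia=100.0 * self.n_hyper / self.n_valid,
            hypox_episodes_gt1min_per24h=_rate(HYPOXEMIA, 60.0),
            hypox_episodes_gt3min_per24h=_rate(HYPOXEMIA, 180.0),
            hyper_episodes_gt1min_per24h=_rate(HYPEROXEMIA, 60.0),
            hyper_episodes_gt3min_per24h=_rate(HYPEROXEMIA, 180.0),
            pct_in_86_96_suppl_o2=(
                100.0 * self.n_in_range_suppl / self.n_suppl
                if self.n_suppl
                else float("nan")
            ),
            pct_normoxemia=100.0 * self.n_norm / self.n_valid,
            mean_of_hourly_median_spo2=float(np.mean(self.hourly_spo2)),
            mean_of_hourly_median_fio2=float(np.mean(self.hourly_fio2)),
            manual_adjustments_per_day=self.n_manual / total_days,
            pct_invalid=100.0 * (self.n_total - self.n_valid) / self.n_total,
            alarm_rate_per_h=self.n_alarms / valid_hours if valid_hours else float("nan"),
            audible_pct=100.0 * self.audible_s / (self.n_total * SAMPLE_INTERVAL_S),
            spo2_histogram=hist,
        )


def summarize_day(
    series: OxiSeries,
    alarm_events: Sequence[AlarmEvent] = (),
    split_on_invalid: bool = True,
) -> ExposureSummary:
    """One-day convenience wrapper over :class:`ExposureAccumulator`."""
    acc = ExposureAccumulator()
    acc.add_day(series, alarm_events, split_on_invalid=split_on_invalid)
    return acc.summary()


def summaries_to_frame(rows: Iterable[tuple[dict, ExposureSummary]]) -> pd.DataFrame:
    """Tabulate (metadata, summary) pairs; one row per subject-day."""
    records = []
    for meta, summ in rows:
        rec = dict(meta)
        rec.update(summ.to_dict())
        records.append(rec)
    return pd.DataFrame(records)


def histogram_to_frame(subject_id: str, hist: dict[int, float]) -> pd.DataFrame:
    """Long-format histogram rows: subject_id, bin, pct."""
    return pd.DataFrame(
        {"subject_id": subject_id, "bin": list(hist.keys()), "pct": list(hist.values())}
    )
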