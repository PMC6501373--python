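"""Threshold-plus-persistence-delay SpO2 alarm logic.

An alarm strategy is a (low threshold, high threshold, delay) triple.
A violation (valid sample strictly outside a threshold) must persist
continuously for the full delay before the alarm annunciates; the alarm
then sounds until the first subsequent valid in-range sample. A single
valid in-range sample resets the persistence timer; invalid samples
pause it by default (``invalid_resets=True`` makes them reset instead).

All intervals are half-open ``[start, end)`` in sample indices on the
5-s grid; durations are ``(end - start) * 5`` seconds. The annunciation
sample is the one at which the accumulated violation time first reaches
the delay (a run of exactly ``delay`` seconds therefore produces a
one-sample audible residue).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import SAMPLE_INTERVAL_S, ConfigError, StrategySpec, TargetRange
from .series import DataError, OxiSeries

LOW = "low"
HIGH = "high"


@dataclass(frozen=True)
class AlarmStrategy:
    """Alarm thresholds (%) and persistence delay (s) for one strategy."""

    name: str
    low_alarm: float
    high_alarm: float
    delay_s: float

    def __post_init__(self) -> None:
        if not self.low_alarm < self.high_alarm:
            raise ConfigError(
                f"low_alarm must be < high_alarm, got "
                f"{self.low_alarm} >= {self.high_alarm}"
            )
        if self.delay_s < 0:
            raise ConfigError(f"delay must be >= 0 s, got {self.delay_s}")
        if self.delay_s % SAMPLE_INTERVAL_S != 0:
            raise ConfigError(
                f"delay must be a multiple of the {SAMPLE_INTERVAL_S:.0f}-s "
                f"sample interval, got {self.delay_s}"
            )

    @property
    def delay_samples(self) -> int:
        """Consecutive violating samples required before annunciation."""
        return max(int(self.delay_s / SAMPLE_INTERVAL_S), 1)


@dataclass(frozen=True)
class AlarmEvent:
    """One audible alarm: activation (delay satisfied) to deactivation."""

    kind: str  # "low" | "high"
    start: int  # sample index of annunciation
    end: int    # exclusive; first valid in-range sample (or series end)

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise DataError(f"alarm event must have start < end, got [{self.start}, {self.end})")

    @property
    def duration_s(self) -> float:
        return (self.end - self.start) * SAMPLE_INTERVAL_S


def strategy_from_target(
    target: TargetRange, kind: str, spec: StrategySpec | None = None
) -> AlarmStrategy:
    """Derive a strategy's absolute thresholds from the target range.

    ``tight`` sits just outside the range (offsets -1/+1, 30-s delay);
    ``loose`` sits 2% wider (offsets -3/+3, 90-s delay). With the
    default 88-95% range this yields (87, 96, 30 s) and (85, 98, 90 s).
    A custom :class:`StrategySpec` overrides the nominal offsets.
    """
    if spec is None:
        from .config import DEFAULT_STRATEGIES

        try:
            spec = DEFAULT_STRATEGIES[kind]
        except KeyError:
            raise ConfigError(f"unknown strategy kind {kind!r}") from None
    low = target.low + spec.low_offset
    high = target.high + spec.high_offset
    if not (1.0 <= low and high <= 100.0):
        raise ConfigError(
            f"derived alarm thresholds ({low}, {high}) fall outside [1, 100]"
        )
    return AlarmStrategy(name=kind, low_alarm=low, high_alarm=high, delay_s=spec.delay_s)


# ---------------------------------------------------------------------------
# detection

_VIOL, _OK, _INVALID = 2, 0, 1


def _runs(states: np.ndarray) -> Iterable[tuple[int, int, int]]:
    """(state, start, length) for maximal constant runs."""
    n = len(states)
    boundaries = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    for a, b in zip(starts, ends):
        yield int(states[a]), int(a), int(b - a)


def _detect_kind(
    states: np.ndarray, kind: str, delay_samples: int, invalid_resets: bool
) -> list[AlarmEvent]:
    events: list[AlarmEvent] = []
    count = 0           # consecutive violating samples toward the delay
    active_start = -1   # annunciation index of the ongoing alarm, -1 if none
    n = len(states)
    for state, start, length in _runs(states):
        if state == _VIOL:
            if active_start < 0:
                if count + length >= delay_samples:
                    active_start = start + (delay_samples - count) - 1
                count += length
        elif state == _INVALID:
            if invalid_resets:
                count = 0
            # otherwise the timer pauses and an active alarm keeps sounding
        else:  # valid in-range: alarm (if any) deactivates, timer resets
            if active_start >= 0:
                events.append(AlarmEvent(kind=kind, start=active_start, end=start))
                active_start = -1
            count = 0
    if active_start >= 0:
        events.append(AlarmEvent(kind=kind, start=active_start, end=n))
    return events


def detect_alarms(
    series: OxiSeries, strategy: AlarmStrategy, invalid_resets: bool = False
) -> list[AlarmEvent]:
    """All audible SpO2 alarm events of both kinds, sorted by activation."""
    valid = series.valid
    spo2 = series.spo2
    d = strategy.delay_samples
    out: list[AlarmEvent] = []
    for kind, viol in (
        (LOW, valid & (spo2 < strategy.low_alarm)),
        (HIGH, valid & (spo2 > strategy.high_alarm)),
    ):
        states = np.where(viol, _VIOL, np.where(valid, _OK, _INVALID)).astype(np.int8)
        out.extend(_detect_kind(states, kind, d, invalid_resets))
    out.sort(key=lambda e: (e.start, e.kind))
    return out


def alarm_rate(events: Sequence[AlarmEvent], series: OxiSeries) -> float:
    """Audible alarms per valid monitored hour."""
    if len(series) == 0:
        raise DataError("empty series")
    hours = series.valid_hours
    if hours == 0:
        raise DataError("series has no valid samples")
    return len(events) / hours


def audible_fraction(events: Sequence[AlarmEvent], series: OxiSeries) -> float:
    """Percent of monitored time with the SpO2 alarm sounding."""
    if len(series) == 0:
        raise DataError("empty series")
    audible = sum(e.duration_s for e in events)
    return 100.0 * audible / series.duration_s


def events_to_frame(
    events: Sequence[AlarmEvent], subject_id: str, day: int
) -> pd.DataFrame:
    """Event table in the on-disk layout."""
    return pd.DataFrame(
        {
            "subject_id": subject_id,
            "day": day,
            "kind": [e.kind for e in events],
            "start_s": [e.start * SAMPLE_INTERVAL_S for e in events],
            "end_s": [e.end * SAMPLE_INTERVAL_S for e in events],
            "duration_s": [e.duration_s for e in events],
        }
    )


def write_events_csv(frames: Iterable[pd.DataFrame], path: str | Path) -> None:
    frames = list(frames)
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(
            columns=["subject_id", "day", "kind", "start_s", "end_s", "duration_s"]
        )
    df.to_csv(path, index=False)
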