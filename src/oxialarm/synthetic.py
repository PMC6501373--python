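"""Synthetic cohort generator.

Emulates the statistical structure of neonatal SpO2 under closed-loop
FiO2 control: a unimodal SpO2 distribution centred inside the target
range, sporadic desaturation events (Poisson arrivals, log-normal
durations with a heavy tail), rare hyperoxemic drifts, signal dropouts,
and an FiO2 trace that rises in response to desaturations and weans over
the study. The controller emulation is a deliberately simple first-order
relaxation toward the target midpoint — it is a statistical stand-in,
not a model of any commercial titration algorithm.

The SpO2 process is

    spo2[t] = round(clip(m + x[t], modified by event envelopes))

where m is the target midpoint and x is AR(1) noise with lag-1
correlation phi = exp(-dt / controller_timeconstant) and stationary SD
``noise_sd`` — mean reversion plays the role of the closed-loop
pull-back. Desaturation envelopes dip to a nadir below the range and are
composed via min(); hyperoxemic envelopes via max().

Determinism: every stream is seeded from (config.seed, subject_index),
so a subject's series is reproducible independent of cohort order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .config import (
    LOOSE,
    SAMPLES_PER_DAY,
    SAMPLE_INTERVAL_S,
    STRATEGY_LABELS,
    TIGHT,
    ConfigError,
    SimConfig,
)
from .series import OxiSeries


@dataclass(frozen=True)
class SimEvent:
    """Ground-truth record of one injected event (sample indices, half-open)."""

    kind: str          # "desat" | "hyper"
    start: int
    end: int
    extreme: float     # nadir (desat) or peak (hyper) SpO2, %


@dataclass(frozen=True)
class StrategySchedule:
    """Per-24-h-block strategy assignment over one subject's study window."""

    days: tuple[str, ...]

    def __post_init__(self) -> None:
        for d in self.days:
            if d not in STRATEGY_LABELS:
                raise ConfigError(f"unknown strategy label {d!r}")

    def __len__(self) -> int:
        return len(self.days)

    def label_for_day(self, day: int) -> str:
        return self.days[day]


def assign_first_day(n_subjects: int, seed: int) -> list[str]:
    """Balanced-block (size 4) randomization of the first-day strategy.

    Every complete block of four consecutive subjects contains exactly
    two tight and two loose assignments in random order; a trailing
    partial block is the prefix of one more balanced permutation.
    """
    if n_subjects < 1:
        raise ConfigError(f"n_subjects must be >= 1, got {n_subjects}")
    rng = np.random.default_rng([seed, 0xB10C])
    labels: list[str] = []
    n_blocks = -(-n_subjects // 4)
    block = np.array([TIGHT, TIGHT, LOOSE, LOOSE])
    for _ in range(n_blocks):
        labels.extend(rng.permutation(block).tolist())
    return labels[:n_subjects]


def build_schedule(first_day: str, study_days: int) -> StrategySchedule:
    """Alternating 24-h strategy blocks beginning with ``first_day``."""
    if first_day not in STRATEGY_LABELS:
        raise ConfigError(f"unknown strategy label {first_day!r}")
    if study_days < 1:
        raise ConfigError(f"study_days must be >= 1, got {study_days}")
    other = LOOSE if first_day == TIGHT else TIGHT
    return StrategySchedule(
        days=tuple(first_day if d % 2 == 0 else other for d in range(study_days))
    )


# ---------------------------------------------------------------------------
# per-subject signal synthesis


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    eps = rng.normal(0.0, innov_sd, size=n)
    eps[0] = rng.normal(0.0, sd)  # stationary start
    return signal.lfilter([1.0], [1.0, -phi], eps)


def _event_starts(
    rng: np.random.Generator, rate_per_h: float, n: int
) -> np.ndarray:
    """Poisson arrival sample indices over an n-sample window, sorted."""
    hours = n * SAMPLE_INTERVAL_S / 3600.0
    k = rng.poisson(rate_per_h * hours)
    return np.sort(rng.integers(0, n, size=k))


def _mixture_durations(rng: np.random.Generator, cfg: SimConfig, k: int) -> np.ndarray:
    mix = cfg.desat_duration
    body = rng.lognormal(np.log(mix.median_s), mix.sigma, size=k)
    tail = rng.lognormal(np.log(mix.tail_median_s), mix.tail_sigma, size=k)
    is_tail = rng.random(k) < mix.tail_frac
    return np.maximum(np.where(is_tail, tail, body), mix.min_s)


def _envelope(length: int, origin: float, extreme: float) -> np.ndarray:
    """Trapezoidal excursion: ramp from ``origin`` to ``extreme``, plateau
    (>= 70% of the event, always >= 1 sample), ramp back."""
    n_ramp = min(max(int(round(0.15 * length)), 0), (length - 1) // 2)
    n_plateau = length - 2 * n_ramp
    drop = np.linspace(origin, extreme, n_ramp + 2)[1:-1]
    plateau = np.full(n_plateau, extreme)
    rise = np.linspace(extreme, origin, n_ramp + 2)[1:-1]
    return np.concatenate([drop, plateau, rise])


def _place_events(
    starts: np.ndarray,
    durations_s: np.ndarray,
    extremes: np.ndarray,
    n: int,
    kind: str,
    origin: float,
    fill: float,
) -> tuple[list[SimEvent], np.ndarray]:
    """Lay event envelopes on the grid, deferring overlaps.

    An arrival falling inside the previous event is pushed to two
    samples past its end, so each arrival yields one distinct episode
    and the realized event count stays an unbiased Poisson draw.
    ``fill`` is the neutral envelope value outside events (100 for dips
    composed with min(), 0 for drifts composed with max()).
    """
    env = np.full(n, fill)
    events: list[SimEvent] = []
    cursor = 0
    for s, dur, ext in zip(starts, durations_s, extremes):
        start = max(int(s), cursor)
        length = max(int(round(dur / SAMPLE_INTERVAL_S)), 2)
        end = start + length
        if end > n:
            break
        env[start:end] = _envelope(length, origin, float(ext))
        events.append(SimEvent(kind=kind, start=start, end=end, extreme=float(ext)))
        cursor = end + 2  # >= 1 in-range sample between events
    return events, env


def _dropout_mask(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    if cfg.dropout_rate <= 0.0:
        return mask
    mean_run = max(cfg.dropout_mean_run_s / SAMPLE_INTERVAL_S, 1.0)
    n_runs = int(round(cfg.dropout_rate * n / mean_run))
    if n_runs == 0:
        return mask
    starts = rng.integers(0, n, size=n_runs)
    lengths = rng.geometric(1.0 / mean_run, size=n_runs)
    for s, ln in zip(starts, lengths):
        mask[s : min(s + ln, n)] = True
    return mask


def generate_subject(
    config: SimConfig,
    subject_index: int,
    return_events: bool = False,
) -> OxiSeries | tuple[OxiSeries, list[SimEvent]]:
    """Simulate one subject's full-study log.

    Deterministic given ``(config.seed, subject_index)``. With
    ``return_events`` the ground-truth injected events are returned
    alongside the series (useful for calibration and testing).
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ConfigError(
            f"subject_index must be in [0, {config.n_subjects}), got {subject_index}"
        )
    rng = np.random.default_rng([config.seed, subject_index])
    n = config.study_days * SAMPLES_PER_DAY
    tr = config.target_range
    m = tr.midpoint
    phi = float(np.exp(-SAMPLE_INTERVAL_S / config.controller_timeconstant))

    spo2 = m + _ar1_noise(rng, n, config.noise_sd, phi)

    # desaturations
    d_starts = _event_starts(rng, config.desat_rate, n)
    d_durs = _mixture_durations(rng, config, len(d_starts))
    dd = config.desat_depth
    depths = np.minimum(
        dd.min_below + rng.exponential(dd.mean_excess, size=len(d_starts)),
        dd.max_below,
    )
    nadirs = tr.low - depths
    desats, d_env = _place_events(d_starts, d_durs, nadirs, n, "desat", origin=m, fill=100.0)
    spo2 = np.minimum(spo2, d_env)

    # hyperoxemic drifts
    h_starts = _event_starts(rng, config.hyper_rate, n)
    h_durs = np.maximum(
        rng.lognormal(
            np.log(config.hyper_duration_median_s),
            config.hyper_duration_sigma,
            size=len(h_starts),
        ),
        10.0,
    )
    peaks = rng.uniform(min(tr.high + 2.0, 100.0), 100.0, size=len(h_starts))
    hypers, h_env = _place_events(h_starts, h_durs, peaks, n, "hyper", origin=m, fill=0.0)
    spo2 = np.maximum(spo2, h_env)

    spo2 = np.clip(np.round(spo2), 0.0, 100.0)

    # FiO2: weaning baseline + filtered proportional response to low SpO2
    base = np.linspace(config.fio2_start, config.fio2_end, n)
    err = np.maximum(m - spo2, 0.0)
    alpha = SAMPLE_INTERVAL_S / config.controller_timeconstant
    resp = signal.lfilter([alpha], [1.0, -(1.0 - alpha)], config.controller_gain * err)
    fio2 = base + resp

    # manual caregiver adjustments: flags plus a small persistent baseline step
    manual = np.zeros(n, dtype=bool)
    n_adj = rng.poisson(config.manual_adjustments_per_day * config.study_days)
    if n_adj > 0:
        idx = np.sort(rng.integers(0, n, size=n_adj))
        manual[idx] = True
        steps = rng.choice([-0.02, 0.02], size=n_adj)
        delta = np.zeros(n)
        delta[idx] += steps
        fio2 = fio2 + np.cumsum(delta)

    fio2 = np.round(np.clip(fio2, 0.21, 1.0), 2)

    invalid = _dropout_mask(rng, config, n)
    valid = ~invalid
    if invalid.any():
        held = np.where(valid, spo2, np.nan)
        spo2 = pd.Series(held).ffill().bfill().to_numpy()

    series = OxiSeries(
        subject_id=f"S{subject_index:02d}",
        spo2=spo2,
        fio2=fio2,
        valid=valid,
        manual_adjustment=manual,
    )
    if return_events:
        return series, desats + hypers
    return series


def generate_cohort(config: SimConfig) -> list[OxiSeries]:
    """All subjects' logs for the configured cohort."""
    return [generate_subject(config, i) for i in range(config.n_subjects)]
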