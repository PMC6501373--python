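"""Study configuration objects and YAML loading.

The configuration mirrors how the study is set up at the bedside: a
clinician-chosen SpO2 target range programmed into the closed-loop FiO2
controller, two alarm strategies defined as offsets around that range, a
24-hour alternation schedule, and the characteristics of the simulated
cohort (event rates, signal quality, controller behaviour).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

#: fixed logging cadence of the ventilator data logger, seconds
SAMPLE_INTERVAL_S = 5.0
#: samples in one 24-h study day at the 5-s cadence
SAMPLES_PER_DAY = int(round(24 * 3600 / SAMPLE_INTERVAL_S))  # 17,280

TIGHT = "tight"
LOOSE = "loose"
STRATEGY_LABELS = (TIGHT, LOOSE)


class ConfigError(ValueError):
    """Raised when a configuration field is out of its permitted domain."""


@dataclass(frozen=True)
class TargetRange:
    """Clinician-set SpO2 target interval for the automated controller (%)."""

    low: float = 88.0
    high: float = 95.0

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high <= 100.0):
            raise ConfigError(
                f"target_range: require 0 < low < high <= 100, got "
                f"low={self.low}, high={self.high}"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)


@dataclass(frozen=True)
class DesatDurationMix:
    """Log-normal desaturation duration with an explicit heavy tail.

    A fraction ``tail_frac`` of events is drawn from a second, longer
    log-normal so that minute-scale episodes occur at a realistic daily
    rate even though the body of the distribution is tens of seconds.
    """

    median_s: float = 25.0
    sigma: float = 0.5
    tail_frac: float = 0.02
    tail_median_s: float = 120.0
    tail_sigma: float = 0.4
    min_s: float = 10.0

    def __post_init__(self) -> None:
        if self.median_s <= 0 or self.tail_median_s <= 0 or self.min_s <= 0:
            raise ConfigError("desat_duration: medians and min_s must be positive")
        if not 0.0 <= self.tail_frac < 1.0:
            raise ConfigError(
                f"desat_duration.tail_frac must be in [0, 1), got {self.tail_frac}"
            )
        if self.sigma <= 0 or self.tail_sigma <= 0:
            raise ConfigError("desat_duration: sigma parameters must be positive")


@dataclass(frozen=True)
class DesatDepth:
    """Desaturation nadir depth below the target-range low (%).

    Depth = ``min_below`` + Exponential(``mean_excess``), clipped at
    ``max_below``: most desaturations are shallow dips just under the
    range, with an exponential tail of deep events reaching hypoxemia.
    """

    min_below: float = 2.0
    mean_excess: float = 2.5
    max_below: float = 18.0

    def __post_init__(self) -> None:
        if not 0.0 < self.min_below <= self.max_below:
            raise ConfigError(
                f"desat_depth: require 0 < min_below <= max_below, got "
                f"{self.min_below}, {self.max_below}"
            )
        if self.mean_excess <= 0:
            raise ConfigError(
                f"desat_depth.mean_excess must be > 0, got {self.mean_excess}"
            )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate intubated neonates in their first week of life under
    closed-loop FiO2 control: SpO2 mostly inside the 88-95% target range,
    a handful of brief desaturations per hour, rare hyperoxemic drifts,
    occasional signal dropout, and FiO2 weaning from ~0.33 toward room air.
    """

    n_subjects: int = 20
    study_days: int = 6
    sample_interval: float = SAMPLE_INTERVAL_S
    target_range: TargetRange = field(default_factory=TargetRange)
    desat_rate: float = 8.0           # events / hour
    desat_duration: DesatDurationMix = field(default_factory=DesatDurationMix)
    desat_depth: DesatDepth = field(default_factory=DesatDepth)
    hyper_rate: float = 0.3           # events / hour
    hyper_duration_median_s: float = 60.0
    hyper_duration_sigma: float = 0.5
    dropout_rate: float = 0.02        # fraction of invalid samples
    dropout_mean_run_s: float = 30.0
    noise_sd: float = 1.2             # stationary SD of the SpO2 AR(1) noise, %
    controller_gain: float = 0.012    # delta-FiO2 per % SpO2 error
    controller_timeconstant: float = 100.0  # s; sets AR(1) lag-1 correlation
    fio2_start: float = 0.33
    fio2_end: float = 0.25
    manual_adjustments_per_day: float = 2.0  # Poisson mean
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if self.study_days < 1:
            raise ConfigError(f"study_days must be >= 1, got {self.study_days}")
        if self.sample_interval != SAMPLE_INTERVAL_S:
            raise ConfigError(
                f"sample_interval is fixed at {SAMPLE_INTERVAL_S} s (data-logger "
                f"cadence), got {self.sample_interval}"
            )
        for name in ("desat_rate", "hyper_rate", "manual_adjustments_per_day"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError(
                f"dropout_rate must be in [0, 1), got {self.dropout_rate}"
            )
        for name in ("fio2_start", "fio2_end"):
            v = getattr(self, name)
            if not 0.21 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0.21, 1.0], got {v}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.controller_timeconstant <= 0:
            raise ConfigError(
                f"controller_timeconstant must be > 0, got "
                f"{self.controller_timeconstant}"
            )
        if self.controller_gain < 0:
            raise ConfigError(
                f"controller_gain must be >= 0, got {self.controller_gain}"
            )
        if self.dropout_mean_run_s < self.sample_interval:
            raise ConfigError(
                "dropout_mean_run_s must be at least one sample interval"
            )

    @property
    def samples_per_day(self) -> int:
        return SAMPLES_PER_DAY


@dataclass(frozen=True)
class StrategySpec:
    """Offsets (relative to the target range) and delay defining a strategy."""

    low_offset: float
    high_offset: float
    delay_s: float


#: nominal strategy definitions: tight alarms sit just outside the target
#: range with a 30-s persistence delay; loose alarms sit 2% wider with 90 s.
DEFAULT_STRATEGIES: dict[str, StrategySpec] = {
    TIGHT: StrategySpec(low_offset=-1.0, high_offset=+1.0, delay_s=30.0),
    LOOSE: StrategySpec(low_offset=-3.0, high_offset=+3.0, delay_s=90.0),
}


@dataclass(frozen=True)
class StudyConfig:
    """Full simulated-study configuration: cohort, strategies, exit rules."""

    sim: SimConfig = field(default_factory=SimConfig)
    strategies: Mapping[str, StrategySpec] = field(
        default_factory=lambda: dict(DEFAULT_STRATEGIES)
    )
    max_study_days: int = 6
    early_exit_prob: float = 0.0   # per-day probability of clinical exit
    misset_prob: float = 0.0       # per-day probability of mis-set alarms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_study_days < 1:
            raise ConfigError(
                f"max_study_days must be >= 1, got {self.max_study_days}"
            )
        for name in ("early_exit_prob", "misset_prob"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigError(f"{name} must be in [0, 1), got {v}")
        for label in STRATEGY_LABELS:
            if label not in self.strategies:
                raise ConfigError(f"strategies must define '{label}'")


# ---------------------------------------------------------------------------
# YAML round-trip


def _sim_from_mapping(d: Mapping[str, Any]) -> SimConfig:
    d = dict(d)
    if "target_range" in d and isinstance(d["target_range"], Mapping):
        d["target_range"] = TargetRange(**d["target_range"])
    if "desat_duration" in d and isinstance(d["desat_duration"], Mapping):
        d["desat_duration"] = DesatDurationMix(**d["desat_duration"])
    if "desat_depth" in d and isinstance(d["desat_depth"], Mapping):
        d["desat_depth"] = DesatDepth(**d["desat_depth"])
    try:
        return SimConfig(**d)
    except TypeError as exc:  # unknown field name
        raise ConfigError(str(exc)) from exc


def load_sim_config(path: str | Path) -> SimConfig:
    """Load a :class:`SimConfig` from YAML mirroring the field names."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return _sim_from_mapping(raw)


def load_study_config(path: str | Path) -> StudyConfig:
    """Load a :class:`StudyConfig`; ``sim:`` and ``strategies:`` blocks nest."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    d = dict(raw)
    if "sim" in d and isinstance(d["sim"], Mapping):
        d["sim"] = _sim_from_mapping(d["sim"])
    if "strategies" in d and isinstance(d["strategies"], Mapping):
        d["strategies"] = {
            name: StrategySpec(**spec) for name, spec in d["strategies"].items()
        }
    try:
        return StudyConfig(**d)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def dump_study_config(config: StudyConfig, path: str | Path) -> None:
    """Write a StudyConfig back to YAML (field names preserved)."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)
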