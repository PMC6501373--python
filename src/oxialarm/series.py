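"""Uniformly sampled SpO2/FiO2 log for one subject.

The data logger records SpO2 (%), FiO2 (fraction) and a validity flag
every 5 s. Samples flagged invalid (probe dropout, poor signal) are kept
on the grid so the series has no gaps; they carry the last valid SpO2
value internally but are excluded from every metric and alarm
computation. On disk the SpO2 field of an invalid sample is left empty.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SAMPLE_INTERVAL_S, SAMPLES_PER_DAY

#: half-width of the tolerance used when comparing FiO2 against room air
ROOM_AIR_TOL = 0.005

CSV_COLUMNS = ["timestamp_s", "spo2", "fio2", "valid", "manual_adjustment"]


class DataError(ValueError):
    """Raised for structurally invalid series (non-uniform grid, bad values)."""


def on_room_air(fio2: np.ndarray | float) -> np.ndarray | bool:
    """True where FiO2 equals 0.21 within the representation tolerance."""
    return np.abs(np.asarray(fio2) - 0.21) <= ROOM_AIR_TOL


def on_supplemental_o2(fio2: np.ndarray | float) -> np.ndarray | bool:
    """True where FiO2 exceeds 0.21 beyond the representation tolerance."""
    return np.asarray(fio2) > 0.21 + ROOM_AIR_TOL


@dataclass
class OxiSeries:
    """One subject's log on the uniform 5-s grid.

    Parameters
    ----------
    subject_id
        Cohort identifier, e.g. ``"S03"``.
    spo2
        Oxygen saturation per sample, %. Integer-valued (device
        resolution) but stored as float. Invalid samples hold the last
        valid reading.
    fio2
        Inspired-oxygen fraction per sample, in [0.21, 1.0].
    valid
        Sample validity flags.
    manual_adjustment
        True at samples where a caregiver changed the FiO2 baseline.
    start_time
        Offset of the first sample from the study clock origin, seconds.
    """

    subject_id: str
    spo2: np.ndarray
    fio2: np.ndarray
    valid: np.ndarray
    manual_adjustment: np.ndarray = None  # type: ignore[assignment]
    start_time: float = 0.0
    sample_interval: float = field(default=SAMPLE_INTERVAL_S)

    def __post_init__(self) -> None:
        self.spo2 = np.asarray(self.spo2, dtype=float)
        self.fio2 = np.asarray(self.fio2, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.manual_adjustment is None:
            self.manual_adjustment = np.zeros(self.spo2.shape, dtype=bool)
        self.manual_adjustment = np.asarray(self.manual_adjustment, dtype=bool)
        n = len(self.spo2)
        if n == 0:
            raise DataError("series must contain at least one sample")
        for name in ("fio2", "valid", "manual_adjustment"):
            if len(getattr(self, name)) != n:
                raise DataError(f"column '{name}' length differs from spo2")
        if self.sample_interval != SAMPLE_INTERVAL_S:
            raise DataError(
                f"series must be on the {SAMPLE_INTERVAL_S}-s grid, "
                f"got {self.sample_interval}"
            )
        v = self.valid
        sp = self.spo2[v]
        if sp.size and (np.nanmin(sp) < 0 or np.nanmax(sp) > 100):
            raise DataError("valid SpO2 samples must lie in [0, 100]")
        if np.nanmin(self.fio2) < 0.21 - ROOM_AIR_TOL or np.nanmax(self.fio2) > 1.0:
            raise DataError("FiO2 must lie in [0.21, 1.0]")

    # -- basic geometry ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.spo2)

    @property
    def n_samples(self) -> int:
        return len(self.spo2)

    @property
    def duration_s(self) -> float:
        return len(self) * self.sample_interval

    @property
    def duration_days(self) -> float:
        return self.duration_s / 86400.0

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def valid_hours(self) -> float:
        return self.n_valid * self.sample_interval / 3600.0

    @property
    def timestamps_s(self) -> np.ndarray:
        return self.start_time + self.sample_interval * np.arange(len(self))

    def day_slice(self, day: int) -> "OxiSeries":
        """Samples of 24-h block ``day`` (0-based) as a new series."""
        a, b = day * SAMPLES_PER_DAY, (day + 1) * SAMPLES_PER_DAY
        if a >= len(self):
            raise DataError(f"day {day} out of range for {self.duration_days:.2f}-day series")
        return self.islice(a, min(b, len(self)))

    def islice(self, a: int, b: int) -> "OxiSeries":
        return OxiSeries(
            subject_id=self.subject_id,
            spo2=self.spo2[a:b],
            fio2=self.fio2[a:b],
            valid=self.valid[a:b],
            manual_adjustment=self.manual_adjustment[a:b],
            start_time=self.start_time + a * self.sample_interval,
        )

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-form frame in the on-disk column layout."""
        spo2 = self.spo2.copy()
        spo2[~self.valid] = np.nan  # written as empty field
        return pd.DataFrame(
            {
                "timestamp_s": self.timestamps_s,
                "spo2": spo2,
                "fio2": self.fio2,
                "valid": self.valid.astype(int),
                "manual_adjustment": self.manual_adjustment.astype(int),
            }
        )

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase, subject_id: str | None = None) -> "OxiSeries":
        """Read a per-subject log; forward-fills SpO2 across invalid samples."""
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"log is missing columns: {missing}")
        ts = df["timestamp_s"].to_numpy(dtype=float)
        if len(ts) > 1:
            steps = np.diff(ts)
            if not np.allclose(steps, SAMPLE_INTERVAL_S, atol=1e-6):
                raise DataError("timestamps are not on a uniform 5-s grid")
        valid = df["valid"].to_numpy(dtype=bool)
        spo2 = df["spo2"].to_numpy(dtype=float)
        # hold last valid value through dropouts; leading invalids fall back
        spo2 = pd.Series(spo2).ffill().bfill().to_numpy()
        if np.isnan(spo2).any():
            raise DataError("log contains no valid SpO2 sample")
        if subject_id is None:
            subject_id = str(Path(path).stem) if isinstance(path, (str, Path)) else "unknown"
        return cls(
            subject_id=subject_id,
            spo2=spo2,
            fio2=df["fio2"].to_numpy(dtype=float),
            valid=valid,
            manual_adjustment=df["manual_adjustment"].to_numpy(dtype=bool),
            start_time=float(ts[0]) if len(ts) else 0.0,
        )
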