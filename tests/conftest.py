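import numpy as np
import pytest

from oxialarm import OxiSeries, SimConfig, TargetRange


def make_series(
    spo2,
    fio2=0.30,
    valid=None,
    manual=None,
    subject_id="T00",
) -> OxiSeries:
    """Build a short series from plain lists; scalar fio2 is broadcast."""
    spo2 = np.asarray(spo2, dtype=float)
    n = len(spo2)
    fio2 = np.full(n, fio2, dtype=float) if np.isscalar(fio2) else np.asarray(fio2, dtype=float)
    valid = np.ones(n, dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    return OxiSeries(
        subject_id=subject_id,
        spo2=spo2,
        fio2=fio2,
        valid=valid,
        manual_adjustment=manual,
    )


def random_series(rng: np.random.Generator, n: int | None = None) -> OxiSeries:
    """Short random series exercising thresholds, dropouts and room air."""
    if n is None:
        n = int(rng.integers(40, 240))
    spo2 = np.clip(np.round(rng.normal(91, 6, size=n)), 60, 100)
    fio2 = np.round(rng.choice([0.21, 0.25, 0.40], size=n, p=[0.2, 0.4, 0.4]), 2)
    valid = rng.random(n) > 0.1
    if not valid.any():
        valid[0] = True
    return make_series(spo2, fio2=fio2, valid=valid)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


@pytest.fixture
def target() -> TargetRange:
    return TargetRange()


@pytest.fixture
def quiet_config() -> SimConfig:
    """No events, no noise, no dropout: every sample sits in the range."""
    return SimConfig(
        n_subjects=1,
        study_days=1,
        desat_rate=0.0,
        hyper_rate=0.0,
        dropout_rate=0.0,
        noise_sd=0.0,
        manual_adjustments_per_day=0.0,
        seed=11,
    )
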