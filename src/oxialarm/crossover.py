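"""Paired crossover analysis: signed-rank tests, Hodges-Lehmann CIs, power.

Each subject experiences both alarm strategies in alternating 24-h
blocks, so the unit of analysis is the within-subject difference of a
pooled outcome (tight minus loose). The module provides

* :func:`wilcoxon_signed_rank` / :func:`paired_t` — the paired tests,
  with the classic either/or selection made explicit by a Shapiro-Wilk
  normality check on the differences;
* :func:`hl_median_difference_ci` — the Hodges-Lehmann estimate (median
  of the Walsh averages) with the distribution-free confidence interval
  from signed-rank critical values;
* :func:`power_simulation` — Monte-Carlo power of the paired design for
  a given mean percent change and within-subject SD, with a
  noncentral-t closed form as analytic companion;
* :class:`PairedCrossover` — a model object built from per-subject
  pooled outcomes whose :meth:`~PairedCrossover.fit` returns a
  :class:`PairedCrossoverResults` with estimates, intervals and a
  ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import LOOSE, TIGHT

__all__ = [
    "PairedComparison",
    "PairedCrossover",
    "PairedCrossoverResults",
    "PowerResult",
    "compare_paired",
    "hl_median_difference_ci",
    "paired_t",
    "percent_reduction",
    "power_paired_t_analytic",
    "power_simulation",
    "signed_rank_cdf",
    "walsh_averages",
    "wilcoxon_signed_rank",
]

EXACT_N_MAX = 25  # exact signed-rank distribution up to here, normal approx beyond


def percent_reduction(baseline: float, value: float) -> float:
    """Percent reduction of ``value`` relative to ``baseline``.

    E.g. median alarm rates of 5.2/h (tight) and 1.6/h (loose) give a
    69% reduction.
    """
    if baseline == 0:
        raise ZeroDivisionError("baseline must be nonzero")
    return 100.0 * (baseline - value) / baseline


# ---------------------------------------------------------------------------
# paired tests


def _clean_diffs(diffs: Sequence[float]) -> np.ndarray:
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1 or len(d) == 0:
        raise ValueError("differences must be a non-empty 1-d sequence")
    if np.isnan(d).any():
        raise ValueError("differences contain NaN; exclude incomplete pairs first")
    return d


def wilcoxon_signed_rank(
    diffs: Sequence[float], zero_method: str = "wilcox"
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Exact null distribution when n <= 25 with no ties among the nonzero
    absolute differences; otherwise the normal approximation with
    continuity and tie correction. Zero differences are dropped
    (``zero_method='wilcox'``, the classic convention) or kept per Pratt
    (``'pratt'``). A degenerate all-zero input returns ``(0.0, 1.0)``
    with a warning.
    """
    d = _clean_diffs(diffs)
    nonzero = d[d != 0]
    if len(nonzero) == 0:
        warnings.warn("all paired differences are zero; test is degenerate, p = 1")
        return 0.0, 1.0
    effective = nonzero if zero_method == "wilcox" else d
    n = len(effective)
    has_ties = len(np.unique(np.abs(effective))) < n
    method = "exact" if (n <= EXACT_N_MAX and not has_ties and zero_method == "wilcox") else "approx"
    res = stats.wilcoxon(
        d,
        zero_method=zero_method,
        correction=(method == "approx"),
        alternative="two-sided",
        method=method,
    )
    return float(res.statistic), float(res.pvalue)


def paired_t(diffs: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t test (one-sample t on the differences)."""
    d = _clean_diffs(diffs)
    if len(d) < 2:
        raise ValueError("paired t requires at least 2 differences")
    res = stats.ttest_1samp(d, 0.0)
    return float(res.statistic), float(res.pvalue)


def choose_test(diffs: Sequence[float], alpha: float = 0.05) -> str:
    """'t' if Shapiro-Wilk does not reject normality of the differences.

    This makes the conventional "paired t or Wilcoxon, as appropriate"
    rule explicit. Degenerate inputs (n < 3, constant differences) fall
    back to the rank test, which remains well defined there.
    """
    d = _clean_diffs(diffs)
    if len(d) < 3 or np.ptp(d) == 0:
        return "wilcoxon"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.shapiro(d)
    return "t" if p >= alpha else "wilcoxon"


# ---------------------------------------------------------------------------
# Hodges-Lehmann estimate and distribution-free CI


def walsh_averages(diffs: Sequence[float]) -> np.ndarray:
    """The n(n+1)/2 pairwise means (d_i + d_j)/2, i <= j, sorted."""
    d = _clean_diffs(diffs)
    i, j = np.triu_indices(len(d))
    return np.sort((d[i] + d[j]) / 2.0)


@lru_cache(maxsize=128)
def signed_rank_cdf(n: int) -> np.ndarray:
    """P(T <= t) of the null signed-rank statistic, t = 0 .. n(n+1)/2.

    Computed by the subset-sum recursion over ranks 1..n (each rank is
    positive or negative with probability 1/2 under the null).
    """
    m = n * (n + 1) // 2
    f = np.zeros(m + 1)
    f[0] = 1.0
    for r in range(1, n + 1):
        g = f.copy()
        g[r:] += f[:-r]
        f = g
    return np.cumsum(f) / 2.0**n


def _signed_rank_critical(n: int, alpha_half: float) -> int:
    """Largest c with P(T <= c) <= alpha/2; -1 if even c = 0 exceeds it."""
    if n <= EXACT_N_MAX:
        cdf = signed_rank_cdf(n)
        idx = np.searchsorted(cdf, alpha_half, side="right") - 1
        return int(idx)
    mu = n * (n + 1) / 4.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = stats.norm.ppf(alpha_half)
    c = int(np.floor(mu + z * sigma))
    return max(c, -1)


def hl_median_difference_ci(
    diffs: Sequence[float], level: float = 0.95
) -> tuple[float, float, float]:
    """Hodges-Lehmann estimate and distribution-free CI for the median difference.

    The estimate is the median of the Walsh averages; the interval
    takes the (C+1)-th smallest and largest Walsh averages, where C is
    the signed-rank critical value at (1-level)/2 — exact for n <= 25,
    normal approximation beyond. The achieved coverage is the smallest
    attainable level >= the requested one (the interval is slightly
    conservative), and degenerates to the full Walsh-average range when
    n is too small for the requested level.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    d = _clean_diffs(diffs)
    w = walsh_averages(d)
    est = float(np.median(w))
    n = len(d)
    m = len(w)
    c = _signed_rank_critical(n, (1.0 - level) / 2.0)
    if c < 0:
        lo_idx, hi_idx = 0, m - 1
    else:
        lo_idx, hi_idx = c, m - 1 - c
    if lo_idx > hi_idx:  # pathological tiny n
        lo_idx, hi_idx = 0, m - 1
    return est, float(w[lo_idx]), float(w[hi_idx])


# ---------------------------------------------------------------------------
# power


@dataclass(frozen=True)
class PowerResult:
    """Monte-Carlo power estimate with its binomial standard error."""

    power: float
    se: float
    reps: int
    n: int
    test: str

    def __str__(self) -> str:
        return f"power = {self.power:.3f} (MC SE {self.se:.4f}, {self.reps} reps, n={self.n}, {self.test})"


def power_simulation(
    effect_pct: float,
    sd_pct: float,
    n: int,
    alpha: float = 0.05,
    reps: int = 10_000,
    seed: int | None = None,
    test: str = "t",
) -> PowerResult:
    """Monte-Carlo power of the two-sided paired test.

    Draws ``n`` within-subject percent-change values from
    Normal(effect_pct, sd_pct^2) per replicate, applies the two-sided
    paired test of zero mean change at ``alpha``, and reports the
    rejection fraction. ``test='t'`` is fully vectorized;
    ``test='wilcoxon'`` loops over replicates.
    """
    if n < 2:
        raise ValueError("power simulation needs n >= 2 subjects")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    if test == "t":
        draws = rng.normal(effect_pct, sd_pct, size=(reps, n))
        mean = draws.mean(axis=1)
        sd = draws.std(axis=1, ddof=1)
        tstat = mean / (sd / np.sqrt(n))
        crit = stats.t.ppf(1.0 - alpha / 2.0, n - 1)
        rejections = int((np.abs(tstat) > crit).sum())
    elif test == "wilcoxon":
        rejections = 0
        for _ in range(reps):
            d = rng.normal(effect_pct, sd_pct, size=n)
            _, p = wilcoxon_signed_rank(d)
            rejections += p < alpha
    else:
        raise ValueError(f"unknown test {test!r}; expected 't' or 'wilcoxon'")
    p_hat = rejections / reps
    se = float(np.sqrt(p_hat * (1.0 - p_hat) / reps))
    return PowerResult(power=p_hat, se=se, reps=reps, n=n, test=test)


def power_paired_t_analytic(
    effect_pct: float, sd_pct: float, n: int, alpha: float = 0.05
) -> float:
    """Closed-form power of the two-sided paired t via the noncentral t."""
    if n < 2:
        raise ValueError("need n >= 2")
    nc = effect_pct / sd_pct * np.sqrt(n)
    df = n - 1
    crit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(1.0 - stats.nct.cdf(crit, df, nc) + stats.nct.cdf(-crit, df, nc))


# ---------------------------------------------------------------------------
# model / results


@dataclass(frozen=True)
class PairedComparison:
    """One metric's paired contrast (tight minus loose)."""

    metric: str
    n: int
    statistic: float
    p_value: float
    hl_estimate: float
    ci_low: float
    ci_high: float
    test_used: str
    level: float = 0.95

    def __post_init__(self) -> None:
        if not self.ci_low <= self.hl_estimate <= self.ci_high:
            raise ValueError(
                f"{self.metric}: HL estimate {self.hl_estimate} outside "
                f"CI [{self.ci_low}, {self.ci_high}]"
            )
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError(f"{self.metric}: p-value {self.p_value} outside (0, 1]")


def compare_paired(
    tight: Sequence[float],
    loose: Sequence[float],
    metric: str = "metric",
    test: str = "auto",
    level: float = 0.95,
) -> PairedComparison:
    """Paired contrast of one metric; difference = tight - loose."""
    a = np.asarray(tight, dtype=float)
    b = np.asarray(loose, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tight and loose must have equal length (paired)")
    d = a - b
    if test == "auto":
        test = choose_test(d)
    if test == "t" and np.ptp(d) == 0:
        test = "wilcoxon"  # t undefined for constant differences
    if test == "t":
        statistic, p = paired_t(d)
    elif test == "wilcoxon":
        statistic, p = wilcoxon_signed_rank(d)
    else:
        raise ValueError(f"unknown test {test!r}")
    est, lo, hi = hl_median_difference_ci(d, level=level)
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return PairedComparison(
        metric=metric,
        n=len(d),
        statistic=statistic,
        p_value=p,
        hl_estimate=est,
        ci_low=lo,
        ci_high=hi,
        test_used=test,
        level=level,
    )


def _median_iqr(x: np.ndarray) -> str:
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.1f} ({q1:.1f}-{q3:.1f})"


class PairedCrossover:
    """Paired crossover model over per-subject pooled outcomes.

    Parameters
    ----------
    data
        Mapping ``metric -> (tight values, loose values)``, aligned by
        subject. Use :meth:`from_dataframe` to build it from a long
        table of per-subject, per-strategy pooled summaries; subjects
        missing either strategy are dropped there.
    """

    def __init__(self, data: Mapping[str, tuple[np.ndarray, np.ndarray]]):
        if not data:
            raise ValueError("no metrics to compare")
        self.data = {
            m: (np.asarray(a, dtype=float), np.asarray(b, dtype=float))
            for m, (a, b) in data.items()
        }
        for m, (a, b) in self.data.items():
            if a.shape != b.shape or a.ndim != 1:
                raise ValueError(f"metric {m!r}: arms must be equal-length 1-d arrays")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        subject_col: str = "subject_id",
        strategy_col: str = "strategy",
        metrics: Sequence[str] | None = None,
    ) -> "PairedCrossover":
        """Build from a long frame with one row per subject x strategy.

        Rows with either arm missing (or NaN for a metric) exclude that
        subject from that metric's pairing.
        """
        if metrics is None:
            metrics = [
                c
                for c in df.columns
                if c not in (subject_col, strategy_col)
                and pd.api.types.is_numeric_dtype(df[c])
            ]
        data = {}
        for m in metrics:
            wide = df.pivot_table(
                index=subject_col, columns=strategy_col, values=m, aggfunc="first"
            )
            if TIGHT not in wide.columns or LOOSE not in wide.columns:
                continue
            wide = wide.dropna(subset=[TIGHT, LOOSE])
            if len(wide) == 0:
                continue
            data[m] = (wide[TIGHT].to_numpy(), wide[LOOSE].to_numpy())
        return cls(data)

    def fit(self, test: str = "auto", level: float = 0.95) -> "PairedCrossoverResults":
        comparisons = {
            m: compare_paired(a, b, metric=m, test=test, level=level)
            for m, (a, b) in self.data.items()
        }
        return PairedCrossoverResults(self, comparisons, level=level)


class PairedCrossoverResults:
    """Fitted paired contrasts for every metric, with a summary table."""

    def __init__(
        self,
        model: PairedCrossover,
        comparisons: Mapping[str, PairedComparison],
        level: float = 0.95,
    ):
        self.model = model
        self.comparisons = dict(comparisons)
        self.level = level

    def __getitem__(self, metric: str) -> PairedComparison:
        return self.comparisons[metric]

    def to_frame(self) -> pd.DataFrame:
        """One row per metric: arm medians (IQR), test, p, HL difference CI."""
        rows = []
        for m, c in self.comparisons.items():
            a, b = self.model.data[m]
            rows.append(
                {
                    "metric": m,
                    "n": c.n,
                    "loose_median_iqr": _median_iqr(b),
                    "tight_median_iqr": _median_iqr(a),
                    "test": c.test_used,
                    "statistic": c.statistic,
                    "p_value": c.p_value,
                    "hl_diff_tight_minus_loose": c.hl_estimate,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text outcome table in the usual crossover-report layout."""
        df = self.to_frame()
        lines = [
            "Paired crossover analysis (difference = tight - loose, "
            f"{self.level:.0%} Hodges-Lehmann CI)",
            "=" * 78,
        ]
        for _, r in df.iterrows():
            lines.append(
                f"{r['metric']:<34} n={r['n']:>3}  "
                f"loose {r['loose_median_iqr']:>18}  tight {r['tight_median_iqr']:>18}"
            )
            p = r["p_value"]
            p_str = "<0.001" if p < 0.001 else f"{p:.3f}"
            lines.append(
                f"{'':<34} {r['test']:<9} p={p_str:<7} "
                f"HL diff {r['hl_diff_tight_minus_loose']:+.3f} "
                f"[{r['ci_low']:+.3f}, {r['ci_high']:+.3f}]"
            )
        return "\n".join(lines)
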