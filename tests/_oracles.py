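"""Independent brute-force oracles.

Deliberately naive per-sample / full-enumeration implementations used
only to cross-check the package's vectorized or closed-form routines.
"""

from __future__ import annotations

from itertools import product

import numpy as np

SAMPLE_S = 5.0


def naive_alarm_scan(
    spo2: np.ndarray,
    valid: np.ndarray,
    low: float,
    high: float,
    delay_s: float,
    invalid_resets: bool = False,
) -> list[tuple[str, int, int]]:
    """Per-sample state machine for one strategy; returns (kind, start, end)."""
    out = []
    d_req = max(int(delay_s / SAMPLE_S), 1)
    for kind in ("low", "high"):
        count = 0
        active_start = None
        for i in range(len(spo2)):
            if not valid[i]:
                if invalid_resets:
                    count = 0
                continue  # timer pauses; active alarm keeps sounding
            viol = spo2[i] < low if kind == "low" else spo2[i] > high
            if viol:
                if active_start is None:
                    count += 1
                    if count >= d_req:
                        active_start = i
            else:
                if active_start is not None:
                    out.append((kind, active_start, i))
                    active_start = None
                count = 0
        if active_start is not None:
            out.append((kind, active_start, len(spo2)))
    out.sort(key=lambda e: (e[1], e[0]))
    return out


def naive_episodes(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, by linear scan."""
    out = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def wilcoxon_exact_enum(diffs) -> tuple[float, float]:
    """Two-sided exact signed-rank p by enumerating all sign assignments."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = _rank(np.abs(d))
    t_obs = float(ranks[d > 0].sum())
    ts = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in product([0, 1], repeat=n)]
    )
    p_le = np.mean(ts <= t_obs)
    p_ge = np.mean(ts >= t_obs)
    return t_obs, float(min(1.0, 2.0 * min(p_le, p_ge)))


def _rank(x: np.ndarray) -> np.ndarray:
    """Average ranks, 1-based (ties shared)."""
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    sorted_x = x[order]
    i = 0
    while i < len(x):
        j = i
        while j < len(x) and sorted_x[j] == sorted_x[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0  # mean of 1-based ranks i+1..j
        i = j
    return ranks


def signed_rank_cdf_enum(n: int) -> np.ndarray:
    """Null CDF of the signed-rank statistic by explicit subset enumeration."""
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1)
    for signs in product([0, 1], repeat=n):
        counts[sum(r for r, s in zip(range(1, n + 1), signs) if s)] += 1
    return np.cumsum(counts) / 2.0**n


def hl_interval_enum(diffs, level: float = 0.95) -> tuple[float, float, float]:
    """HL estimate and CI from enumerated Walsh averages and the enumerated
    signed-rank distribution (order-statistic construction)."""
    d = np.asarray(diffs, dtype=float)
    n = len(d)
    walsh = sorted(
        (d[i] + d[j]) / 2.0 for i in range(n) for j in range(i, n)
    )
    walsh = np.asarray(walsh)
    est = float(np.median(walsh))
    cdf = signed_rank_cdf_enum(n)
    alpha_half = (1.0 - level) / 2.0
    c = -1
    for t in range(len(cdf)):
        if cdf[t] <= alpha_half:
            c = t
        else:
            break
    m = len(walsh)
    if c < 0:
        return est, float(walsh[0]), float(walsh[-1])
    return est, float(walsh[c]), float(walsh[m - 1 - c])
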