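"""Figure analogues of the study's descriptive plots.

matplotlib is imported lazily; the rest of the package works without it.
"""

from __future__ import annotations

import pandas as pd


def _ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_cohort_histogram(fig1: pd.DataFrame, ax=None):
    """Median SpO2 histogram with IQR whiskers (supplemental-oxygen time)."""
    ax = _ax(ax)
    err = [
        fig1["median_pct"] - fig1["q1_pct"],
        fig1["q3_pct"] - fig1["median_pct"],
    ]
    ax.bar(fig1["bin"], fig1["median_pct"], yerr=err, capsize=2, color="0.6")
    ax.set_xlabel("SpO2 (%)")
    ax.set_ylabel("time (%) when FiO2 > 0.21")
    return ax


def plot_alarm_rate_distribution(fig2: pd.DataFrame, ax=None):
    """Histogram of daily SpO2-alarm rates, one distribution per strategy."""
    ax = _ax(ax)
    for label, sub in fig2.groupby("strategy"):
        ax.hist(sub["alarm_rate_per_h"], bins=15, alpha=0.6, label=label)
    ax.set_xlabel("SpO2 alarms (#/hour)")
    ax.set_ylabel("study days")
    ax.legend()
    return ax
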