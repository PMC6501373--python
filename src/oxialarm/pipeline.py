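"""End-to-end simulated study: generate -> schedule -> alarms -> metrics
-> paired analysis -> report.

The orchestration mirrors how the clinical dataset was produced and
screened: subjects are randomized to a first-day strategy in balanced
blocks of four, strategies alternate every 24 h for up to six days,
days whose recorded alarm settings differ from the assigned strategy
are excluded as protocol violations, subjects with fewer than two
analyzed days are excluded, and per-subject outcomes are pooled over
all days under each strategy before the paired analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alarms import AlarmStrategy, detect_alarms, events_to_frame, strategy_from_target
from .config import LOOSE, STRATEGY_LABELS, TIGHT, StudyConfig
from .crossover import PairedCrossover, PairedCrossoverResults
from .metrics import ExposureAccumulator, summarize_day
from .series import OxiSeries
from .synthetic import assign_first_day, build_schedule, generate_subject

logger = logging.getLogger("oxialarm")

#: outcomes entering the paired analysis (Table-4-analogue)
OUTCOME_METRICS = [
    "alarm_rate_per_h",
    "audible_pct",
    "pct_hypoxemia",
    "hypox_episodes_gt1min_per24h",
    "hypox_episodes_gt3min_per24h",
    "pct_hyperoxemia",
    "hyper_episodes_gt1min_per24h",
    "hyper_episodes_gt3min_per24h",
]

#: settings-and-course metrics (Table-3-analogue)
COURSE_METRICS = [
    "mean_of_hourly_median_spo2",
    "mean_of_hourly_median_fio2",
    "pct_in_86_96_suppl_o2",
    "pct_normoxemia",
    "manual_adjustments_per_day",
]

REASON_VIOLATION = "alarm settings inconsistent with assigned strategy"
REASON_TOO_FEW_DAYS = "did not complete two analyzed days"
REASON_ONE_ARM = "no analyzed day under one strategy"


def screen_violations(
    applied: AlarmStrategy, assigned: AlarmStrategy
) -> tuple[bool, str | None]:
    """Keep a day only if its recorded settings match the assigned strategy."""
    same = (
        applied.low_alarm == assigned.low_alarm
        and applied.high_alarm == assigned.high_alarm
        and applied.delay_s == assigned.delay_s
    )
    return (True, None) if same else (False, REASON_VIOLATION)


def day_accounting(
    analyzed_by_strategy: Mapping[str, int],
    excluded_violation_days: int = 0,
    not_completed_days: int = 0,
) -> dict:
    """Study-day bookkeeping with the assigned = analyzed + excluded identity."""
    analyzed_total = int(sum(analyzed_by_strategy.values()))
    return {
        "analyzed_days_by_strategy": dict(analyzed_by_strategy),
        "analyzed_days_total": analyzed_total,
        "excluded_violation_days": int(excluded_violation_days),
        "not_completed_days": int(not_completed_days),
        "assigned_days_total": analyzed_total
        + int(excluded_violation_days)
        + int(not_completed_days),
    }


def cohort_histogram(histograms: Sequence[Mapping[int, float]]) -> pd.DataFrame:
    """Per-bin median and IQR of subjects' SpO2 histograms.

    A subject contributes 0% to any bin absent from its histogram, so
    the quartiles are taken over the full cohort at every bin.
    """
    hists = [h for h in histograms if h]
    if not hists:
        return pd.DataFrame(columns=["bin", "median_pct", "q1_pct", "q3_pct"])
    bins = sorted({b for h in hists for b in h})
    rows = []
    for b in bins:
        vals = np.array([h.get(b, 0.0) for h in hists])
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append({"bin": b, "median_pct": med, "q1_pct": q1, "q3_pct": q3})
    return pd.DataFrame(rows)


@dataclass
class StudyReport:
    """Everything the simulated study produces, ready to write to disk."""

    config: StudyConfig
    roster: pd.DataFrame
    day_summaries: pd.DataFrame
    pooled_summaries: pd.DataFrame
    results: PairedCrossoverResults | None
    table3: pd.DataFrame
    table4: pd.DataFrame
    fig1_histogram: pd.DataFrame
    fig2_alarm_rates: pd.DataFrame
    accounting: dict
    alarm_events: pd.DataFrame

    def save(self, outdir: str | Path, fmt: str = "csv") -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "roster": self.roster,
            "day_summaries": self.day_summaries,
            "pooled_summaries": self.pooled_summaries,
            "table3_course": self.table3,
            "table4_outcomes": self.table4,
            "fig1_histogram": self.fig1_histogram,
            "fig2_alarm_rates": self.fig2_alarm_rates,
            "alarm_events": self.alarm_events,
        }
        for name, df in tables.items():
            if fmt == "json":
                df.to_json(out / f"{name}.json", orient="records", indent=1)
            else:
                df.to_csv(out / f"{name}.csv", index=False)
        with open(out / "accounting.json", "w") as fh:
            json.dump(self.accounting, fh, indent=1)
        if self.results is not None:
            (out / "summary.txt").write_text(self.results.summary() + "\n")


def _config_hash(config: StudyConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _round_tables(df: pd.DataFrame) -> pd.DataFrame:
    """Display rounding for rendered tables (rates/percentages to 0.1)."""
    out = df.copy()
    for c in out.columns:
        if pd.api.types.is_float_dtype(out[c]):
            out[c] = out[c].round(1)
    return out


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full simulated crossover study; deterministic given the seed."""
    sim = config.sim
    logger.info(
        "run_study: seed=%d config=%s subjects=%d", config.seed, _config_hash(config), sim.n_subjects
    )
    n_days_full = min(sim.study_days, config.max_study_days)
    first = assign_first_day(sim.n_subjects, config.seed)
    target = sim.target_range
    strategies = {
        label: strategy_from_target(target, label, config.strategies[label])
        for label in STRATEGY_LABELS
    }

    day_rows: list[dict] = []
    event_frames: list[pd.DataFrame] = []
    roster_rows: list[dict] = []
    kept_days: dict[str, dict[str, list[tuple[OxiSeries, list]]]] = {}
    excluded_violation_days = 0
    not_completed_days = 0

    for i in range(sim.n_subjects):
        rng = np.random.default_rng([config.seed, 0x5D, i])
        schedule = build_schedule(first[i], n_days_full)
        series = generate_subject(sim, i)
        subject_id = series.subject_id

        days_completed = n_days_full
        if config.early_exit_prob > 0.0:
            for d in range(1, n_days_full):
                if rng.random() < config.early_exit_prob:
                    days_completed = d
                    break
        not_completed_days += n_days_full - days_completed

        kept_days[subject_id] = {TIGHT: [], LOOSE: []}
        for d in range(days_completed):
            day_series = series.day_slice(d)
            label = schedule.label_for_day(d)
            assigned = strategies[label]
            applied = assigned
            if config.misset_prob > 0.0 and rng.random() < config.misset_prob:
                shift = float(rng.choice([-2.0, -1.0, 1.0, 2.0]))
                applied = dataclasses.replace(assigned, low_alarm=assigned.low_alarm + shift)
            events = detect_alarms(day_series, applied)
            keep, reason = screen_violations(applied, assigned)
            summ = summarize_day(day_series, events)
            day_rows.append(
                {
                    "subject_id": subject_id,
                    "day": d,
                    "strategy": label,
                    "applied_low": applied.low_alarm,
                    "applied_high": applied.high_alarm,
                    "applied_delay_s": applied.delay_s,
                    "analyzed": keep,
                    "exclusion_reason": reason,
                    **summ.to_dict(),
                }
            )
            event_frames.append(events_to_frame(events, subject_id, d))
            if keep:
                kept_days[subject_id][label].append((day_series, events))
            else:
                excluded_violation_days += 1

        roster_rows.append(
            {
                "subject_id": subject_id,
                "first_day_strategy": first[i],
                "days_completed": days_completed,
                "days_analyzed": sum(len(v) for v in kept_days[subject_id].values()),
            }
        )

    # subject screening and per-strategy pooling
    pooled_rows: list[dict] = []
    subject_exclusions: dict[str, str] = {}
    subject_histograms: list[dict[int, float]] = []
    analyzed_by_strategy = {TIGHT: 0, LOOSE: 0}
    for subject_id, by_label in kept_days.items():
        n_analyzed = sum(len(v) for v in by_label.values())
        if n_analyzed < 2:
            subject_exclusions[subject_id] = REASON_TOO_FEW_DAYS
            continue
        if not by_label[TIGHT] or not by_label[LOOSE]:
            subject_exclusions[subject_id] = REASON_ONE_ARM
            continue
        whole = ExposureAccumulator()
        for label in STRATEGY_LABELS:
            acc = ExposureAccumulator()
            for day_series, events in by_label[label]:
                acc.add_day(day_series, events)
                whole.add_day(day_series, events)
            analyzed_by_strategy[label] += len(by_label[label])
            summ = acc.summary()
            pooled_rows.append(
                {
                    "subject_id": subject_id,
                    "strategy": label,
                    "n_days": len(by_label[label]),
                    **summ.to_dict(),
                }
            )
        subject_histograms.append(whole.summary().spo2_histogram)

    day_summaries = pd.DataFrame(day_rows)
    pooled_summaries = pd.DataFrame(pooled_rows)
    roster = pd.DataFrame(roster_rows)
    roster["excluded"] = roster["subject_id"].map(subject_exclusions).fillna("")

    results: PairedCrossoverResults | None = None
    if not pooled_summaries.empty:
        analyzable = pooled_summaries.drop(columns=["n_days"])
        metrics = [m for m in OUTCOME_METRICS + COURSE_METRICS if m in analyzable.columns]
        model = PairedCrossover.from_dataframe(analyzable, metrics=metrics)
        if model.data:
            results = model.fit()

    # Table-3-analogue: settings and course by strategy
    table3_rows: list[dict] = []
    for label in (LOOSE, TIGHT):
        strat = strategies[label]
        sub = pooled_summaries[pooled_summaries["strategy"] == label] if len(pooled_summaries) else pd.DataFrame()
        row = {
            "strategy": label,
            "n_subjects": len(sub),
            "low_alarm": strat.low_alarm,
            "high_alarm": strat.high_alarm,
            "delay_s": strat.delay_s,
        }
        for m in COURSE_METRICS:
            if len(sub):
                row[f"{m}_mean"] = float(sub[m].mean())
                row[f"{m}_sd"] = float(sub[m].std(ddof=1)) if len(sub) > 1 else 0.0
            else:
                row[f"{m}_mean"] = row[f"{m}_sd"] = float("nan")
        table3_rows.append(row)
    table3 = _round_tables(pd.DataFrame(table3_rows))

    table4 = (
        _round_tables(
            results.to_frame().set_index("metric").loc[
                [m for m in OUTCOME_METRICS if m in results.comparisons]
            ].reset_index()
        )
        if results is not None
        else pd.DataFrame()
    )

    fig1 = cohort_histogram(subject_histograms)
    if len(day_summaries):
        kept = day_summaries[day_summaries["analyzed"]]
        fig2 = kept[["subject_id", "day", "strategy", "alarm_rate_per_h"]].copy()
    else:
        fig2 = pd.DataFrame(columns=["subject_id", "day", "strategy", "alarm_rate_per_h"])

    accounting = day_accounting(
        analyzed_by_strategy,
        excluded_violation_days=excluded_violation_days,
        not_completed_days=not_completed_days,
    )
    accounting.update(
        {
            "enrolled_subjects": sim.n_subjects,
            "analyzed_subjects": sim.n_subjects - len(subject_exclusions),
            "excluded_subjects": {
                sid: reason for sid, reason in sorted(subject_exclusions.items())
            },
            "seed": config.seed,
            "config_hash": _config_hash(config),
        }
    )
    # identity check: every assigned day is analyzed, excluded, or not completed
    assigned_total = sum(r["days_completed"] for r in roster_rows) + not_completed_days
    # days of excluded subjects were analyzed-quality but never pooled
    excluded_subject_days = sum(
        sum(len(v) for v in kept_days[sid].values()) for sid in subject_exclusions
    )
    accounting["excluded_subject_days"] = excluded_subject_days
    accounting["assigned_days_total"] = assigned_total
    assert (
        accounting["analyzed_days_total"]
        + excluded_violation_days
        + not_completed_days
        + excluded_subject_days
        == assigned_total
    ), "day accounting identity violated"

    logger.info(
        "run_study: analyzed %d days (%s), %d violation days, %d subjects excluded",
        accounting["analyzed_days_total"],
        analyzed_by_strategy,
        excluded_violation_days,
        len(subject_exclusions),
    )
    event_df = (
        pd.concat(event_frames, ignore_index=True)
        if event_frames
        else pd.DataFrame(columns=["subject_id", "day", "kind", "start_s", "end_s", "duration_s"])
    )
    return StudyReport(
        config=config,
        roster=roster,
        day_summaries=day_summaries,
        pooled_summaries=pooled_summaries,
        results=results,
        table3=table3,
        table4=table4,
        fig1_histogram=fig1,
        fig2_alarm_rates=fig2,
        accounting=accounting,
        alarm_events=event_df,
    )
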