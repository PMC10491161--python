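"""End-to-end analysis of a multi-genotype DAM experiment.

Given generated (or loaded) monitor data for one experimental genotype and
its genetic controls, this pipeline scores sleep, computes the per-fly
behavioral metrics (sleep onset after dusk, evening anticipation slope,
evening peak phase, windowed sleep change, night sleep), runs the
group-comparison statistics with the appropriate normality gating (sleep
onset is always treated as non-normal), and renders verdicts against both
controls.  Outputs are tidy CSV tables; the whole run is deterministic for
a fixed experiment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import sleep as sl
from .dam import MINUTES_PER_DAY, FlySeries, to_fly_series
from .rhythm import anticipation_slope, evening_peak_phase
from .stats import (
    CONTROL,
    EXPERIMENTAL,
    Group,
    GroupDesign,
    StatReport,
    Verdict,
    run_comparison,
    vs_both_controls,
)
from .synthetic import Experiment

METRICS = (
    "onset_zt",
    "anticipation_slope",
    "evening_peak_zt",
    "afternoon_sleep_change",
    "night_sleep_min",
)
# sleep onset is floored at dusk, so it is always routed to Kruskal-Wallis/Dunn
FORCE_NONPARAMETRIC = {"onset_zt"}
TESTED_METRICS = ("onset_zt", "anticipation_slope", "evening_peak_zt", "afternoon_sleep_change")


@dataclass
class ExperimentAnalysis:
    metrics: pd.DataFrame  # tidy: fly_id, genotype, role, metric, value
    reports: dict[str, StatReport]
    verdicts: dict[str, dict[str, Verdict]]
    n_excluded_dead: int

    def metric_values(self, metric: str, genotype: str) -> np.ndarray:
        sel = (self.metrics["metric"] == metric) & (self.metrics["genotype"] == genotype)
        return self.metrics.loc[sel, "value"].dropna().to_numpy()


def fly_metrics(series: FlySeries) -> dict[str, float]:
    """All per-fly metrics for one ZT-aligned series of whole protocol days."""
    indicator = sl.score_series(series)
    onsets = []
    for d in range(series.n_days):
        if series.day_tags[d] == "discard":
            continue
        onset = sl.sleep_onset_after_dusk(
            series.day(d), flagged=series.day_flagged(d)
        )
        if onset is not None:
            onsets.append(onset)
    day_ind = indicator.reshape(series.n_days, MINUTES_PER_DAY)
    tags = series.day_tags
    manip = [d for d in range(series.n_days) if tags[d] == "manipulation"]
    base = [d for d in range(series.n_days) if tags[d] == "baseline"]
    if manip and base:
        change = float(
            np.mean([sl.sleep_amount(day_ind[d], sl.AFTERNOON) for d in manip])
            - np.mean([sl.sleep_amount(day_ind[d], sl.AFTERNOON) for d in base])
        )
    elif series.n_days >= 2:
        change = float(
            sl.sleep_amount(day_ind[-1], sl.AFTERNOON)
            - sl.sleep_amount(day_ind[0], sl.AFTERNOON)
        )
    else:
        change = np.nan
    phase = evening_peak_phase(series).evening_peak_zt
    return {
        "onset_zt": float(np.mean(onsets)) if onsets else np.nan,
        "anticipation_slope": anticipation_slope(series).slope,
        "evening_peak_zt": np.nan if phase is None else float(phase),
        "afternoon_sleep_change": change,
        "night_sleep_min": float(
            np.mean([sl.sleep_amount(day_ind[d], sl.NIGHT) for d in range(series.n_days)])
        ),
    }


def analyze_experiment(
    experiment: Experiment,
    outdir: str | Path | None = None,
    alpha: float = 0.05,
) -> ExperimentAnalysis:
    """Score, measure and statistically compare all cohorts of an experiment."""
    rows = []
    n_dead = 0
    for label, cohort in experiment.cohorts.items():
        role = experiment.roles[label]
        for f, (m, ch) in enumerate(cohort.fly_channels):
            series = to_fly_series(
                cohort.monitors[m], cohort.schedule, ch, fly_id=f"{label}:fly{f:03d}"
            )
            if sl.is_dead(series):
                n_dead += 1
                continue
            for metric, value in fly_metrics(series).items():
                rows.append(
                    {"fly_id": series.fly_id, "genotype": label, "role": role,
                     "metric": metric, "value": value}
                )
    metrics = pd.DataFrame(rows).sort_values(["metric", "genotype", "fly_id"]).reset_index(drop=True)

    reports: dict[str, StatReport] = {}
    verdicts: dict[str, dict[str, Verdict]] = {}
    for metric in TESTED_METRICS:
        groups = []
        for label in experiment.cohorts:
            sel = (metrics["metric"] == metric) & (metrics["genotype"] == label)
            vals = metrics.loc[sel, "value"].dropna().to_numpy()
            if len(vals) < 2:
                continue
            role = EXPERIMENTAL if experiment.roles[label] == "experimental" else CONTROL
            groups.append(Group(label, role, vals))
        roles_present = {g.role for g in groups}
        if EXPERIMENTAL not in roles_present or CONTROL not in roles_present:
            continue
        design = GroupDesign(groups)
        report = run_comparison(
            design, force_nonparametric=metric in FORCE_NONPARAMETRIC, alpha=alpha
        )
        reports[metric] = report
        verdicts[metric] = vs_both_controls(report, design)

    analysis = ExperimentAnalysis(metrics, reports, verdicts, n_dead)
    if outdir is not None:
        _write_outputs(analysis, Path(outdir))
    return analysis


def _write_outputs(analysis: ExperimentAnalysis, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    analysis.metrics.to_csv(outdir / "metrics.csv", index=False, float_format="%.10g")
    stat_rows = []
    for metric, report in sorted(analysis.reports.items()):
        for r in report.posthoc:
            stat_rows.append(
                {"metric": metric, "omnibus": report.omnibus_test,
                 "omnibus_p": report.omnibus_p, "pair": f"{r.pair[0]} vs {r.pair[1]}",
                 "statistic": r.statistic, "p_raw": r.p_raw, "p_adj": r.p_adj,
                 "significant": r.significant, "direction": r.direction}
            )
    pd.DataFrame(stat_rows).to_csv(outdir / "stats.csv", index=False, float_format="%.10g")
    verdict_rows = [
        {"metric": metric, "experimental": label, "significant": v.significant}
        for metric, per_exp in sorted(analysis.verdicts.items())
        for label, v in sorted(per_exp.items())
    ]
    pd.DataFrame(verdict_rows).to_csv(outdir / "verdicts.csv", index=False)
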