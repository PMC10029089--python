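"""Cohort-level reports tying the stages together.

``run_full_pipeline`` mirrors the analysis sequence: classify every
patient under both schemes, cross-tabulate, summarise survival per class
(median OS with the IQR of observed event times), test group separation by
log-rank and pairwise Cox hazard ratios against the wild-type reference,
and optionally run the cross-validated cutoff search.  The report is a
plain JSON-serialisable dict; ``render_text`` turns it into the
human-readable summary the CLI prints.  Kaplan–Meier curves are exported
as (time, survival, at-risk) tables rather than images.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .classifier import (
    classify_cohort,
    classify_traditional,
    reclassification_table,
)
from .core_io import AllelicLabel, PatientRecord, RunConfig, TraditionalLabel
from .cutoff_search import CutoffSearchResult, crossval_cutoff, fixed_grid
from .survival_stats import cox_univariate, km_estimate, logrank

logger = logging.getLogger("tp53allelic")

__all__ = ["run_full_pipeline", "render_text", "group_survival_summary"]

_CLASS_ORDER = [
    AllelicLabel.WT.value,
    AllelicLabel.del17p_only.value,
    AllelicLabel.probable_monoallelic.value,
    AllelicLabel.probable_biallelic.value,
    AllelicLabel.obligatory_biallelic.value,
]


def group_survival_summary(
    cohort: Sequence[PatientRecord], labels: Sequence[str]
) -> dict:
    """Per-group n, events, KM median OS, IQR of observed event times, curve."""
    out: dict[str, dict] = {}
    labels = list(labels)
    for lab in sorted(set(labels), key=lambda s: _CLASS_ORDER.index(s) if s in _CLASS_ORDER else 99):
        idx = [i for i, l in enumerate(labels) if l == lab]
        times = np.array([cohort[i].os_months for i in idx])
        events = np.array([cohort[i].os_event for i in idx])
        curve = km_estimate(times, events)
        ev_times = times[events]
        iqr = (
            [float(np.percentile(ev_times, 25)), float(np.percentile(ev_times, 75))]
            if ev_times.size
            else None
        )
        out[lab] = {
            "n": len(idx),
            "events": int(events.sum()),
            "median_os_months": curve.median,
            "event_time_iqr": iqr,
            "km_curve": {
                "time": [float(t) for t in curve.event_times],
                "survival": [float(s) for s in curve.survival],
                "at_risk": [int(r) for r in curve.at_risk],
            },
        }
    return out


def _pairwise_logrank(cohort, labels) -> dict:
    groups = sorted(set(labels), key=lambda s: _CLASS_ORDER.index(s) if s in _CLASS_ORDER else 99)
    times = np.array([p.os_months for p in cohort])
    events = np.array([p.os_event for p in cohort])
    lab_arr = np.array(labels)
    res = {}
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            mask = (lab_arr == a) | (lab_arr == b)
            t = logrank(times[mask], events[mask], lab_arr[mask])
            res[f"{a} vs {b}"] = {
                "statistic": t.statistic,
                "p_value": t.p_value,
            }
    return res


def _cox_vs_wt(cohort, labels) -> dict:
    """Univariate hazard ratios of each class against the WT reference."""
    times = np.array([p.os_months for p in cohort])
    events = np.array([p.os_event for p in cohort])
    lab_arr = np.array(labels)
    res = {}
    if AllelicLabel.WT.value not in lab_arr:
        return res
    for lab in sorted(set(labels)):
        if lab == AllelicLabel.WT.value:
            continue
        mask = (lab_arr == AllelicLabel.WT.value) | (lab_arr == lab)
        x = (lab_arr[mask] == lab).astype(float)
        try:
            fit = cox_univariate(times[mask], events[mask], x)
        except (ValueError, RuntimeError) as exc:
            logger.warning("Cox fit for %s vs WT failed: %s", lab, exc)
            continue
        res[f"{lab} vs WT"] = {
            "hazard_ratio": fit.hazard_ratio,
            "ci95": [fit.ci_low, fit.ci_high],
        }
    return res


def run_full_pipeline(
    cohort: Sequence[PatientRecord],
    config: RunConfig,
    optimize_cutoff: bool = False,
    candidate_cutoffs=None,
) -> dict:
    """Run classify -> survival comparison -> (optional) cutoff search.

    Deterministic given the cohort and ``config.seed``.  The survival
    section degenerates gracefully (with a logged note) when fewer than two
    classes are present.
    """
    n = len(cohort)
    calls = classify_cohort(cohort, config)
    allelic_labels = [c.label.value for c in calls]
    trad_labels = [classify_traditional(p).value for p in cohort]

    report: dict = {
        "n_patients": n,
        "config": {
            "cutoff": config.cutoff,
            "min_node": config.min_node,
            "cv_runs": config.cv_runs,
            "test_fraction": config.test_fraction,
            "seed": config.seed,
        },
        "traditional_counts": {
            lab.value: trad_labels.count(lab.value) for lab in TraditionalLabel
        },
        "allelic_counts": {
            lab.value: allelic_labels.count(lab.value) for lab in AllelicLabel
        },
        "reclassification": reclassification_table(cohort, config).to_dict(),
    }

    report["survival_by_class"] = group_survival_summary(cohort, allelic_labels)
    if len(set(allelic_labels)) >= 2:
        report["pairwise_logrank"] = _pairwise_logrank(cohort, allelic_labels)
        report["cox_vs_wt"] = _cox_vs_wt(cohort, allelic_labels)
    else:
        logger.info("single survival group; omitting between-group tests")
        report["pairwise_logrank"] = {}
        report["cox_vs_wt"] = {}

    if optimize_cutoff:
        grid = fixed_grid() if candidate_cutoffs is None else candidate_cutoffs
        result: CutoffSearchResult = crossval_cutoff(cohort, grid, config)
        report["cutoff_search"] = result.to_dict()
    return report


def render_text(report: dict) -> str:
    """Plain-text summary of a pipeline report."""
    lines = []
    lines.append(f"cohort: {report['n_patients']} patients")
    cfg = report["config"]
    lines.append(
        f"config: cutoff={cfg['cutoff']:.2f} min_node={cfg['min_node']} "
        f"cv_runs={cfg['cv_runs']} seed={cfg['seed']}"
    )
    lines.append("")
    lines.append("traditional hit classes:")
    for lab, cnt in report["traditional_counts"].items():
        lines.append(f"  {lab:22s} {cnt}")
    lines.append("allelic-configuration classes:")
    for lab, cnt in report["allelic_counts"].items():
        lines.append(f"  {lab:22s} {cnt}")
    lines.append("")
    lines.append("survival by allelic class (median OS months [IQR of event times]):")
    for lab, s in report["survival_by_class"].items():
        med = "not reached" if s["median_os_months"] is None else f"{s['median_os_months']:.1f}"
        iqr = (
            f" [{s['event_time_iqr'][0]:.0f}-{s['event_time_iqr'][1]:.0f}]"
            if s["event_time_iqr"]
            else ""
        )
        lines.append(f"  {lab:22s} n={s['n']:<5d} events={s['events']:<5d} median={med}{iqr}")
    if report.get("pairwise_logrank"):
        lines.append("")
        lines.append("pairwise log-rank:")
        for pair, r in report["pairwise_logrank"].items():
            lines.append(f"  {pair:45s} chi2={r['statistic']:.2f} p={r['p_value']:.3g}")
    if report.get("cox_vs_wt"):
        lines.append("")
        lines.append("univariate Cox vs WT:")
        for pair, r in report["cox_vs_wt"].items():
            lines.append(
                f"  {pair:45s} HR={r['hazard_ratio']:.2f} "
                f"[{r['ci95'][0]:.2f}-{r['ci95'][1]:.2f}]"
            )
    if "cutoff_search" in report:
        cs = report["cutoff_search"]
        lines.append("")
        lines.append(
            f"cutoff search: selected VAF cutoff {100 * cs['selected_cutoff']:.0f}% "
            f"(mean test C {max(m for m in cs['cv_mean'] if m == m):.4f} over {cs['runs']} runs)"
        )
    return "\n".join(lines) + "\n"
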