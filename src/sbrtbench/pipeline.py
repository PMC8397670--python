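"""End-to-end evaluation: normalize -> metrics -> objectives -> cohort stats.

Every number emitted by the reporter is produced by a module operation
(DVH engine, conformity indices, objective checker, rank statistics);
this module only orchestrates and tabulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import conformity as conf
from .dvh import (
    dvh as compute_dvh,
    dose_mean,
    dose_quantile_pct,
    dose_to_hottest_volume,
    volume_at_dose_cm3,
    volume_at_dose_pct,
)
from .grids import Plan, StructureRole
from .objectives import (
    Disposition,
    Objective,
    ObjectiveReport,
    default_objectives,
    evaluate,
)
from .prescription import Prescription, STUDY_PRESCRIPTION, normalize_plan
from .stats import KWResult, kruskal_wallis, multiplicity_policy, summarize

__all__ = [
    "METRIC_COLUMNS",
    "PRIMARY_METRIC",
    "plan_metrics",
    "EvaluationResult",
    "evaluate_cohort",
    "cohort_statistics",
]

#: Metric columns of the per-plan table, with units in brackets.
METRIC_COLUMNS = [
    "itv_dmedian[Gy]",
    "itv_v90pct[%]",
    "ptv_dmean[Gy]",
    "ptv_dmedian[Gy]",
    "ptv_v70pct[%]",
    "ptv_d0p1ml[Gy]",
    "ptv_d2pct[Gy]",
    "ptv_d98pct[Gy]",
    "ci_rtog",
    "ci_paddick",
    "gi",
    "lung_ipsi_dmean[Gy]",
    "lung_contra_dmean[Gy]",
    "chest_wall_v30[ml]",
]

#: The study's pre-declared primary endpoint (tested without correction).
PRIMARY_METRIC = "ptv_dmean[Gy]"


def plan_metrics(plan: Plan, rx: Prescription = STUDY_PRESCRIPTION) -> dict[str, float]:
    """All per-plan dosimetric metrics of a *normalized* plan."""
    grid = plan.grid
    itv = plan.mask(StructureRole.ITV)
    ptv = plan.mask(StructureRole.PTV)
    curve_itv = compute_dvh(grid, itv)
    curve_ptv = compute_dvh(grid, ptv)
    t90 = 58.1  # printed 90% threshold
    t70 = conf.REFERENCE_DOSE_GY
    vols = conf.isodose_volumes(plan, t70)
    out = {
        "itv_dmedian[Gy]": dose_quantile_pct(curve_itv, 50),
        "itv_v90pct[%]": volume_at_dose_pct(grid, itv, t90),
        "ptv_dmean[Gy]": dose_mean(grid, ptv),
        "ptv_dmedian[Gy]": dose_quantile_pct(curve_ptv, 50),
        "ptv_v70pct[%]": volume_at_dose_pct(grid, ptv, t70),
        "ptv_d0p1ml[Gy]": dose_to_hottest_volume(curve_ptv, 0.1),
        "ptv_d2pct[Gy]": dose_quantile_pct(curve_ptv, 2),
        "ptv_d98pct[Gy]": dose_quantile_pct(curve_ptv, 98),
        "ci_rtog": conf.ci_rtog(vols),
        "ci_paddick": conf.ci_paddick(vols),
        "gi": conf.gradient_index(vols),
    }
    for key, role in (
        ("lung_ipsi_dmean[Gy]", StructureRole.LUNG_IPSI),
        ("lung_contra_dmean[Gy]", StructureRole.LUNG_CONTRA),
    ):
        out[key] = (
            dose_mean(grid, plan.mask(role)) if role in plan.structures else float("nan")
        )
    if StructureRole.CHEST_WALL in plan.structures:
        out["chest_wall_v30[ml]"] = volume_at_dose_cm3(
            grid, plan.mask(StructureRole.CHEST_WALL), 30.0
        )
    else:
        out["chest_wall_v30[ml]"] = float("nan")
    return out


@dataclass
class EvaluationResult:
    """Output of the evaluate stage: one table row and one report per plan."""

    table: pd.DataFrame  # all plans, with 'disposition' column
    reports: list[ObjectiveReport]
    scale_factors: list[float]

    @property
    def included(self) -> pd.DataFrame:
        return self.table[self.table["disposition"] == Disposition.INCLUDED.value]


def evaluate_cohort(
    plans: Sequence[Plan],
    rx: Prescription = STUDY_PRESCRIPTION,
    objectives: Sequence[Objective] | None = None,
) -> EvaluationResult:
    """Normalize each plan, compute its metrics and its objective report."""
    if not plans:
        raise ValueError("no plans to evaluate")
    objectives = default_objectives(rx) if objectives is None else objectives
    rows = []
    reports: list[ObjectiveReport] = []
    scales: list[float] = []
    for plan in plans:
        normed, s = normalize_plan(plan, rx)
        scales.append(s)
        report = evaluate(normed, objectives, rx)
        reports.append(report)
        row = {
            "institution": plan.meta.institution_id,
            "patient": plan.meta.patient_id,
            "technique": plan.meta.technique.value,
            "algorithm": plan.meta.algorithm.value,
        }
        row.update(plan_metrics(normed, rx))
        row["disposition"] = report.disposition.value
        row["minor_deviation"] = report.has_minor_deviation
        rows.append(row)
    table = pd.DataFrame(rows)
    return EvaluationResult(table=table, reports=reports, scale_factors=scales)


@dataclass
class CohortStatistics:
    summary: pd.DataFrame
    kw_results: dict[str, dict[str, KWResult]] = field(default_factory=dict)
    policy: str = "primary unadjusted; Holm-Bonferroni for the rest"


def cohort_statistics(
    included: pd.DataFrame,
    group_by: str = "technique",
    per_patient: bool = True,
    primary_metric: str = PRIMARY_METRIC,
    family: Sequence[str] | None = None,
) -> CohortStatistics:
    """Group summary plus Kruskal-Wallis comparisons with the selective policy.

    By default summaries are per patient (matching how the benchmark tabulates
    them) and the tested family is every metric column; the primary metric is
    reported without multiplicity adjustment.
    """
    metrics = [c for c in METRIC_COLUMNS if c in included.columns]
    family = list(metrics) if family is None else list(family)
    group_cols = ["patient", group_by] if per_patient else [group_by]
    summary = summarize(included, group_by=group_cols, metrics=metrics)

    kw_all: dict[str, dict[str, KWResult]] = {}
    patients = sorted(included["patient"].unique()) if per_patient else ["pooled"]
    for patient in patients:
        sub = included if patient == "pooled" else included[included["patient"] == patient]
        if sub[group_by].nunique() < 2:
            continue
        results: dict[str, KWResult] = {}
        for metric in family:
            vals = sub[metric].to_numpy()
            groups = sub[group_by].to_numpy()
            mask = ~pd.isna(vals)
            if pd.Series(groups[mask]).nunique() < 2:
                continue
            results[metric] = kruskal_wallis(vals[mask], groups[mask])
        if primary_metric in results:
            results = multiplicity_policy(results, primary_metric)
        kw_all[str(patient)] = results
    return CohortStatistics(summary=summary, kw_results=kw_all)
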