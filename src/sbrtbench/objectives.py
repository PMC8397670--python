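"""Tiered protocol objectives, verdicts and plan disposition.

The benchmark protocol evaluates every normalized plan against an ordered
set of target objectives, each with an optional *minor deviation* tier:

=====================  ==========================  =========================
objective              main                        minor deviation
=====================  ==========================  =========================
PTV coverage           D95% > 45.2 Gy (70%)        D90% > 45.2 Gy
ITV coverage           D95% > 58.1 Gy (90%)        D90% > 58.1 Gy
conformity             CI_RTOG < 1.20              CI_RTOG < 1.25
hot spot               PTV D0.1 ml < 69 Gy (107%)  < 71 Gy (110%)
=====================  ==========================  =========================

plus hard organ-at-risk rules without a minor tier (spinal canal
D0.1 ml < 18 Gy; chest wall V30Gy < 30 ml) and a report-only ALARA entry for
the bilateral lungs.  Comparisons are strict as printed; boundary equality
counts as failure of that tier.  Thresholds default to the printed rounded
values (the protocol as distributed); an exact-percent basis is available.

Disposition: a pencil-beam-labelled plan is excluded outright (algorithm
non-compliant for lung SBRT); any VIOLATION verdict excludes the plan; plans
with only minor deviations remain included (and are flagged).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import conformity as conf
from .dvh import (
    dvh as compute_dvh,
    dose_mean,
    dose_quantile_pct,
    dose_to_hottest_volume,
    volume_at_dose_cm3,
)
from .grids import Algorithm, Plan, StructureRole, Technique
from .prescription import (
    Prescription,
    STUDY_PRESCRIPTION,
    dose_at_percent,
    display_gy,
    mean_itv_dose,
)

__all__ = [
    "Verdict",
    "Disposition",
    "Objective",
    "ObjectiveResult",
    "ObjectiveReport",
    "default_objectives",
    "evaluate",
    "tally_deviations",
    "DeviationTally",
    "objectives_to_dicts",
    "objectives_from_dicts",
]


class Verdict(str, enum.Enum):
    PASS = "PASS"
    MINOR = "MINOR"
    VIOLATION = "VIOLATION"


class Disposition(str, enum.Enum):
    INCLUDED = "INCLUDED"
    EXCLUDED_CONSTRAINT = "EXCLUDED_CONSTRAINT"
    EXCLUDED_ALGORITHM = "EXCLUDED_ALGORITHM"


@dataclass(frozen=True)
class MetricSpec:
    """One measurable quantity on a plan: kind + structure + parameter."""

    kind: str  # D_PCT | D_ABSVOL | V_ABS | CI_RTOG | DMEAN
    structure: StructureRole | None = None
    param: float | None = None  # % for D_PCT, cm^3 for D_ABSVOL, Gy for V_ABS

    def describe(self) -> str:
        s = self.structure.value if self.structure else ""
        if self.kind == "D_PCT":
            return f"{s} D{self.param:g}%"
        if self.kind == "D_ABSVOL":
            return f"{s} D{self.param:g}ml"
        if self.kind == "V_ABS":
            return f"{s} V{self.param:g}Gy"
        if self.kind == "CI_RTOG":
            return "CI_RTOG"
        return f"{s} Dmean"


@dataclass(frozen=True)
class Objective:
    """One protocol row: a main comparison plus an optional minor tier.

    The minor tier may relax the limit, the metric, or both (the coverage
    objectives keep the limit and relax D95% to D90%).
    """

    id: str
    metric: MetricSpec
    comparator: str  # "<" or ">"
    limit: float
    units: str
    minor_metric: MetricSpec | None = None
    minor_limit: float | None = None
    tier: str = "target"  # target | oar_hard | alara

    def __post_init__(self) -> None:
        if self.comparator not in ("<", ">"):
            raise ValueError(f"comparator must be '<' or '>', got {self.comparator!r}")
        if self.minor_limit is not None and self.minor_metric is None:
            # a relaxed limit on the same metric must be strictly weaker
            weaker = (
                self.minor_limit > self.limit
                if self.comparator == "<"
                else self.minor_limit < self.limit
            )
            if not weaker:
                raise ValueError(f"objective {self.id}: minor limit is not weaker than the limit")


@dataclass
class ObjectiveResult:
    objective_id: str
    metric: str
    measured: float
    verdict: Verdict | None  # None for report-only (ALARA) entries
    limit: float | None
    units: str


@dataclass
class ObjectiveReport:
    """Per-plan protocol evaluation."""

    plan_label: str
    technique: Technique
    algorithm: Algorithm
    patient_id: str
    results: list[ObjectiveResult]
    disposition: Disposition
    has_minor_deviation: bool

    def verdict_of(self, objective_id: str) -> Verdict | None:
        for r in self.results:
            if r.objective_id == objective_id:
                return r.verdict
        raise KeyError(objective_id)


def default_objectives(
    rx: Prescription = STUDY_PRESCRIPTION, basis: str = "printed"
) -> list[Objective]:
    """The benchmark protocol objective set for a prescription.

    ``basis="printed"`` uses the rounded thresholds as distributed on the
    protocol sheet (45.2, 58.1, 69, 71 Gy for the 64.5 Gy prescription);
    ``basis="exact"`` recomputes them as unrounded percentages.
    """
    if basis == "printed":
        t70 = display_gy(dose_at_percent(rx, 70))
        t90 = display_gy(dose_at_percent(rx, 90))
        t107 = round(dose_at_percent(rx, 107))
        t110 = round(dose_at_percent(rx, 110))
    elif basis == "exact":
        t70 = dose_at_percent(rx, 70)
        t90 = dose_at_percent(rx, 90)
        t107 = dose_at_percent(rx, 107)
        t110 = dose_at_percent(rx, 110)
    else:
        raise ValueError(f"unknown threshold basis {basis!r}")
    ptv, itv = StructureRole.PTV, StructureRole.ITV
    return [
        Objective(
            id="ptv_coverage",
            metric=MetricSpec("D_PCT", ptv, 95),
            comparator=">",
            limit=t70,
            units="Gy",
            minor_metric=MetricSpec("D_PCT", ptv, 90),
            minor_limit=t70,
        ),
        Objective(
            id="itv_coverage",
            metric=MetricSpec("D_PCT", itv, 95),
            comparator=">",
            limit=t90,
            units="Gy",
            minor_metric=MetricSpec("D_PCT", itv, 90),
            minor_limit=t90,
        ),
        Objective(
            id="ci_rtog",
            metric=MetricSpec("CI_RTOG"),
            comparator="<",
            limit=1.20,
            units="",
            minor_limit=1.25,
        ),
        Objective(
            id="d0p1ml",
            metric=MetricSpec("D_ABSVOL", ptv, 0.1),
            comparator="<",
            limit=t107,
            units="Gy",
            minor_limit=t110,
        ),
        Objective(
            id="spinal_canal_d0p1ml",
            metric=MetricSpec("D_ABSVOL", StructureRole.SPINAL_CANAL, 0.1),
            comparator="<",
            limit=18.0,
            units="Gy",
            tier="oar_hard",
        ),
        Objective(
            id="chest_wall_v30",
            metric=MetricSpec("V_ABS", StructureRole.CHEST_WALL, 30.0),
            comparator="<",
            limit=30.0,
            units="ml",
            tier="oar_hard",
        ),
        Objective(
            id="lungs_alara",
            metric=MetricSpec("DMEAN", StructureRole.LUNG_IPSI),
            comparator="<",
            limit=float("inf"),
            units="Gy",
            tier="alara",
        ),
    ]


def _measure(plan: Plan, spec: MetricSpec, curves: dict) -> float:
    if spec.kind == "CI_RTOG":
        return conf.ci_rtog(conf.isodose_volumes(plan))
    mask = plan.mask(spec.structure)
    if spec.kind == "DMEAN":
        return dose_mean(plan.grid, mask)
    if spec.kind == "V_ABS":
        return volume_at_dose_cm3(plan.grid, mask, spec.param)
    if spec.structure not in curves:
        curves[spec.structure] = compute_dvh(plan.grid, mask)
    curve = curves[spec.structure]
    if spec.kind == "D_PCT":
        return dose_quantile_pct(curve, spec.param)
    if spec.kind == "D_ABSVOL":
        return dose_to_hottest_volume(curve, spec.param)
    raise ValueError(f"unknown metric kind {spec.kind!r}")


def _holds(value: float, comparator: str, limit: float) -> bool:
    return value < limit if comparator == "<" else value > limit


def evaluate(
    plan: Plan,
    objectives: Sequence[Objective] | None = None,
    rx: Prescription = STUDY_PRESCRIPTION,
    normalization_rtol: float = 1e-3,
) -> ObjectiveReport:
    """Evaluate one plan against the protocol.

    The plan must already be normalized (mean ITV dose equal to the nominal
    total within ``normalization_rtol``): every threshold assumes the anchor.
    """
    objectives = default_objectives(rx) if objectives is None else objectives
    m = mean_itv_dose(plan)
    if abs(m - rx.nominal_total_gy) / rx.nominal_total_gy > normalization_rtol:
        raise ValueError(
            f"plan is not normalized: mean ITV dose {m:.3f} Gy != {rx.nominal_total_gy} Gy"
        )
    curves: dict = {}
    results: list[ObjectiveResult] = []
    any_violation = False
    any_minor = False
    for obj in objectives:
        measured = _measure(plan, obj.metric, curves)
        if obj.tier == "alara":
            results.append(
                ObjectiveResult(obj.id, obj.metric.describe(), measured, None, None, obj.units)
            )
            continue
        if _holds(measured, obj.comparator, obj.limit):
            verdict = Verdict.PASS
        elif obj.tier == "target" and (obj.minor_metric is not None or obj.minor_limit is not None):
            minor_spec = obj.minor_metric or obj.metric
            minor_limit = obj.minor_limit if obj.minor_limit is not None else obj.limit
            minor_val = measured if obj.minor_metric is None else _measure(plan, minor_spec, curves)
            verdict = (
                Verdict.MINOR if _holds(minor_val, obj.comparator, minor_limit) else Verdict.VIOLATION
            )
        else:
            verdict = Verdict.VIOLATION
        any_violation |= verdict is Verdict.VIOLATION
        any_minor |= verdict is Verdict.MINOR
        results.append(
            ObjectiveResult(obj.id, obj.metric.describe(), measured, verdict, obj.limit, obj.units)
        )
    if plan.meta.algorithm is Algorithm.PB:
        disposition = Disposition.EXCLUDED_ALGORITHM
    elif any_violation:
        disposition = Disposition.EXCLUDED_CONSTRAINT
    else:
        disposition = Disposition.INCLUDED
    return ObjectiveReport(
        plan_label=f"{plan.meta.institution_id}/{plan.meta.patient_id}",
        technique=plan.meta.technique,
        algorithm=plan.meta.algorithm,
        patient_id=plan.meta.patient_id,
        results=results,
        disposition=disposition,
        has_minor_deviation=any_minor,
    )


@dataclass
class DeviationTally:
    """Minor-deviation counts per objective, by technique and by algorithm."""

    table: pd.DataFrame  # rows: objective ids; columns: groups + "Total"
    excluded: list[ObjectiveReport] = field(default_factory=list)


def tally_deviations(
    reports: Sequence[ObjectiveReport],
    group_by: tuple[str, ...] = ("technique", "algorithm"),
) -> DeviationTally:
    """Count MINOR verdicts per objective per group (plus totals).

    Excluded plans (algorithm or constraint) are listed separately and do
    not enter the counts, matching how the benchmark tabulates deviations.
    """
    if not reports:
        raise ValueError("no reports to tally")
    for key in group_by:
        if key not in ("technique", "algorithm"):
            raise KeyError(f"unknown grouping key {key!r}")
    included = [r for r in reports if r.disposition is Disposition.INCLUDED]
    excluded = [r for r in reports if r.disposition is not Disposition.INCLUDED]
    obj_ids = [res.objective_id for res in reports[0].results if res.verdict is not None]
    columns: list[str] = []
    getters: list[Callable[[ObjectiveReport], bool]] = []
    if "technique" in group_by:
        for tech in Technique:
            columns.append(tech.value)
            getters.append(lambda r, t=tech: r.technique is t)
    if "algorithm" in group_by:
        for alg in Algorithm:
            columns.append(alg.value)
            getters.append(lambda r, a=alg: r.algorithm is a)
    counts = np.zeros((len(obj_ids), len(columns) + 1), dtype=int)
    for rep in included:
        for i, oid in enumerate(obj_ids):
            if rep.verdict_of(oid) is Verdict.MINOR:
                for jcol, match in enumerate(getters):
                    if match(rep):
                        counts[i, jcol] += 1
                counts[i, -1] += 1
    table = pd.DataFrame(counts, index=obj_ids, columns=columns + ["Total"])
    return DeviationTally(table=table, excluded=excluded)


# --------------------------------------------------------------------------- #
# (de)serialization so other prescriptions can reuse the engine


def objectives_to_dicts(objectives: Sequence[Objective]) -> list[dict]:
    out = []
    for o in objectives:
        d = {
            "id": o.id,
            "metric": {
                "kind": o.metric.kind,
                "structure": o.metric.structure.value if o.metric.structure else None,
                "param": o.metric.param,
            },
            "comparator": o.comparator,
            "limit": o.limit,
            "units": o.units,
            "tier": o.tier,
        }
        if o.minor_metric is not None:
            d["minor_metric"] = {
                "kind": o.minor_metric.kind,
                "structure": o.minor_metric.structure.value if o.minor_metric.structure else None,
                "param": o.minor_metric.param,
            }
        if o.minor_limit is not None:
            d["minor_limit"] = o.minor_limit
        out.append(d)
    return out


def _metric_from_dict(d: dict) -> MetricSpec:
    return MetricSpec(
        kind=d["kind"],
        structure=StructureRole(d["structure"]) if d.get("structure") else None,
        param=d.get("param"),
    )


def objectives_from_dicts(items: Sequence[dict]) -> list[Objective]:
    out = []
    for d in items:
        out.append(
            Objective(
                id=d["id"],
                metric=_metric_from_dict(d["metric"]),
                comparator=d["comparator"],
                limit=float(d["limit"]),
                units=d.get("units", ""),
                minor_metric=_metric_from_dict(d["minor_metric"]) if "minor_metric" in d else None,
                minor_limit=float(d["minor_limit"]) if "minor_limit" in d else None,
                tier=d.get("tier", "target"),
            )
        )
    return out
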