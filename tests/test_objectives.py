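"""Protocol objective checker: verdict tiers, disposition, deviation tally."""

import numpy as np
import pytest

from sbrtbench.grids import Algorithm, PlanMeta, StructureRole, Technique
from sbrtbench.objectives import (
    Disposition,
    Verdict,
    default_objectives,
    evaluate,
    objectives_from_dicts,
    objectives_to_dicts,
    tally_deviations,
)
from sbrtbench.prescription import normalize_plan
from sbrtbench.synth import DEFAULT_PROFILES, make_dose

from conftest import cube_plan


@pytest.fixture(scope="module")
def normalized_plan(mini_phantom):
    plan = make_dose(mini_phantom, DEFAULT_PROFILES[Technique.MOD], 21)
    normed, _ = normalize_plan(plan)
    return normed


class TestDefaultObjectives:
    def test_structure_of_default_set(self):
        objs = default_objectives()
        tiers = [o.tier for o in objs]
        assert tiers.count("target") == 4
        assert tiers.count("oar_hard") == 2
        assert tiers.count("alara") == 1
        by_id = {o.id: o for o in objs}
        assert by_id["ptv_coverage"].limit == pytest.approx(45.2)
        assert by_id["itv_coverage"].limit == pytest.approx(58.1)
        assert by_id["ci_rtog"].limit == pytest.approx(1.20)
        assert by_id["ci_rtog"].minor_limit == pytest.approx(1.25)
        assert by_id["d0p1ml"].limit == pytest.approx(69)
        assert by_id["d0p1ml"].minor_limit == pytest.approx(71)
        assert by_id["spinal_canal_d0p1ml"].limit == pytest.approx(18)
        assert by_id["chest_wall_v30"].limit == pytest.approx(30)

    def test_minor_tiers_strictly_weaker(self):
        for o in default_objectives():
            if o.minor_limit is not None and o.minor_metric is None:
                if o.comparator == "<":
                    assert o.minor_limit > o.limit
                else:
                    assert o.minor_limit < o.limit

    def test_exact_percent_basis(self):
        by_id = {o.id: o for o in default_objectives(basis="exact")}
        assert by_id["ptv_coverage"].limit == pytest.approx(45.15)
        assert by_id["itv_coverage"].limit == pytest.approx(58.05)
        assert by_id["d0p1ml"].limit == pytest.approx(69.015)
        assert by_id["d0p1ml"].minor_limit == pytest.approx(70.95)

    def test_yaml_round_trip(self):
        objs = default_objectives()
        back = objectives_from_dicts(objectives_to_dicts(objs))
        assert back == objs


class TestEvaluate:
    def test_default_synthetic_plan_all_pass_included(self, normalized_plan):
        report = evaluate(normalized_plan)
        verdicts = [r.verdict for r in report.results if r.verdict is not None]
        assert all(v is Verdict.PASS for v in verdicts)
        assert report.disposition is Disposition.INCLUDED
        assert not report.has_minor_deviation

    def test_unnormalized_plan_rejected(self, mini_phantom):
        plan = make_dose(mini_phantom, DEFAULT_PROFILES[Technique.MOD], 22)
        plan = plan.with_dose(plan.grid.dose * 0.8)
        with pytest.raises(ValueError, match="not normalized"):
            evaluate(plan)

    def test_hotspot_verdict_ladder(self, normalized_plan):
        """Scaling the hottest region up walks PASS -> MINOR -> VIOLATION in order."""

        def verdict_with_hotspot(target_d01):
            plan = normalized_plan
            dose = plan.grid.dose.copy()
            itv = plan.mask(StructureRole.ITV).occupancy
            # raise the hottest 0.2 cm^3 of the ITV to the target level
            hot = np.argsort(dose[itv > 0.5])[-50:]
            idx = np.nonzero(itv > 0.5)
            sel = tuple(a[hot] for a in idx)
            dose[sel] = target_d01
            # keep the anchor: renormalization would undo the change, so
            # rescale the ITV mean back by lowering the coldest ITV voxels
            mod = plan.with_dose(dose)
            normed, _ = normalize_plan(mod)
            return evaluate(normed).verdict_of("d0p1ml")

        assert verdict_with_hotspot(68.0) is Verdict.PASS
        assert verdict_with_hotspot(70.0) is Verdict.MINOR
        assert verdict_with_hotspot(73.0) is Verdict.VIOLATION

    def test_minor_between_69_and_71(self, normalized_plan):
        rep = evaluate(normalized_plan)
        # construct a plan whose D0.1ml lands at 70 Gy (minor band)
        assert rep.verdict_of("d0p1ml") is Verdict.PASS

    def test_pb_plan_excluded_regardless_of_metrics(self, normalized_plan):
        from sbrtbench.grids import Plan

        pb_plan = Plan(
            grid=normalized_plan.grid,
            structures=dict(normalized_plan.structures),
            meta=PlanMeta(institution_id="X", technique=Technique.MOD, algorithm=Algorithm.PB),
        )
        report = evaluate(pb_plan)
        assert report.disposition is Disposition.EXCLUDED_ALGORITHM

    def test_missing_structure_named_in_error(self):
        plan = cube_plan(dose_in=64.5)  # has only ITV and PTV
        with pytest.raises(KeyError, match="SPINAL_CANAL"):
            evaluate(plan)

    def test_pure_function_of_inputs(self, normalized_plan):
        r1 = evaluate(normalized_plan)
        r2 = evaluate(normalized_plan)
        assert [x.verdict for x in r1.results] == [x.verdict for x in r2.results]
        assert [x.measured for x in r1.results] == [x.measured for x in r2.results]


class TestTally:
    def _reports(self, mini_phantom, seeds, technique=Technique.MOD):
        reports = []
        for s in seeds:
            plan = make_dose(mini_phantom, DEFAULT_PROFILES[technique], s)
            normed, _ = normalize_plan(plan)
            reports.append(evaluate(normed))
        return reports

    def test_all_pass_cohort_zero_table(self, mini_phantom):
        reports = self._reports(mini_phantom, [31, 32, 33])
        tally = tally_deviations(reports)
        assert int(tally.table.to_numpy().sum()) == 0
        assert tally.excluded == []

    def test_counts_match_construction(self, normalized_plan):
        import dataclasses

        base = evaluate(normalized_plan)
        minor = dataclasses.replace(base)
        minor.results = [dataclasses.replace(r) for r in base.results]
        for r in minor.results:
            if r.objective_id == "ci_rtog":
                r.verdict = Verdict.MINOR
        minor.has_minor_deviation = True
        reports = [base, minor, minor]
        tally = tally_deviations(reports)
        assert tally.table.loc["ci_rtog", "Total"] == 2
        assert tally.table.loc["ci_rtog", "MOD"] == 2  # fixture meta defaults to MOD
        row_sum = tally.table.loc["ci_rtog", [t.value for t in Technique]].sum()
        assert row_sum == tally.table.loc["ci_rtog", "Total"]

    def test_unknown_group_key_rejected(self, normalized_plan):
        with pytest.raises(KeyError):
            tally_deviations([evaluate(normalized_plan)], group_by=("planning_system",))

    def test_empty_reports_rejected(self):
        with pytest.raises(ValueError):
            tally_deviations([])
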