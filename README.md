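# sbrtbench

Dosimetric benchmarking of lung SBRT treatment plans with mean-ITV-dose
prescription normalization.

## The problem

Stereotactic body radiotherapy (SBRT) of peripheral lung tumours is planned
very differently across institutions: prescribed dose, normalization method
and the dose profile inside the target all vary, which makes delivered doses
and outcomes hard to compare.  One remedy is a *multiparameter* prescription:
normalize a fixed fractionation (here 3 × 21.5 Gy) to the **mean dose of the
internal target volume (ITV)** and add an explicit ladder of coverage,
conformity and hot-spot objectives for the ITV and the planning target
volume (PTV).  Benchmarking a pool of plans from many institutions and
delivery platforms against such a protocol requires a reproducible
evaluation pipeline — that pipeline is this package.

`sbrtbench` is for medical physicists and methodologists who want to

* evaluate voxelized dose distributions (DICOM RT Dose + RT Structure Set,
  or a simple internal container) against the tiered protocol,
* compute the standard plan-quality metrics exactly as defined below, and
* compare plan cohorts across delivery techniques (robotic radiosurgery,
  modulated, 3D-conformal) and dose-calculation algorithms.

Because benchmark submissions are rarely shareable, the package also ships a
calibrated synthetic plan generator (two phantom patients with peripheral
lesions, PTV ≈ 23.8 and 19.4 cm³, 5 mm ITV→PTV margin) so the entire
pipeline can be exercised and tested without clinical data.

## The model and metrics

With the prescription anchor D̄(ITV) = 64.5 Gy after normalization
(scale s = 64.5 Gy / mean ITV dose):

* **DVH metrics** at 0.1 Gy binning, occupancy-weighted:
  Dx% (dose received by at least x% of a structure), D 0.1 ml (dose to the
  hottest 0.1 ml), V(d) (volume receiving at least d).  Dmean/Dmedian are
  voxel-exact, so the anchor is not quantized.
* **Conformity / gradient**, with PIV = V(45.2 Gy) the 70 %-isodose volume,
  TV = V(PTV), TV_PIV = PTV volume inside the 45.2 Gy isodose:

      CI_RTOG    = PIV / TV
      CI_Paddick = TV_PIV² / (PIV · TV)
      GI         = V(22.6 Gy) / V(45.2 Gy)

* **BED** under the linear-quadratic model, BED = n·d·(1 + d/(α/β)) with
  α/β = 10 Gy: the prescription corresponds to 203 Gy₁₀; the 70 % / 90 % /
  107 % / 110 % levels print as 45.2 / 58.1 / 69 / 71 Gy (BED 112* / 170 /
  228 / 239 Gy₁₀; *112 from the equivalent 3 × 15 Gy scheme).
* **Protocol ladder** with minor-deviation tiers (PTV D95 % > 45.2 Gy, minor
  D90 %; ITV D95 % > 58.1 Gy, minor D90 %; CI_RTOG < 1.20, minor < 1.25;
  PTV D0.1 ml < 69 Gy, minor < 71 Gy), hard OAR rules (spinal canal
  D0.1 ml < 18 Gy, chest wall V30Gy < 30 ml) and a report-only ALARA lung
  entry.  Pencil-beam plans are excluded by rule; any violation excludes a
  plan; minor deviations are flagged but kept.
* **Cohort statistics**: median/mean/std per technique and patient, plus a
  from-scratch tie-corrected Kruskal–Wallis rank test with a selective
  multiplicity policy (the pre-declared primary endpoint — mean PTV dose —
  uncorrected, all other metrics Holm–Bonferroni adjusted, α = 0.05).

## Worked example

```python
from sbrtbench import (default_phantoms, make_dose, DEFAULT_PROFILES,
                       normalize_plan, evaluate, Technique)

phantom = default_phantoms()["patient1"]          # peripheral lesion, PTV ~23.8 cm3
plan = make_dose(phantom, DEFAULT_PROFILES[Technique.MOD], seed=7)
normed, s = normalize_plan(plan)                  # anchor: mean ITV dose = 64.5 Gy
print(f"normalization scale: {s:.4f}")
report = evaluate(normed)
for r in report.results:
    print(f"{r.objective_id:>20s}: {r.measured:8.3f}  "
          f"{r.verdict.value if r.verdict else 'report-only'}")
print("disposition:", report.disposition.value)
```

prints

```
normalization scale: 1.0068
        ptv_coverage:   47.915  PASS
        itv_coverage:   61.224  PASS
             ci_rtog:    1.106  PASS
              d0p1ml:   67.739  PASS
 spinal_canal_d0p1ml:    0.991  PASS
      chest_wall_v30:    4.412  PASS
         lungs_alara:    8.992  report-only
disposition: INCLUDED
```

i.e. this modulated plan, after rescaling by 1.0068, gives at least
47.9 Gy to 95 % of the PTV (limit 45.2 Gy), at least 61.2 Gy to 95 % of the
ITV (limit 58.1 Gy), spills 10.6 % of the prescription isodose outside the
PTV (CI_RTOG 1.106 < 1.20), keeps the hottest 0.1 ml below 69 Gy and meets
both organ-at-risk rules — the plan enters the analysis cohort.

The command-line interface runs the same stages on plan files:

```bash
sbrtbench simulate --seed 1 --out-dir plans/        # synthetic benchmark cohort
sbrtbench evaluate plans/ --out-dir results/        # metrics.csv + reports.json
sbrtbench cohort --metrics results/metrics.csv --out-dir results/
```

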