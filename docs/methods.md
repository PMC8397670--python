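# Methods

This note documents the models, conventions and numerical choices behind
`sbrtbench`, in the order a plan travels through the pipeline.

## Lattice model and volumes

Dose grids are regular lattices in patient coordinates (x, y, z; mm), voxel
values attributed to voxel centres.  Structures are *fractional occupancy*
fields on the same lattice; every metric is occupancy-weighted.  A
structure's volume is Σ occupancy × voxel volume.  Dose and masks must share
a lattice; trilinear resampling is available for ingestion but is never
applied implicitly, because partial-volume handling is precisely where
planning systems disagree.

Isodose volumes (for the conformity and gradient indices) are computed by
thresholding voxel doses and summing volumes — no iso-surface extraction.
This "voxel convention" is simple, fast, and exactly reproducible; it
differs from marching-cubes-style volumes by at most a surface-voxel layer.

## Contour rasterization

DICOM RT structures arrive as closed planar polygons.  Two policies:

* **fractional** (default): 3×3×3 supersampling of each voxel; a subsample
  point is inside if its z lies within half a contour-plane spacing of the
  *nearest* contour plane and its (x, y) falls inside an odd number of that
  plane's polygons (even-odd rule, so donut-shaped contours work).  The
  nearest-plane assignment matters: testing membership against *all* planes
  within reach would cancel pairs of planes by parity when a point is
  equidistant from two of them.
* **binary**: voxel centres only, occupancy ∈ {0, 1} — mimics coarser
  planning systems, offered because inter-system partial-volume differences
  are a known source of benchmark discrepancies.

A rasterized sphere of radius 10 mm at 1 mm pitch reproduces its analytic
volume to better than 2 % (tested).

## DVH engine

Cumulative DVHs use a fixed 0.1 Gy bin width.  The volume at edge e is the
occupancy with dose ≥ e (right-open histogram bins make the edge value
exact).  Conventions, chosen once and used everywhere:

* **Dx %** — largest dose received by at least x % of the volume, linearly
  interpolated between the bracketing 0.1 Gy edges; a `strict_bin` mode
  snaps to the lower edge for sensitivity checks (planning systems differ
  and neither convention is canonical).  Ties on flat curve segments
  resolve toward the *higher* dose, which is conservative for hot-spot
  (maximum-dose) objectives.
* **D v ml** — same machinery with an absolute-volume target.
* **Dmean, Dmedian** — computed voxel-exactly from the occupancy weights,
  not from the binned curve.  This matters because the mean ITV dose is the
  normalization anchor: a binned mean would quantize the anchor by up to
  0.05 Gy.
* **V(d)** — voxel-exact threshold sum, reported as % of structure volume
  or absolute cm³ (the chest-wall rule is absolute).

Degenerate inputs raise: zero-volume masks, percentages outside (0, 100],
requested volumes above the structure volume.

## Prescription, normalization, BED

The protocol prescribes 3 × 21.5 Gy normalized to the mean ITV dose
(nominal total 64.5 Gy).  `normalize_plan` multiplies the dose array by
s = 64.5 / mean-ITV-dose; the post-condition (anchor exact to 1e-9
relative, renormalization scale 1) is enforced by tests.  The objective
checker refuses plans whose anchor is off by more than 0.1 % — every
threshold presumes the anchor.

BED uses the standard LQ form n·d·(1 + d/(α/β)), α/β = 10 Gy.  Display
conventions reproduce the protocol sheet as distributed:

* doses: half-up to one decimal (45.15 → 45.2, 58.05 → 58.1), computed
  through a fixed-precision decimal so binary float artefacts
  (0.70 × 64.5 = 45.149999…) round as intended;
* BED: nearest integer with ties-to-even.  Ties-to-even rather than
  half-up is deliberate: it reproduces *all* printed anchors — 203.175 →
  203, 170.38 → 170, 227.78 → 228, 238.75 → 239 — including 112 for the
  equivalent 3 × 15 Gy scheme (112.5 unrounded).  Note the protocol sheet
  lists "BED = 112 Gy₁₀" beside the 45.2 Gy threshold although LQ gives
  113.3 Gy₁₀ for 45.2 Gy in 3 fractions; the 112 figure is consistent with
  3 × 15 Gy = 45.0 Gy and is treated as such, not silently corrected.

Objective thresholds default to the printed rounded values (45.2, 58.1,
69, 71 Gy) because that is the protocol institutions actually received; an
exact-percent basis (45.15, 58.05, 69.015, 70.95 Gy) is a config switch.

## Protocol objectives and disposition

Comparisons are strict (`<`, `>`) as printed; boundary equality counts as
failure of that tier (the protocol does not address exact-boundary cases,
so the stricter reading is documented rather than guessed).  The coverage
objectives' minor tier relaxes the *metric* (D95 % → D90 %) at the same
limit; conformity and hot-spot relax the *limit*.  Hard OAR rules have no
minor tier.  The lung objective is ALARA: reported, never a verdict.

Disposition: pencil-beam-labelled plans are excluded outright (the
algorithm class is non-compliant for lung SBRT); any VIOLATION excludes the
plan; plans with only minor deviations stay in the analysis but are
flagged — a plan with several minor deviations is still acceptable, since
the protocol counts deviations without ejecting such plans.  A conformity
index at or above the minor limit (≥ 1.25) is a violation and excludes.

## Synthetic plan generator

**What it emulates.**  Two stylized thorax phantoms carry ellipsoidal ITVs
with a 5 mm isotropic margin, targeted to PTV volumes of 23.8 cm³
(patient 1, lesion abutting the chest wall) and 19.4 cm³ (patient 2, chest
wall distant).  The thorax is an ellipsoid whose radial band forms the
chest wall; lungs are the interior minus a mediastinal slab, split into
ipsi/contralateral halves; spinal canal and esophagus are z-aligned
cylinders.  PTV dilation uses a first-order analytic distance to the
ellipsoid surface, d = (ρ − 1)·ρ/|∇ρ| — exact for spheres and accurate to
well below the lattice pitch for moderate aspect ratios (an earlier
voxelized-EDT dilation biased distances by ~half a fine voxel and missed
the analytic sphere-dilation volume by ~7 %).  If a target PTV volume is
requested, the semi-axes are rescaled by bisection until the dilated volume
matches within 1 %.  Default lattice: 2 mm pitch, 96×96×80 voxels
(192×192×160 mm); masks are rasterized with 2× linear supersampling.

**Dose model.**  Dose is a function of the signed Euclidean distance to the
PTV surface (computed once per phantom and reused), not of beam transport —
downstream analytics only see the resulting field, so a calibrated falloff
model suffices.  In units of the prescription anchor:

* inside the ITV: g = h − (h − L_itv)·ρ^κ — a centrally peaked hot spot
  with peak h (`hotspot_factor`), ITV-surface level L_itv and shape κ;
* across the margin: g = L_ptv + (L_itv − L_ptv)·(|sd|/margin)^q; the
  exponent q sets how much of the margin shell stays near the ITV level and
  is the main technique discriminator for the mean PTV dose;
* outside: g = L_ptv·[(1 − τ)·2^(−s/f_near) + τ·2^(−(s/f_tail)^1.5)] — a
  steep penumbra plus a sub-exponential low-dose bath.  f_near is solved
  (Brent) so the profile reaches 50 % of the PTV-surface level exactly at
  `falloff_scale_mm`, making that parameter the direct dial for the
  gradient index.  `penumbra_asymmetry` scales the distance coordinate by
  (1 + a·cos θ_z), slowing the falloff superiorly and steepening it
  inferiorly.

Per-plan interinstitutional variation comes from small seeded jitters of
(L_ptv, f, h, q, a) plus Gaussian-correlated voxel noise (σ given in Gy,
smoothed at 1.2 voxels, clipped at zero).  Seeding is counter-based
(Philox: cohort master seed = key, plan index = counter), so cohorts are
reproducible and order-independent.

**Default profiles** (frozen after the one-off calibration run in
`scripts/calibrate_profiles.py`): the three technique classes differ mainly
in margin exponent (RRS 2.2, MOD 1.7, 3D 1.15), falloff scale (10.8, 10.9,
11.8 mm) and noise (0.45, 0.35, 0.30 Gy).  After normalization this yields
median mean-PTV doses of ≈ 56.1 / 56.8 / 57.6 Gy (RRS < MOD < 3D),
CI_RTOG ≈ 1.10–1.12 (all plans within [1.05, 1.20]), GI ≈ 4.3–4.8 (all
within [3.4, 6.7]), and every default plan passes all protocol objectives
with margin — jitter scales were chosen small enough that this holds across
master seeds, at the cost of slightly smaller between-plan spread than a
real multi-institution pool shows.

**The benchmark cohort** (`make_study_cohort`): 57 submissions — 8 RRS
(all Monte Carlo), 34 MOD (Boltzmann/AAA-dominated), 15 3D (collapsed-cone
dominated) — with four pencil-beam-labelled plans and one modulated plan
generated non-conformally (PTV-surface level 0.80, no jitter → CI_RTOG
≈ 1.4, a robust violation).  Exclusions therefore leave exactly 52
analyzable plans at any master seed.  No minor deviations are planted: a
planted near-boundary deviation would make the tally seed-dependent.

**What the generator does *not* emulate**, and hence what passing tests do
not show about real data: beam/arc geometry, MLC sequences and
heterogeneity-corrected transport (dose is radially stylized, so e.g. the
ipsilateral lung mean of ~9–10 Gy runs above typical clinical values of
~4–6 Gy); inter-observer contouring variation; planning-system
partial-volume idiosyncrasies (only approximated by the two rasterization
modes); and genuinely heavy-tailed institutional outliers.

## Cohort statistics

Group summaries use midpoint medians and the sample (n−1) standard
deviation; a single-plan group reports its value with std absent.

The Kruskal–Wallis test is implemented from scratch: midranks for ties,
H = [12/(N(N+1)) Σ nᵢ(r̄ᵢ − (N+1)/2)²] / C with the tie correction
C = 1 − Σ(t³−t)/(N³−N), and an upper-tail χ² p-value with k−1 degrees of
freedom (the standard large-sample reference).  If all values are
identical, H = 0 and p = 1 by convention.  For N ≤ 12 an exact permutation
p-value over all distinct label assignments is offered; it is validated in
tests against independent enumeration, and the χ² approximation's size is
validated empirically (0.05 ± 0.01 at α = 0.05, three groups of 10, 10 000
null simulations).  The implementation is additionally cross-checked
against `scipy.stats.kruskal` on tied data.

Multiplicity follows the benchmark's selective policy: the pre-declared
primary endpoint (mean PTV dose) is tested uncorrected; all other metrics
in the tested family are Holm–Bonferroni adjusted (step-down, monotone,
capped at 1).  Holm is used because it dominates plain Bonferroni without
distributional assumptions; the exact correction family is configurable
(default: every metric column) and recorded in the report.  Analyses run
per patient by default, with a pooled option.

## Internal container format

A `.sbrtplan` file is: the magic line `#SBRTPLAN 1`, a line with the JSON
header's byte length, the UTF-8 JSON header (origin/spacing/dims, structure
table, plan metadata), then raw little-endian float64 arrays in C order —
dose first, then each structure's occupancy in header order.  Write∘read is
the identity to full numeric precision; readers validate magic, header,
payload length and all plan invariants (occupancy range, ITV ⊆ PTV).

## Problem sizes and tolerances in the test suite

Unit and property tests run on small analytic grids (≤ 26³) and a coarse
phantom (2.5 mm pitch); pipeline-level tests regenerate the full 57-plan
cohort on the 2 mm phantoms, which takes ~30 s including phantom
construction.  Oracle comparisons use one DVH bin (0.1 Gy) for interpolated
dose quantiles, 1e-9 relative for threshold volumes and the normalization
anchor, and 1e-12 for algebraic index identities.  The acceptance script
regenerates everything from its `--seed` in well under a minute.

## Known limitations

* The dose model is radial; it cannot produce plans whose 45.2 Gy isodose
  is topologically disconnected from the PTV, nor realistic build-up
  regions.
* OAR doses are indicative only (see generator non-goals above).
* DICOM support covers axis-aligned RT Dose grids and planar contours;
  oblique orientations and 3D meshes are out of scope.
* The exact-permutation test enumerates all assignments and is limited to
  N ≤ 12 by design.
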