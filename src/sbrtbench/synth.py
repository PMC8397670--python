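"""Synthetic phantom patients and technique-flavoured dose distributions.

Two stylized thorax phantoms emulate the benchmark's two peripheral
early-stage lung lesions (ellipsoidal ITV, isotropic 5 mm ITV-to-PTV margin,
PTV sizes of about 23.8 and 19.4 cm^3, lungs / chest-wall shell / spinal
canal / esophagus as organs at risk).  Dose is modelled geometrically as a
function of the signed Euclidean distance to the PTV surface rather than by
beam transport: the downstream analytics only ever see the resulting dose
field, so a calibrated falloff model is sufficient.

The radial dose profile (in units of the mean ITV dose, i.e. of the
prescription anchor) is

* inside the ITV: a centrally peaked hot spot
  ``g = h - (h - L_itv) * rho^kappa`` with ``rho`` the normalized ellipsoid
  radius, ``h`` the peak (``hotspot_factor``) and ``L_itv`` the ITV surface
  level;
* across the ITV->PTV margin: a monotone bridge
  ``g = L_ptv + (L_itv - L_ptv) * (|sd|/margin)^q`` whose exponent ``q``
  controls how much of the margin stays near the ITV level (the main
  technique discriminator for the mean PTV dose);
* outside the PTV: a two-component falloff
  ``g = L_ptv * [(1 - tau) * 2^(-s/f_near) + tau * 2^(-(s/f_tail)^1.5)]``
  -- a steep penumbra plus a sub-exponential low-dose bath.  ``f_near`` is
  solved so that the profile reaches 50% of the PTV-surface level exactly at
  ``falloff_scale_mm``, which therefore directly steers the gradient index.

``penumbra_asymmetry`` stretches the falloff along +z and compresses it
along -z, emulating the direction-dependent penumbra of real beam
arrangements.  Gaussian-correlated noise (clipped at zero dose) and small
seeded per-plan parameter jitter emulate interinstitutional variation.

Default technique profiles are frozen after a one-off calibration
(``scripts/calibrate_profiles.py``) so that, after mean-ITV normalization,
plans meet all protocol objectives with CI_RTOG in [1.05, 1.2], GI in
[3.4, 6.7] and per-technique mean PTV doses ordered RRS < MOD < 3D.

Seeding is counter-based: a cohort master seed is the Philox key and the
plan index the Philox counter, so cohorts are reproducible and
order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, optimize

from .grids import (
    Algorithm,
    DoseGrid,
    GeometryError,
    Plan,
    PlanMeta,
    StructureMask,
    StructureRole,
    Technique,
)

__all__ = [
    "OarLayout",
    "PhantomSpec",
    "Phantom",
    "TechniqueProfile",
    "DEFAULT_PROFILES",
    "patient_1_spec",
    "patient_2_spec",
    "make_phantom",
    "default_phantoms",
    "make_dose",
    "make_cohort",
    "make_study_cohort",
    "STUDY_GROUP_SIZES",
    "STUDY_ALGORITHM_COUNTS",
]

_SUPERSAMPLE = 2  # linear supersampling factor for mask rasterization


# --------------------------------------------------------------------------- #
# phantom geometry


@dataclass
class OarLayout:
    """Stylized thorax: ellipsoidal cavity, shell-like chest wall, cylinders.

    The thorax is an ellipsoid; the chest wall is the radial band just
    outside its surface; the lungs are the interior minus a mediastinal slab,
    split into ipsi- and contralateral halves by the lesion side; spinal
    canal and esophagus are z-aligned cylinders.
    """

    thorax_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    thorax_semi_axes: tuple[float, float, float] = (78.0, 70.0, 95.0)
    shell_outer_ratio: float = 1.10
    lung_inner_ratio: float = 0.985
    mediastinum_halfwidth_mm: float = 16.0
    canal_center_xy: tuple[float, float] = (0.0, 62.0)
    canal_radius_mm: float = 5.0
    esophagus_center_xy: tuple[float, float] = (10.0, 18.0)
    esophagus_radius_mm: float = 5.0


@dataclass
class PhantomSpec:
    """Geometry of one phantom patient."""

    name: str
    itv_semi_axes: tuple[float, float, float]
    itv_center: tuple[float, float, float]
    margin_mm: float = 5.0
    origin: tuple[float, float, float] = (-95.0, -95.0, -79.0)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    dims: tuple[int, int, int] = (96, 96, 80)
    target_ptv_volume_cm3: float | None = None
    oar: OarLayout = field(default_factory=OarLayout)

    def cache_key(self) -> str:
        return repr(
            (
                self.name,
                self.itv_semi_axes,
                self.itv_center,
                self.margin_mm,
                self.origin,
                self.spacing,
                self.dims,
                self.target_ptv_volume_cm3,
            )
        )


def patient_1_spec() -> PhantomSpec:
    """Peripheral left-upper-lobe lesion, PTV close to the chest wall (~23.8 cm^3)."""
    return PhantomSpec(
        name="patient1",
        itv_semi_axes=(13.5, 12.0, 14.5),
        itv_center=(-56.0, -8.0, 22.0),
        target_ptv_volume_cm3=23.8,
    )


def patient_2_spec() -> PhantomSpec:
    """Peripheral right-lower-lobe lesion, chest wall distant (~19.4 cm^3)."""
    return PhantomSpec(
        name="patient2",
        itv_semi_axes=(12.5, 11.5, 13.0),
        itv_center=(44.0, 0.0, -24.0),
        target_ptv_volume_cm3=19.4,
    )


@dataclass
class Phantom:
    """Plan skeleton: structure masks plus cached geometry fields.

    ``sd_ptv_mm`` is the signed Euclidean distance to the PTV surface
    (negative inside) at voxel centres; ``rho_itv`` the normalized ellipsoid
    radius of the ITV (1 on the ITV surface).  Both are reused by every dose
    realization on the phantom.
    """

    spec: PhantomSpec
    masks: dict[StructureRole, StructureMask]
    sd_ptv_mm: np.ndarray
    rho_itv: np.ndarray

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.spec.origin, dtype=float)

    @property
    def spacing(self) -> np.ndarray:
        return np.asarray(self.spec.spacing, dtype=float)

    def volume_cm3(self, role: StructureRole) -> float:
        m = self.masks[role]
        return float(m.occupancy.sum()) * float(np.prod(self.spacing)) / 1000.0


def _axes_coords(origin, spacing, dims, k: int = 1):
    """Voxel-centre coordinates along each axis, optionally supersampled k-fold."""
    out = []
    for a in range(3):
        if k == 1:
            out.append(origin[a] + spacing[a] * np.arange(dims[a]))
        else:
            # subcell centres: voxel spans [c - s/2, c + s/2], split into k subcells
            base = origin[a] + spacing[a] * np.arange(dims[a])
            off = (np.arange(k) + 0.5) / k - 0.5
            out.append((base[:, None] + spacing[a] * off[None, :]).ravel())
    return out


def _block_mean(fine: np.ndarray, k: int) -> np.ndarray:
    nx, ny, nz = (s // k for s in fine.shape)
    return (
        fine.reshape(nx, k, ny, k, nz, k).mean(axis=(1, 3, 5))
        if k > 1
        else fine.astype(np.float64)
    )


def make_phantom(spec: PhantomSpec, seed: int = 0) -> Phantom:
    """Build the structure masks and geometry fields of one phantom patient.

    Deterministic given (spec, seed); the seed is reserved for future
    stochastic anatomy and currently unused.  If ``target_ptv_volume_cm3``
    is set, the ITV semi-axes are rescaled (bisection on the scale factor)
    until the dilated PTV volume matches within 1%.
    """
    del seed  # anatomy is deterministic
    origin = np.asarray(spec.origin, float)
    spacing = np.asarray(spec.spacing, float)
    dims = tuple(spec.dims)
    k = _SUPERSAMPLE
    fx, fy, fz = _axes_coords(origin, spacing, dims, k)
    fine_spacing = spacing / k
    fine_voxvol_cm3 = float(np.prod(fine_spacing)) / 1000.0
    c = np.asarray(spec.itv_center, float)
    ax = np.asarray(spec.itv_semi_axes, float)

    X = fx[:, None, None]
    Y = fy[None, :, None]
    Z = fz[None, None, :]

    def surface_distance(scale: float) -> np.ndarray:
        """First-order distance to the (scaled) ITV ellipsoid surface, mm.

        d = (rho - 1) * rho / |grad|, with rho the implicit ellipsoid radius;
        exact for spheres and accurate to well below the lattice pitch for
        moderate aspect ratios.  Negative inside.
        """
        a = scale * ax
        u0, u1, u2 = (X - c[0]) / a[0], (Y - c[1]) / a[1], (Z - c[2]) / a[2]
        rho = np.sqrt(u0**2 + u1**2 + u2**2)
        gnum = np.sqrt((u0 / a[0]) ** 2 + (u1 / a[1]) ** 2 + (u2 / a[2]) ** 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            d = (rho - 1.0) * rho / gnum
        return np.where(gnum > 0, d, -float(a.min()))

    def ptv_volume(scale: float) -> tuple[float, np.ndarray, np.ndarray]:
        d = surface_distance(scale)
        itv = d <= 0.0
        ptv = d <= spec.margin_mm
        return float(ptv.sum()) * fine_voxvol_cm3, itv, ptv

    scale = 1.0
    vol, itv_f, ptv_f = ptv_volume(scale)
    if spec.target_ptv_volume_cm3 is not None:
        target = spec.target_ptv_volume_cm3
        lo, hi = 0.3, 2.5
        for _ in range(40):
            if abs(vol - target) / target <= 0.01:
                break
            if vol < target:
                lo = scale
            else:
                hi = scale
            scale = 0.5 * (lo + hi)
            vol, itv_f, ptv_f = ptv_volume(scale)

    if not itv_f.any():
        raise GeometryError("ITV does not intersect the lattice")
    bnd = (
        ptv_f[0].any()
        or ptv_f[-1].any()
        or ptv_f[:, 0].any()
        or ptv_f[:, -1].any()
        or ptv_f[:, :, 0].any()
        or ptv_f[:, :, -1].any()
    )
    if bnd:
        raise GeometryError("PTV touches the lattice boundary; enlarge the lattice")

    # signed distance to PTV surface on the fine lattice, block-averaged down
    d_out = ndimage.distance_transform_edt(~ptv_f, sampling=fine_spacing)
    d_in = ndimage.distance_transform_edt(ptv_f, sampling=fine_spacing)
    sd = _block_mean(d_out - d_in, k)

    # OARs on the fine lattice as well, so shells get fractional edges
    oar = spec.oar
    tc = np.asarray(oar.thorax_center, float)
    ta = np.asarray(oar.thorax_semi_axes, float)
    R = np.sqrt(
        ((X - tc[0]) / ta[0]) ** 2 + ((Y - tc[1]) / ta[1]) ** 2 + ((Z - tc[2]) / ta[2]) ** 2
    )
    shell = (R >= 1.0) & (R <= oar.shell_outer_ratio)
    interior = R < oar.lung_inner_ratio
    ipsi_sign = math.copysign(1.0, c[0] - tc[0])
    side = ipsi_sign * (X - tc[0]) > oar.mediastinum_halfwidth_mm
    far_side = -ipsi_sign * (X - tc[0]) > oar.mediastinum_halfwidth_mm
    canal = (X - oar.canal_center_xy[0]) ** 2 + (Y - oar.canal_center_xy[1]) ** 2 <= (
        oar.canal_radius_mm**2
    )
    eso = (X - oar.esophagus_center_xy[0]) ** 2 + (Y - oar.esophagus_center_xy[1]) ** 2 <= (
        oar.esophagus_radius_mm**2
    )
    lung_ipsi = interior & side & ~itv_f
    lung_contra = interior & far_side

    occ = {
        StructureRole.ITV: _block_mean(itv_f, k),
        StructureRole.PTV: _block_mean(ptv_f, k),
        StructureRole.LUNG_IPSI: _block_mean(lung_ipsi, k),
        StructureRole.LUNG_CONTRA: _block_mean(lung_contra, k),
        StructureRole.CHEST_WALL: _block_mean(shell, k),
        StructureRole.SPINAL_CANAL: _block_mean(canal & (R < 1.05), k),
        StructureRole.ESOPHAGUS: _block_mean(eso & interior, k),
    }
    names = {
        StructureRole.ITV: "ITV",
        StructureRole.PTV: "PTV",
        StructureRole.LUNG_IPSI: "Lung_ipsi",
        StructureRole.LUNG_CONTRA: "Lung_contra",
        StructureRole.CHEST_WALL: "Chest_wall",
        StructureRole.SPINAL_CANAL: "Spinal_canal",
        StructureRole.ESOPHAGUS: "Esophagus",
    }
    masks = {
        role: StructureMask(
            name=names[role], role=role, origin=origin, spacing=spacing, occupancy=o
        )
        for role, o in occ.items()
    }

    bx, by, bz = _axes_coords(origin, spacing, dims, 1)
    rho = np.sqrt(
        ((bx[:, None, None] - c[0]) / (scale * ax[0])) ** 2
        + ((by[None, :, None] - c[1]) / (scale * ax[1])) ** 2
        + ((bz[None, None, :] - c[2]) / (scale * ax[2])) ** 2
    )
    return Phantom(spec=spec, masks=masks, sd_ptv_mm=sd, rho_itv=rho)


_PHANTOM_CACHE: dict[str, Phantom] = {}


def default_phantoms() -> dict[str, Phantom]:
    """The two study phantoms, built once per process and cached."""
    out = {}
    for spec in (patient_1_spec(), patient_2_spec()):
        key = spec.cache_key()
        if key not in _PHANTOM_CACHE:
            _PHANTOM_CACHE[key] = make_phantom(spec)
        out[spec.name] = _PHANTOM_CACHE[key]
    return out


# --------------------------------------------------------------------------- #
# dose model


@dataclass(frozen=True)
class TechniqueProfile:
    """Shape parameters of the technique-flavoured dose model.

    Levels are in units of the prescription anchor (mean ITV dose).
    ``jitter_*`` are the per-plan interinstitutional variation scales; a
    ``jitter_scale`` of 0 freezes the profile at its nominal values.
    """

    technique: Technique
    hotspot_factor: float = 1.05  # peak-to-prescription ratio inside the ITV
    falloff_scale_mm: float = 11.0  # distance from PTV-surface level to its 50%
    penumbra_asymmetry: float = 0.12  # +z stretch / -z compression of the falloff
    noise_sd_gy: float = 0.35
    itv_surface_rel: float = 0.945
    ptv_surface_rel: float = 0.74
    margin_exponent: float = 1.0
    hotspot_shape: float = 3.3  # radial exponent kappa of the central hot spot
    tail_fraction: float = 0.18
    tail_ratio: float = 1.7  # f_tail / falloff_scale
    jitter_surface: float = 0.006
    jitter_falloff: float = 0.04
    jitter_hotspot: float = 0.005
    jitter_exponent: float = 0.15
    jitter_asym: float = 0.04
    jitter_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.hotspot_factor < 1:
            raise ValueError("hotspot_factor must be >= 1")
        if self.falloff_scale_mm <= 0:
            raise ValueError("falloff_scale_mm must be > 0")


# Frozen defaults; see scripts/calibrate_profiles.py for the calibration run.
DEFAULT_PROFILES: dict[Technique, TechniqueProfile] = {
    Technique.RRS: TechniqueProfile(
        technique=Technique.RRS,
        hotspot_factor=1.042,
        falloff_scale_mm=10.8,
        penumbra_asymmetry=0.08,
        noise_sd_gy=0.45,
        ptv_surface_rel=0.732,
        margin_exponent=2.20,
    ),
    Technique.MOD: TechniqueProfile(
        technique=Technique.MOD,
        hotspot_factor=1.042,
        falloff_scale_mm=10.9,
        penumbra_asymmetry=0.12,
        noise_sd_gy=0.35,
        ptv_surface_rel=0.737,
        margin_exponent=1.70,
    ),
    Technique.THREE_D: TechniqueProfile(
        technique=Technique.THREE_D,
        hotspot_factor=1.047,
        falloff_scale_mm=11.8,
        penumbra_asymmetry=0.20,
        noise_sd_gy=0.30,
        ptv_surface_rel=0.738,
        margin_exponent=1.15,
    ),
}

_NOMINAL_GY = 64.5  # prescription anchor the profile levels refer to


def _near_scale(f50: float, tau: float, ratio: float) -> float:
    """Solve for f_near so the falloff reaches 50% exactly at f50 mm."""
    if math.isinf(f50):
        return math.inf
    f_tail = ratio * f50

    def g(fn: float) -> float:
        return (
            (1 - tau) * 2.0 ** (-f50 / fn) + tau * 2.0 ** (-((f50 / f_tail) ** 1.5)) - 0.5
        )

    return float(optimize.brentq(g, 1e-3, 100 * f50))


def make_dose(
    phantom: Phantom,
    profile: TechniqueProfile,
    seed: int | np.random.Generator,
    meta: PlanMeta | None = None,
) -> Plan:
    """One synthetic dose realization on a phantom; deterministic given the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    js = profile.jitter_scale
    L_ptv = profile.ptv_surface_rel + js * profile.jitter_surface * rng.standard_normal()
    f50 = profile.falloff_scale_mm * math.exp(js * profile.jitter_falloff * rng.standard_normal())
    h = max(1.0, profile.hotspot_factor + js * profile.jitter_hotspot * rng.standard_normal())
    q = max(0.1, profile.margin_exponent + js * profile.jitter_exponent * rng.standard_normal())
    asym = profile.penumbra_asymmetry + js * profile.jitter_asym * rng.standard_normal()
    L_itv = profile.itv_surface_rel
    m = max(phantom.spec.margin_mm, 1e-6)

    sd = phantom.sd_ptv_mm
    rho = phantom.rho_itv
    g = np.empty_like(sd)

    inside_itv = rho <= 1.0
    outside = (sd >= 0.0) & ~inside_itv
    margin = ~inside_itv & ~outside

    g[inside_itv] = h - (h - L_itv) * np.clip(rho[inside_itv], 0.0, 1.0) ** profile.hotspot_shape
    x = np.clip(-sd[margin] / m, 0.0, 1.0)
    g[margin] = L_ptv + (L_itv - L_ptv) * x**q

    # direction-dependent penumbra: stretch the distance coordinate along -z
    c = np.asarray(phantom.spec.itv_center, float)
    bx, by, bz = _axes_coords(phantom.origin, phantom.spacing, phantom.spec.dims, 1)
    dx = bx[:, None, None] - c[0]
    dy = by[None, :, None] - c[1]
    dz = bz[None, None, :] - c[2]
    r = np.sqrt(dx**2 + dy**2 + dz**2)
    cz = np.divide(dz * np.ones_like(r), r, out=np.zeros_like(r), where=r > 1e-9)
    stretch = np.clip(1.0 + asym * cz, 0.5, 2.0)
    s_eff = sd[outside] / stretch[outside]

    if math.isinf(f50):
        g[outside] = L_ptv
    else:
        tau = profile.tail_fraction
        f_tail = profile.tail_ratio * f50
        fn = _near_scale(f50, tau, profile.tail_ratio)
        g[outside] = L_ptv * (
            (1 - tau) * 2.0 ** (-s_eff / fn) + tau * 2.0 ** (-((s_eff / f_tail) ** 1.5))
        )

    dose = _NOMINAL_GY * g
    if profile.noise_sd_gy > 0:
        noise = rng.standard_normal(dose.shape)
        noise = ndimage.gaussian_filter(noise, sigma=1.2)
        noise *= profile.noise_sd_gy / noise.std()
        dose = dose + noise
    np.clip(dose, 0.0, None, out=dose)

    grid = DoseGrid(origin=phantom.origin, spacing=phantom.spacing, dose=dose)
    return Plan(
        grid=grid,
        structures=dict(phantom.masks),
        meta=meta or PlanMeta(patient_id=phantom.spec.name),
    )


# --------------------------------------------------------------------------- #
# cohorts

STUDY_GROUP_SIZES: dict[Technique, int] = {
    Technique.RRS: 8,
    Technique.MOD: 34,
    Technique.THREE_D: 15,
}

# Submission-pool algorithm mix per technique (robotic units are Monte Carlo
# only; modulated plans split between Boltzmann-transport and AAA; 3D plans
# mostly collapsed cone; pencil beam appears in a handful of submissions).
STUDY_ALGORITHM_COUNTS: dict[Technique, dict[Algorithm, int]] = {
    Technique.RRS: {Algorithm.MC: 8},
    Technique.MOD: {Algorithm.BT: 15, Algorithm.AAA: 14, Algorithm.MC: 3, Algorithm.PB: 2},
    Technique.THREE_D: {
        Algorithm.CC: 10,
        Algorithm.BT: 1,
        Algorithm.MC: 1,
        Algorithm.AAA: 1,
        Algorithm.PB: 2,
    },
}


def _algorithm_sequence(counts: dict[Algorithm, int], n: int) -> list[Algorithm]:
    """Expand an algorithm count table to n labels (largest-remainder rescale)."""
    total = sum(counts.values())
    if total == n:
        seq: list[Algorithm] = []
        for alg, cnt in counts.items():
            seq.extend([alg] * cnt)
        return seq
    quotas = {alg: cnt * n / total for alg, cnt in counts.items()}
    base = {alg: int(math.floor(qt)) for alg, qt in quotas.items()}
    rem = n - sum(base.values())
    order = sorted(quotas, key=lambda a: quotas[a] - base[a], reverse=True)
    for alg in order[:rem]:
        base[alg] += 1
    seq = []
    for alg, cnt in base.items():
        seq.extend([alg] * cnt)
    return seq


def _plan_rng(master_seed: int, plan_index: int) -> np.random.Generator:
    """Counter-based per-plan substream: master seed is the key, plan index the counter."""
    return np.random.Generator(
        np.random.Philox(key=int(master_seed), counter=[0, 0, 0, int(plan_index)])
    )


def make_cohort(
    n_per_group: dict[Technique, int] | tuple[int, int, int],
    master_seed: int,
    profiles: dict[Technique, TechniqueProfile] | None = None,
    phantoms: dict[str, Phantom] | None = None,
    algorithm_counts: dict[Technique, dict[Algorithm, int]] | None = None,
    profile_overrides: dict[int, TechniqueProfile] | None = None,
) -> list[Plan]:
    """Generate a plan cohort with metadata, reproducible from the master seed.

    Plans are grouped by technique; each synthetic institution contributes a
    pair of plans (one per phantom patient) with a common technique and
    algorithm.  ``profile_overrides`` maps global plan indices to replacement
    profiles (used e.g. to plant protocol deviations).
    """
    if isinstance(n_per_group, (tuple, list)):
        n_per_group = dict(zip((Technique.RRS, Technique.MOD, Technique.THREE_D), n_per_group))
    if not n_per_group or any(n < 1 for n in n_per_group.values()):
        raise ValueError("each technique group needs at least one plan")
    profiles = profiles or DEFAULT_PROFILES
    phantoms = phantoms or default_phantoms()
    algorithm_counts = algorithm_counts or STUDY_ALGORITHM_COUNTS
    overrides = profile_overrides or {}
    patient_names = sorted(phantoms)

    plans: list[Plan] = []
    idx = 0
    for tech, n in n_per_group.items():
        tech = Technique(tech)
        algs = _algorithm_sequence(algorithm_counts[tech], n)
        for j in range(n):
            inst = f"{tech.value}-{j // len(patient_names) + 1:02d}"
            patient = patient_names[j % len(patient_names)]
            alg = algs[j]
            meta = PlanMeta(
                institution_id=inst,
                technique=tech,
                algorithm=alg,
                calc_grid_mm=2.0,
                mlc_width_mm=None if tech is Technique.RRS else 5.0,
                energy_label="6 MV FFF" if tech is Technique.RRS else "6 MV FF",
                patient_id=patient,
            )
            profile = overrides.get(idx, profiles[tech])
            plans.append(make_dose(phantoms[patient], profile, _plan_rng(master_seed, idx), meta))
            idx += 1
    return plans


def make_study_cohort(
    master_seed: int, phantoms: dict[str, Phantom] | None = None
) -> tuple[list[Plan], dict]:
    """The 57-plan benchmark cohort: 8 RRS / 34 MOD / 15 3D submissions.

    Four plans carry a pencil-beam label (excluded from analysis by rule) and
    one modulated plan is generated non-conformally so that it violates the
    conformity objective -- mirroring the composition of the benchmark pool.
    Returns the plans plus a description of the planted exclusions.
    """
    # plan indices: RRS 0..7, MOD 8..41, 3D 42..56 (PB labels fall where the
    # algorithm sequence places them; located after generation below)
    bad_ci = replace(
        DEFAULT_PROFILES[Technique.MOD],
        ptv_surface_rel=0.80,
        falloff_scale_mm=12.5,
        noise_sd_gy=0.2,
        jitter_scale=0.0,
    )
    violation_idx = 30  # a modulated AAA plan, patient1
    plans = make_cohort(
        STUDY_GROUP_SIZES,
        master_seed,
        phantoms=phantoms,
        profile_overrides={violation_idx: bad_ci},
    )
    pb = [i for i, p in enumerate(plans) if p.meta.algorithm is Algorithm.PB]
    planted = {
        "pb_plan_indices": pb,
        "constraint_violation_index": violation_idx,
        "n_total": len(plans),
        "n_expected_included": len(plans) - len(pb) - 1,
    }
    return plans, planted
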