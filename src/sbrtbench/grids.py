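"""Core lattice data model: dose grids, structure masks and plan metadata.

All spatial quantities are expressed in millimetres in patient-axis order
(x, y, z); arrays are indexed ``[ix, iy, iz]`` with 0-based indices, and a
voxel's dose is attributed to its centre.  Structure occupancy is fractional
in [0, 1] on the *same* lattice as the dose, so every downstream metric is
occupancy-weighted; the analytics never resample silently.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
import numpy as np
from scipy import ndimage

__all__ = [
    "GeometryError",
    "StructureRole",
    "Technique",
    "Algorithm",
    "DoseGrid",
    "StructureMask",
    "PlanMeta",
    "Plan",
    "volume",
    "resample_trilinear",
]


class GeometryError(ValueError):
    """Dose grid and structure mask do not share a lattice, or a lattice is invalid."""


class StructureRole(str, enum.Enum):
    ITV = "ITV"
    PTV = "PTV"
    LUNG_IPSI = "LUNG_IPSI"
    LUNG_CONTRA = "LUNG_CONTRA"
    CHEST_WALL = "CHEST_WALL"
    SPINAL_CANAL = "SPINAL_CANAL"
    ESOPHAGUS = "ESOPHAGUS"
    OTHER = "OTHER"


class Technique(str, enum.Enum):
    """SBRT delivery technique class."""

    RRS = "RRS"  # robotic radiosurgery (cone-based)
    MOD = "MOD"  # modulated: static IMRT and arc (VMAT)
    THREE_D = "3D"  # 3D-conformal and conformal arc


class Algorithm(str, enum.Enum):
    """Dose-calculation algorithm class."""

    MC = "MC"  # Monte Carlo
    BT = "BT"  # linear Boltzmann transport solver
    CC = "CC"  # collapsed cone
    AAA = "AAA"  # analytical anisotropic algorithm
    PB = "PB"  # pencil beam (non-compliant for lung SBRT)


def _as_vec3(v, name: str, dtype=float) -> np.ndarray:
    arr = np.asarray(v, dtype=dtype)
    if arr.shape != (3,):
        raise GeometryError(f"{name} must be a 3-vector, got shape {arr.shape}")
    return arr


@dataclass
class DoseGrid:
    """Regular 3D lattice of absorbed dose in Gy.

    Parameters
    ----------
    origin
        World position of the centre of voxel (0, 0, 0), mm.
    spacing
        Voxel pitch along (x, y, z), mm, strictly positive.
    dose
        Dose array in Gy, shape ``(nx, ny, nz)``, finite and non-negative.
    """

    origin: np.ndarray
    spacing: np.ndarray
    dose: np.ndarray

    def __post_init__(self) -> None:
        self.origin = _as_vec3(self.origin, "origin")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be > 0, got {self.spacing}")
        self.dose = np.asarray(self.dose, dtype=np.float64)
        if self.dose.ndim != 3:
            raise GeometryError(f"dose must be 3D, got ndim={self.dose.ndim}")
        if not np.all(np.isfinite(self.dose)):
            raise ValueError("dose contains non-finite values")
        if np.any(self.dose < 0):
            raise ValueError("dose contains negative values")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.dose.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def same_lattice(self, other: "DoseGrid | StructureMask", atol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.spacing, other.spacing, atol=atol)
        )

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centres along one axis, mm."""
        n = self.dims[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)


@dataclass
class StructureMask:
    """Fractional voxel occupancy of one anatomical structure.

    Lives on the same lattice as its paired :class:`DoseGrid`; each occupancy
    value is the fraction of the voxel covered by the structure.
    """

    name: str
    role: StructureRole
    origin: np.ndarray
    spacing: np.ndarray
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        self.role = StructureRole(self.role)
        self.origin = _as_vec3(self.origin, "origin")
        self.spacing = _as_vec3(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be > 0, got {self.spacing}")
        self.occupancy = np.asarray(self.occupancy, dtype=np.float64)
        if self.occupancy.ndim != 3:
            raise GeometryError("occupancy must be 3D")
        if not np.all(np.isfinite(self.occupancy)):
            raise ValueError(f"structure {self.name!r}: occupancy contains non-finite values")
        if np.any(self.occupancy < -1e-9) or np.any(self.occupancy > 1 + 1e-9):
            raise ValueError(f"structure {self.name!r}: occupancy outside [0, 1]")
        np.clip(self.occupancy, 0.0, 1.0, out=self.occupancy)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.occupancy.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class PlanMeta:
    """Grouping variables of a submitted plan."""

    institution_id: str = ""
    technique: Technique = Technique.MOD
    algorithm: Algorithm = Algorithm.MC
    calc_grid_mm: float = 2.0
    mlc_width_mm: float | None = None  # absent for cone-based robotic delivery
    energy_label: str = "6 MV FF"
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.technique = Technique(self.technique)
        self.algorithm = Algorithm(self.algorithm)


@dataclass
class Plan:
    """Unit of analysis: a dose grid with its structure set and metadata.

    Must contain at least ITV and PTV masks, with ITV contained in PTV up to
    rasterization tolerance (less than 1% of the ITV occupancy outside PTV).
    """

    grid: DoseGrid
    structures: dict[StructureRole, StructureMask]
    meta: PlanMeta = field(default_factory=PlanMeta)

    def __post_init__(self) -> None:
        self.structures = {StructureRole(k): v for k, v in self.structures.items()}
        for role in (StructureRole.ITV, StructureRole.PTV):
            if role not in self.structures:
                raise ValueError(f"plan is missing required structure {role.value}")
        for role, mask in self.structures.items():
            if not self.grid.same_lattice(mask):
                raise GeometryError(
                    f"structure {mask.name!r} ({role.value}) is not on the dose lattice"
                )
        itv = self.structures[StructureRole.ITV].occupancy
        ptv = self.structures[StructureRole.PTV].occupancy
        itv_total = float(itv.sum())
        if itv_total <= 0:
            raise ValueError("ITV has zero volume")
        outside = float(np.maximum(itv - ptv, 0.0).sum())
        if outside / itv_total >= 0.01:
            raise ValueError(
                f"ITV is not contained in PTV: {100 * outside / itv_total:.2f}% of ITV outside"
            )

    def mask(self, role: StructureRole | str) -> StructureMask:
        role = StructureRole(role)
        try:
            return self.structures[role]
        except KeyError:
            raise KeyError(f"plan has no structure with role {role.value}") from None

    def with_dose(self, dose: np.ndarray) -> "Plan":
        """Copy of the plan with a replaced dose array (same lattice)."""
        return Plan(
            grid=replace(self.grid, dose=dose), structures=dict(self.structures), meta=self.meta
        )


def volume(mask: StructureMask) -> float:
    """Occupancy-weighted structure volume in cm^3."""
    return float(mask.occupancy.sum()) * mask.voxel_volume_mm3 / 1000.0


def resample_trilinear(
    values: np.ndarray,
    src_origin,
    src_spacing,
    dst_origin,
    dst_spacing,
    dst_dims: tuple[int, int, int],
    fill: float = 0.0,
) -> np.ndarray:
    """Trilinearly resample a scalar field onto a new lattice.

    Provided for ingestion (e.g. a dose grid coarser than the structure CT);
    core analytics never call this implicitly.
    """
    src_origin = _as_vec3(src_origin, "src_origin")
    src_spacing = _as_vec3(src_spacing, "src_spacing")
    dst_origin = _as_vec3(dst_origin, "dst_origin")
    dst_spacing = _as_vec3(dst_spacing, "dst_spacing")
    axes = [
        (dst_origin[a] + dst_spacing[a] * np.arange(dst_dims[a]) - src_origin[a]) / src_spacing[a]
        for a in range(3)
    ]
    ix, iy, iz = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([ix.ravel(), iy.ravel(), iz.ravel()])
    out = ndimage.map_coordinates(
        np.asarray(values, dtype=np.float64), coords, order=1, mode="constant", cval=fill
    )
    return out.reshape(dst_dims)
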