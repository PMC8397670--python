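"""Conformity and gradient indices.

All isodose volumes are occupancy-weighted voxel thresholds on the dose
lattice (no surface extraction); this is the documented volume convention.

With ``PIV`` the volume receiving at least the reference dose (the 70%
isodose of the 64.5 Gy prescription, printed as 45.2 Gy), ``TV`` the PTV
volume and ``TV_PIV`` the PTV volume inside the reference isodose:

* ``CI_RTOG   = PIV / TV``             (spillage-sensitive conformity)
* ``CI_Paddick = TV_PIV^2 / (PIV TV)`` (joint coverage / spillage, in [0, 1])
* ``GI = V(half reference) / PIV``     (low-dose-bath steepness, >= 1)

The half level defaults to the printed 22.6 Gy, i.e. exactly half the printed
45.2 Gy reference, not half the unrounded 45.15 Gy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dvh import volume_at_dose_cm3
from .grids import Plan, StructureRole

__all__ = [
    "REFERENCE_DOSE_GY",
    "IsodoseVolumes",
    "isodose_volumes",
    "ci_rtog",
    "ci_paddick",
    "gradient_index",
    "coverage_fraction",
]

REFERENCE_DOSE_GY = 45.2  # printed 70% threshold of the 64.5 Gy prescription


@dataclass(frozen=True)
class IsodoseVolumes:
    """Volumes (cm^3) entering the conformity/gradient indices."""

    piv: float  # total volume receiving >= reference dose
    tv: float  # PTV volume
    tv_piv: float  # PTV volume receiving >= reference dose
    half_piv: float  # total volume receiving >= half the reference dose

    def __post_init__(self) -> None:
        if self.tv_piv > min(self.piv, self.tv) + 1e-9:
            raise ValueError("tv_piv cannot exceed min(piv, tv)")
        if self.half_piv + 1e-9 < self.piv:
            raise ValueError("half_piv cannot be smaller than piv")


def isodose_volumes(plan: Plan, reference_dose_gy: float = REFERENCE_DOSE_GY) -> IsodoseVolumes:
    """Threshold-and-sum isodose volumes of a plan at the reference dose."""
    grid = plan.grid
    voxvol = grid.voxel_volume_cm3
    ptv = plan.mask(StructureRole.PTV)
    half = reference_dose_gy / 2.0
    piv = float(np.count_nonzero(grid.dose >= reference_dose_gy)) * voxvol
    half_piv = float(np.count_nonzero(grid.dose >= half)) * voxvol
    tv = float(ptv.occupancy.sum()) * voxvol
    tv_piv = volume_at_dose_cm3(grid, ptv, reference_dose_gy)
    return IsodoseVolumes(piv=piv, tv=tv, tv_piv=tv_piv, half_piv=half_piv)


def ci_rtog(vols: IsodoseVolumes) -> float:
    """RTOG conformity index PIV / TV."""
    if vols.tv <= 0:
        raise ValueError("PTV volume is zero")
    return vols.piv / vols.tv


def ci_paddick(vols: IsodoseVolumes) -> float:
    """Paddick conformity index TV_PIV^2 / (PIV * TV)."""
    if vols.tv <= 0:
        raise ValueError("PTV volume is zero")
    if vols.piv <= 0:
        raise ValueError("reference isodose volume is zero")
    return vols.tv_piv**2 / (vols.piv * vols.tv)


def gradient_index(vols: IsodoseVolumes) -> float:
    """Gradient index V(half reference) / V(reference); always >= 1."""
    if vols.piv <= 0:
        raise ValueError("reference isodose volume is zero")
    return vols.half_piv / vols.piv


def coverage_fraction(vols: IsodoseVolumes) -> float:
    """Fraction of the PTV covered by the reference isodose (TV_PIV / TV)."""
    if vols.tv <= 0:
        raise ValueError("PTV volume is zero")
    return vols.tv_piv / vols.tv
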