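"""Cumulative dose-volume histograms and DVH-derived point metrics.

The cumulative DVH is an occupancy-weighted histogram on a fixed dose grid
(default bin width 0.1 Gy): the volume at level ``e`` is the summed occupancy
of voxels with dose >= e, times the voxel volume.

Point-metric conventions
------------------------
* ``Dx%`` is the dose received by at least x% of the structure volume.  By
  default it is linearly interpolated between bin edges; a ``strict_bin``
  mode snaps to the bin edge instead (planning systems differ on this).
* ``D v ml`` is the analogous absolute-volume quantile (dose to the hottest
  v ml), ties broken toward the higher dose.
* ``Dmean`` and ``Dmedian`` are computed voxel-exactly from the occupancy
  weights, not from the binned curve, so that they can serve as exact
  normalization anchors free of 0.1 Gy quantization.
* ``V(d Gy)`` is reported as % of structure volume (voxel-exact); an
  absolute-volume variant returns cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import DoseGrid, GeometryError, StructureMask

__all__ = [
    "DVHCurve",
    "dvh",
    "dose_mean",
    "dose_quantile_pct",
    "dose_to_hottest_volume",
    "volume_at_dose_pct",
    "volume_at_dose_cm3",
    "dvh_to_csv",
]

DEFAULT_BIN_WIDTH_GY = 0.1


@dataclass
class DVHCurve:
    """Cumulative dose-volume curve at fixed bin width.

    ``cum_volume_cm3[i]`` is the structure volume receiving at least
    ``edges_gy[i]``; it is non-increasing and starts at the total volume.
    """

    bin_width_gy: float
    edges_gy: np.ndarray
    cum_volume_cm3: np.ndarray
    total_volume_cm3: float
    structure: str = ""

    def cum_volume_pct(self) -> np.ndarray:
        return 100.0 * self.cum_volume_cm3 / self.total_volume_cm3


def _check_pair(grid: DoseGrid, mask: StructureMask) -> None:
    if not grid.same_lattice(mask):
        raise GeometryError(f"structure {mask.name!r} is not on the dose lattice")


def dvh(
    grid: DoseGrid, mask: StructureMask, bin_width_gy: float = DEFAULT_BIN_WIDTH_GY
) -> DVHCurve:
    """Occupancy-weighted cumulative DVH of one structure."""
    _check_pair(grid, mask)
    occ = mask.occupancy
    w = occ[occ > 0]
    if w.size == 0:
        raise ValueError(f"structure {mask.name!r} has zero volume")
    d = grid.dose[occ > 0]
    voxvol = grid.voxel_volume_cm3
    n_bins = int(np.floor(d.max() / bin_width_gy)) + 1
    edges = bin_width_gy * np.arange(n_bins + 1)
    # histogram bins are right-open [e_i, e_{i+1}), so the reversed cumulative
    # sum at edge i is exactly the occupancy with dose >= e_i
    hist, _ = np.histogram(d, bins=np.append(edges, np.inf), weights=w)
    cum = np.cumsum(hist[::-1])[::-1] * voxvol
    total = float(w.sum()) * voxvol
    return DVHCurve(
        bin_width_gy=float(bin_width_gy),
        edges_gy=edges,
        cum_volume_cm3=cum,
        total_volume_cm3=total,
        structure=mask.name,
    )


def dose_mean(grid: DoseGrid, mask: StructureMask) -> float:
    """Voxel-exact occupancy-weighted mean structure dose, Gy."""
    _check_pair(grid, mask)
    occ = mask.occupancy
    total = occ.sum()
    if total <= 0:
        raise ValueError(f"structure {mask.name!r} has zero volume")
    return float((grid.dose * occ).sum() / total)


def _dose_at_cum_volume(curve: DVHCurve, target_cm3: float, strict_bin: bool) -> float:
    """Largest dose level at which the cumulative volume still reaches ``target_cm3``.

    Linear interpolation between the bracketing bin edges by default; ties
    (flat curve segments) resolve toward the higher dose.
    """
    cum = curve.cum_volume_cm3
    edges = curve.edges_gy
    if target_cm3 > curve.total_volume_cm3 * (1 + 1e-12):
        raise ValueError(
            f"requested volume {target_cm3:.4g} cm^3 exceeds structure volume "
            f"{curve.total_volume_cm3:.4g} cm^3"
        )
    # last index with cum >= target (cum is non-increasing)
    ge = np.nonzero(cum >= target_cm3 - 1e-15)[0]
    if ge.size == 0:
        return float(edges[0])
    i = int(ge[-1])
    if strict_bin or i + 1 >= len(cum):
        return float(edges[i])
    v_hi, v_lo = cum[i], cum[i + 1]
    if v_hi <= v_lo + 1e-15:
        return float(edges[i + 1])  # flat: tie toward higher dose
    frac = (v_hi - target_cm3) / (v_hi - v_lo)
    return float(edges[i] + frac * (edges[i + 1] - edges[i]))


def dose_quantile_pct(curve: DVHCurve, pct: float, strict_bin: bool = False) -> float:
    """``Dx%``: dose received by at least ``pct`` percent of the structure, Gy."""
    if not 0 < pct <= 100:
        raise ValueError(f"percentage must be in (0, 100], got {pct}")
    return _dose_at_cum_volume(curve, curve.total_volume_cm3 * pct / 100.0, strict_bin)


def dose_to_hottest_volume(curve: DVHCurve, v_cm3: float, strict_bin: bool = False) -> float:
    """``D v ml``: minimum dose within the hottest ``v_cm3`` of the structure, Gy."""
    if v_cm3 <= 0:
        raise ValueError(f"volume must be > 0, got {v_cm3}")
    return _dose_at_cum_volume(curve, v_cm3, strict_bin)


def volume_at_dose_cm3(grid: DoseGrid, mask: StructureMask, dose_gy: float) -> float:
    """``V(d)`` in absolute cm^3: occupancy-weighted volume with dose >= d."""
    if dose_gy < 0:
        raise ValueError(f"dose level must be >= 0, got {dose_gy}")
    _check_pair(grid, mask)
    sel = grid.dose >= dose_gy
    return float(mask.occupancy[sel].sum()) * grid.voxel_volume_cm3


def volume_at_dose_pct(grid: DoseGrid, mask: StructureMask, dose_gy: float) -> float:
    """``V(d)`` as % of the structure volume."""
    total = float(mask.occupancy.sum()) * grid.voxel_volume_cm3
    if total <= 0:
        raise ValueError(f"structure {mask.name!r} has zero volume")
    return 100.0 * volume_at_dose_cm3(grid, mask, dose_gy) / total


def dvh_to_csv(curve: DVHCurve) -> str:
    """Render a DVH curve as CSV: dose edge, cumulative cm^3, cumulative %."""
    lines = ["dose[Gy],volume[cm3],volume[%]"]
    pct = curve.cum_volume_pct()
    for e, v, p in zip(curve.edges_gy, curve.cum_volume_cm3, pct):
        lines.append(f"{e:.6g},{v:.9g},{p:.9g}")
    return "\n".join(lines) + "\n"
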