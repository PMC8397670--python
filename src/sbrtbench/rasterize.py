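"""Planar-contour rasterization onto the dose lattice.

Structures arrive as stacks of closed planar polygons (DICOM RT Structure
Set convention).  Two reproducible policies are offered, because planning
systems disagree on partial-volume handling:

* ``fractional`` (default): each voxel is supersampled k x k x k (k = 3);
  a subsample point counts as inside when its z lies within the slab of a
  contour plane (half the contour plane spacing on either side) and its
  (x, y) falls inside an odd number of that plane's polygons (even-odd
  rule, so holes work).  Occupancy is the inside fraction.
* ``binary``: voxel centres only, occupancy 0 or 1 -- mimics coarser
  planning systems.
"""

from __future__ import annotations

import numpy as np
from matplotlib.path import Path

__all__ = ["rasterize_contours"]


def _contour_plane_spacing(z_levels: np.ndarray, fallback: float) -> float:
    uniq = np.unique(np.round(z_levels, 6))
    if uniq.size < 2:
        return fallback
    return float(np.median(np.diff(uniq)))


def rasterize_contours(
    contours: list[np.ndarray],
    origin,
    spacing,
    dims: tuple[int, int, int],
    mode: str = "fractional",
    supersample: int = 3,
) -> np.ndarray:
    """Rasterize closed planar polygons to fractional occupancy.

    Parameters
    ----------
    contours
        List of (n_points, 3) world-coordinate arrays (mm), each planar in z.
    mode
        "fractional" (k^3 supersampling) or "binary" (voxel centres only).

    Returns the occupancy array with the lattice's dims.
    """
    if not contours:
        raise ValueError("structure has no contours")
    origin = np.asarray(origin, float)
    spacing = np.asarray(spacing, float)
    if mode == "binary":
        supersample = 1
    elif mode != "fractional":
        raise ValueError(f"unknown rasterization mode {mode!r}")
    k = max(1, int(supersample))

    z_levels = np.array([float(np.mean(c[:, 2])) for c in contours])
    slab = _contour_plane_spacing(z_levels, spacing[2])
    # group polygons by contour plane; even-odd (hole) logic applies within a
    # plane, never across planes
    planes: dict[float, list[Path]] = {}
    for c, zc in zip(contours, z_levels):
        c = np.asarray(c, float)
        if c.ndim != 2 or c.shape[1] != 3 or c.shape[0] < 3:
            raise ValueError("each contour must be an (n>=3, 3) point array")
        key = round(zc, 3)
        planes.setdefault(key, []).append(Path(c[:, :2], closed=True))
    plane_zs = np.array(sorted(planes))

    nx, ny, nz = dims
    occ_fine = np.zeros((nx * k, ny * k, nz * k), dtype=np.uint8)
    off = (np.arange(k) + 0.5) / k - 0.5
    fz = (origin[2] + spacing[2] * (np.arange(nz)[:, None] + off[None, :])).ravel()
    fx = (origin[0] + spacing[0] * (np.arange(nx)[:, None] + off[None, :])).ravel()
    fy = (origin[1] + spacing[1] * (np.arange(ny)[:, None] + off[None, :])).ravel()
    XX, YY = np.meshgrid(fx, fy, indexing="ij")
    pts = np.column_stack([XX.ravel(), YY.ravel()])

    # each fine z belongs to the nearest contour plane (within half a slab);
    # within that plane, a point is inside if it falls in an odd number of
    # polygons
    plane_cache: dict[float, np.ndarray] = {}
    for iz, z in enumerate(fz):
        j = int(np.argmin(np.abs(plane_zs - z)))
        zc = plane_zs[j]
        if abs(z - zc) > slab / 2 + 1e-9:
            continue
        if zc not in plane_cache:
            parity = np.zeros(len(pts), dtype=bool)
            for path in planes[zc]:
                parity ^= path.contains_points(pts)
            plane_cache[zc] = parity.reshape(nx * k, ny * k)
        occ_fine[:, :, iz] = plane_cache[zc]

    occ = occ_fine.reshape(nx, k, ny, k, nz, k).mean(axis=(1, 3, 5))
    return occ
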