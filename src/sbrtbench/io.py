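"""Plan I/O: the internal single-file container and DICOM-RT ingestion.

Internal container (``.sbrtplan``)
----------------------------------
A single file with a self-describing text header followed by raw arrays::

    line 1:  b"#SBRTPLAN 1\\n"                      (magic + format version)
    line 2:  ASCII integer: byte length of the JSON header, then b"\\n"
    next:    UTF-8 JSON header
    then:    raw little-endian float64 arrays, C order, concatenated:
             dose first, then each structure's occupancy in header order.

The JSON header records origin/spacing/dims, the structure table
(name + role) and the plan metadata; a write/read round trip is the
identity on all fields to full numeric precision.

DICOM-RT
--------
``read_dicom_rt`` ingests an RT Dose / RT Structure Set pair referring to a
common frame of reference: dose is rescaled to Gy via the dose-grid scaling
attribute, contours are rasterized onto the dose lattice (see
:mod:`sbrtbench.rasterize`) and structure roles are assigned through a
configurable name-mapping table, since institutional naming varies.
"""

from __future__ import annotations

import json
import os
import re
from typing import Mapping

import numpy as np

from .grids import DoseGrid, GeometryError, Plan, PlanMeta, StructureMask, StructureRole
from .rasterize import rasterize_contours

__all__ = [
    "ParseError",
    "IngestionError",
    "write_internal",
    "read_internal",
    "read_dicom_rt",
    "DEFAULT_NAME_MAP",
]

_MAGIC = b"#SBRTPLAN 1\n"


class ParseError(ValueError):
    """Malformed internal container file."""


class IngestionError(ValueError):
    """DICOM-RT pair cannot be ingested."""


def write_internal(plan: Plan, path: str | os.PathLike) -> None:
    """Write a plan to the internal single-file container."""
    roles = list(plan.structures)
    header = {
        "origin": plan.grid.origin.tolist(),
        "spacing": plan.grid.spacing.tolist(),
        "dims": list(plan.grid.dims),
        "structures": [
            {"name": plan.structures[r].name, "role": r.value} for r in roles
        ],
        "meta": {
            "institution_id": plan.meta.institution_id,
            "technique": plan.meta.technique.value,
            "algorithm": plan.meta.algorithm.value,
            "calc_grid_mm": plan.meta.calc_grid_mm,
            "mlc_width_mm": plan.meta.mlc_width_mm,
            "energy_label": plan.meta.energy_label,
            "patient_id": plan.meta.patient_id,
        },
    }
    payload = json.dumps(header, sort_keys=True).encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(str(len(payload)).encode("ascii") + b"\n")
        fh.write(payload)
        fh.write(np.ascontiguousarray(plan.grid.dose, dtype="<f8").tobytes())
        for r in roles:
            fh.write(np.ascontiguousarray(plan.structures[r].occupancy, dtype="<f8").tobytes())


def read_internal(path: str | os.PathLike) -> Plan:
    """Read a plan from the internal container; validates all invariants."""
    with open(path, "rb") as fh:
        magic = fh.readline()
        if magic != _MAGIC:
            raise ParseError(f"{path}: not an internal plan container (bad magic)")
        try:
            hlen = int(fh.readline().strip())
        except ValueError as exc:
            raise ParseError(f"{path}: malformed header length") from exc
        raw = fh.read(hlen)
        if len(raw) != hlen:
            raise ParseError(f"{path}: truncated header")
        try:
            header = json.loads(raw.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise ParseError(f"{path}: malformed JSON header") from exc
        try:
            dims = tuple(int(d) for d in header["dims"])
            origin = header["origin"]
            spacing = header["spacing"]
            structures = header["structures"]
            meta_d = header["meta"]
        except (KeyError, TypeError) as exc:
            raise ParseError(f"{path}: missing header field: {exc}") from exc
        n_vox = int(np.prod(dims))
        n_arrays = 1 + len(structures)
        blob = fh.read(n_arrays * n_vox * 8)
        if len(blob) != n_arrays * n_vox * 8:
            raise ParseError(
                f"{path}: truncated array payload "
                f"({len(blob)} of {n_arrays * n_vox * 8} bytes)"
            )
    arrays = np.frombuffer(blob, dtype="<f8").reshape(n_arrays, *dims)
    try:
        grid = DoseGrid(origin=origin, spacing=spacing, dose=arrays[0].copy())
        masks = {}
        for s, arr in zip(structures, arrays[1:]):
            role = StructureRole(s["role"])
            masks[role] = StructureMask(
                name=s["name"], role=role, origin=origin, spacing=spacing, occupancy=arr.copy()
            )
        meta = PlanMeta(**meta_d)
        return Plan(grid=grid, structures=masks, meta=meta)
    except (ValueError, GeometryError) as exc:
        raise ParseError(f"{path}: invalid plan content: {exc}") from exc


# --------------------------------------------------------------------------- #
# DICOM-RT

#: Default structure-name mapping: role -> case-insensitive regexes tried in
#: order against ROI names.  Institutional naming varies; override per site.
DEFAULT_NAME_MAP: dict[StructureRole, list[str]] = {
    StructureRole.ITV: [r"^itv"],
    StructureRole.PTV: [r"^ptv"],
    StructureRole.LUNG_IPSI: [r"lung.*ipsi", r"ipsi.*lung"],
    StructureRole.LUNG_CONTRA: [r"lung.*contra", r"contra.*lung"],
    StructureRole.CHEST_WALL: [r"chest.*wall", r"thoracic.*wall"],
    StructureRole.SPINAL_CANAL: [r"spinal.*(canal|cord)", r"myelon"],
    StructureRole.ESOPHAGUS: [r"esophagus", r"oesophagus"],
}


def _assign_role(name: str, name_map: Mapping[StructureRole, list[str]]) -> StructureRole:
    for role, patterns in name_map.items():
        for pat in patterns:
            if re.search(pat, name, flags=re.IGNORECASE):
                return StructureRole(role)
    return StructureRole.OTHER


def read_dicom_rt(
    dose_path: str | os.PathLike,
    struct_path: str | os.PathLike,
    name_map: Mapping[StructureRole, list[str]] | None = None,
    rasterization: str = "fractional",
    meta: PlanMeta | None = None,
) -> Plan:
    """Ingest an RT Dose + RT Structure Set pair into a Plan.

    The two datasets must share a frame of reference; dose is converted to
    Gy; every mapped structure is rasterized onto the dose lattice.
    """
    import pydicom

    name_map = DEFAULT_NAME_MAP if name_map is None else name_map
    ds_dose = pydicom.dcmread(dose_path)
    ds_struct = pydicom.dcmread(struct_path)

    if getattr(ds_dose, "Modality", "") != "RTDOSE":
        raise IngestionError(f"{dose_path}: not an RT Dose object")
    units = getattr(ds_dose, "DoseUnits", "GY")
    if units != "GY":
        raise IngestionError(f"unsupported dose units {units!r} (expected GY)")

    dose_for = getattr(ds_dose, "FrameOfReferenceUID", None)
    struct_fors = set()
    for item in getattr(ds_struct, "ReferencedFrameOfReferenceSequence", []):
        struct_fors.add(item.FrameOfReferenceUID)
    for roi in getattr(ds_struct, "StructureSetROISequence", []):
        struct_fors.add(getattr(roi, "ReferencedFrameOfReferenceUID", None))
    struct_fors.discard(None)
    if dose_for is None or not struct_fors:
        raise IngestionError("missing frame-of-reference linkage")
    if dose_for not in struct_fors:
        raise IngestionError(
            f"dose and structure set are in different frames of reference "
            f"({dose_for} vs {sorted(struct_fors)})"
        )

    ipp = np.array([float(v) for v in ds_dose.ImagePositionPatient])
    row_sp, col_sp = (float(v) for v in ds_dose.PixelSpacing)  # (row=y, col=x)
    offsets = np.array([float(v) for v in ds_dose.GridFrameOffsetVector])
    dz = float(np.median(np.diff(offsets))) if offsets.size > 1 else 1.0
    orient = [float(v) for v in getattr(ds_dose, "ImageOrientationPatient", [1, 0, 0, 0, 1, 0])]
    if not np.allclose(orient, [1, 0, 0, 0, 1, 0]):
        raise IngestionError("only axis-aligned dose grids are supported")

    scaling = float(getattr(ds_dose, "DoseGridScaling", 1.0))
    raw = ds_dose.pixel_array  # (frames=z, rows=y, cols=x)
    dose = (raw.astype(np.float64) * scaling).transpose(2, 1, 0)  # -> (x, y, z)
    origin = np.array([ipp[0], ipp[1], ipp[2] + offsets[0]])
    spacing = np.array([col_sp, row_sp, dz])
    grid = DoseGrid(origin=origin, spacing=spacing, dose=dose)

    roi_names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in getattr(ds_struct, "StructureSetROISequence", [])
    }
    masks: dict[StructureRole, StructureMask] = {}
    for rc in getattr(ds_struct, "ROIContourSequence", []):
        number = int(rc.ReferencedROINumber)
        name = roi_names.get(number, f"ROI-{number}")
        role = _assign_role(name, name_map)
        if role is StructureRole.OTHER:
            continue
        contours = []
        for cs in getattr(rc, "ContourSequence", []):
            pts = np.array([float(v) for v in cs.ContourData]).reshape(-1, 3)
            contours.append(pts)
        if not contours:
            raise IngestionError(f"structure {name!r} has zero contours")
        occ = rasterize_contours(
            contours, origin, spacing, grid.dims, mode=rasterization
        )
        masks[role] = StructureMask(
            name=name, role=role, origin=origin, spacing=spacing, occupancy=occ
        )
    return Plan(grid=grid, structures=masks, meta=meta or PlanMeta())
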