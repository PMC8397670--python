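"""Shared fixtures: tiny analytic grids, a fast coarse phantom, and the two
study phantoms (built once per session; they are the expensive objects)."""

from __future__ import annotations

import numpy as np
import pytest

from sbrtbench.grids import DoseGrid, Plan, PlanMeta, StructureMask, StructureRole
from sbrtbench.synth import (
    OarLayout,
    Phantom,
    PhantomSpec,
    default_phantoms,
    make_phantom,
)


def make_grid(dose: np.ndarray, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> DoseGrid:
    return DoseGrid(origin=origin, spacing=spacing, dose=dose)


def make_mask(
    occ: np.ndarray,
    role: StructureRole = StructureRole.PTV,
    spacing=(1.0, 1.0, 1.0),
    origin=(0.0, 0.0, 0.0),
    name: str | None = None,
) -> StructureMask:
    return StructureMask(
        name=name or role.value, role=role, origin=origin, spacing=spacing, occupancy=occ
    )


def cube_plan(
    n: int = 12,
    dose_in: float = 64.5,
    dose_out: float = 0.0,
    spacing: float = 1.0,
) -> Plan:
    """Ideal step-dose plan: cubic PTV with binary occupancy, dose exactly
    ``dose_in`` on PTV voxels and ``dose_out`` elsewhere; ITV is an inner cube."""
    dims = (n, n, n)
    ptv = np.zeros(dims)
    itv = np.zeros(dims)
    lo, hi = n // 4, 3 * n // 4
    ptv[lo:hi, lo:hi, lo:hi] = 1.0
    lo2, hi2 = lo + 1, hi - 1
    itv[lo2:hi2, lo2:hi2, lo2:hi2] = 1.0
    dose = np.where(ptv > 0, dose_in, dose_out)
    sp = (spacing,) * 3
    return Plan(
        grid=make_grid(dose, spacing=sp),
        structures={
            StructureRole.PTV: make_mask(ptv, StructureRole.PTV, spacing=sp),
            StructureRole.ITV: make_mask(itv, StructureRole.ITV, spacing=sp),
        },
        meta=PlanMeta(institution_id="fixture"),
    )


def mini_phantom_spec() -> PhantomSpec:
    """A coarse, quick-to-build phantom for property tests."""
    return PhantomSpec(
        name="mini",
        itv_semi_axes=(10.0, 10.0, 10.0),
        itv_center=(-20.0, 0.0, 0.0),
        origin=(-59.0, -59.0, -49.0),
        spacing=(2.5, 2.5, 2.5),
        dims=(48, 48, 40),
        oar=OarLayout(
            thorax_semi_axes=(45.0, 45.0, 60.0),
            mediastinum_halfwidth_mm=10.0,
            canal_center_xy=(0.0, 38.0),
            esophagus_center_xy=(8.0, 12.0),
        ),
    )


@pytest.fixture(scope="session")
def mini_phantom() -> Phantom:
    return make_phantom(mini_phantom_spec())


@pytest.fixture(scope="session")
def study_phantoms() -> dict[str, Phantom]:
    return default_phantoms()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
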