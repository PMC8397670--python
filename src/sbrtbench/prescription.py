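"""Mean-ITV-dose prescription normalization and linear-quadratic BED.

The benchmarking protocol prescribes 3 x 21.5 Gy *normalized to the mean ITV
dose*: every submitted dose distribution is rescaled so that the
occupancy-weighted mean dose of the internal target volume equals the nominal
total of 64.5 Gy.  All coverage / hot-spot thresholds downstream are fractions
of that anchor, so the anchor itself must be voxel-exact (no DVH binning).

BED uses the standard linear-quadratic form  ``BED = n d (1 + d / (alpha/beta))``
with alpha/beta = 10 Gy for tumour.  Display helpers reproduce the rounded
values as printed in the protocol sheet (45.2 / 58.1 Gy; BED 203, 170, 228,
239 and 112 Gy10 - the last for 3 x 15 Gy = 45 Gy).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, ROUND_HALF_UP, Decimal

from .dvh import dose_mean
from .grids import Plan, StructureRole

__all__ = [
    "Prescription",
    "STUDY_PRESCRIPTION",
    "normalize_plan",
    "dose_at_percent",
    "bed",
    "display_gy",
    "display_bed",
]


@dataclass(frozen=True)
class Prescription:
    """Fractionation scheme with its normalization anchor.

    ``anchor`` is the quantity the nominal total dose is pinned to; only the
    mean ITV dose is supported, which is the point of this protocol.
    """

    n_fractions: int = 3
    dose_per_fraction_gy: float = 21.5
    alpha_beta_gy: float = 10.0
    anchor: str = "MEAN_ITV"

    def __post_init__(self) -> None:
        if self.n_fractions <= 0 or self.dose_per_fraction_gy <= 0 or self.alpha_beta_gy <= 0:
            raise ValueError("prescription parameters must be positive")
        if self.anchor != "MEAN_ITV":
            raise ValueError(f"unsupported normalization anchor {self.anchor!r}")

    @property
    def nominal_total_gy(self) -> float:
        return self.n_fractions * self.dose_per_fraction_gy


#: The study prescription: 3 x 21.5 Gy to the mean ITV dose (BED 203 Gy10).
STUDY_PRESCRIPTION = Prescription()


def mean_itv_dose(plan: Plan) -> float:
    return dose_mean(plan.grid, plan.mask(StructureRole.ITV))


def normalize_plan(plan: Plan, rx: Prescription = STUDY_PRESCRIPTION) -> tuple[Plan, float]:
    """Rescale the dose so the mean ITV dose equals the nominal total.

    Returns the scaled plan and the scale factor ``s``.  Idempotent: applying
    it to an already-normalized plan yields ``s = 1``.
    """
    m = mean_itv_dose(plan)
    if m <= 0:
        raise ValueError("mean ITV dose is zero; cannot normalize")
    s = rx.nominal_total_gy / m
    return plan.with_dose(plan.grid.dose * s), s


def dose_at_percent(rx: Prescription, pct: float) -> float:
    """Unrounded absolute dose at ``pct`` percent of the nominal total, Gy."""
    if pct <= 0:
        raise ValueError(f"percentage must be > 0, got {pct}")
    return rx.nominal_total_gy * pct / 100.0


def bed(total_dose_gy: float, n_fractions: int, alpha_beta_gy: float = 10.0) -> float:
    """Linear-quadratic biologically effective dose, Gy_(alpha/beta)."""
    if total_dose_gy < 0 or n_fractions <= 0 or alpha_beta_gy <= 0:
        raise ValueError("bed() requires non-negative dose and positive fractions/alpha-beta")
    d = total_dose_gy / n_fractions
    return total_dose_gy * (1.0 + d / alpha_beta_gy)


def _dec(value: float) -> Decimal:
    # go through a fixed-precision string so that values like 45.149999999999999
    # (binary artefact of 0.70 * 64.5) are treated as the intended 45.15
    return Decimal(f"{value:.6f}")


def display_gy(value: float) -> float:
    """Protocol display rounding for doses: half-up to one decimal."""
    return float(_dec(value).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def display_bed(value: float) -> int:
    """Protocol display rounding for BED: to the nearest integer, ties to even.

    Ties-to-even reproduces every BED value on the protocol sheet, including
    112 Gy10 for 3 x 15 Gy (= 112.5 unrounded).
    """
    return int(_dec(value).quantize(Decimal("1"), rounding=ROUND_HALF_EVEN))
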