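"""Proximate-composition data model, completion and internal-consistency audit.

A record holds the five proximate components of 100 g of edible portion
(moisture, ash, protein, fat, carbohydrate) plus energy.  Carbohydrate may be
completed by difference (CHO = 100 - sum of the other four) and energy by the
Atwater conversion (4/4/9 kcal per gram of CHO/protein/fat).  The auditor
checks mass closure, the printed-vs-derived CHO gap and the printed-vs-Atwater
energy gap, and reports findings without ever mutating a record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .errors import InvalidComponent, MissingField, NegativeDifference
from .rounding import round_half_up

__all__ = [
    "FoodClass",
    "ChoSource",
    "AtwaterFactors",
    "KjeldahlFactor",
    "ProximateRecord",
    "FindingCode",
    "ValidationFinding",
    "EnergyValue",
    "cho_by_difference",
    "atwater_energy",
    "protein_from_nitrogen",
    "complete_record",
    "mass_closure_residual",
    "validate_record",
]

#: tolerance used for the exact-closure invariant of by-difference records
_CLOSURE_EPS = 1e-6


class FoodClass(str, Enum):
    dish = "dish"
    sweet = "sweet"


class ChoSource(str, Enum):
    measured_printed = "measured_printed"
    by_difference = "by_difference"


class AtwaterFactors(BaseModel):
    """Energy conversion factors in kcal per gram."""

    cho_kcal_per_g: float = Field(default=4.0, gt=0)
    protein_kcal_per_g: float = Field(default=4.0, gt=0)
    fat_kcal_per_g: float = Field(default=9.0, gt=0)


class KjeldahlFactor(BaseModel):
    """Nitrogen-to-protein multiplier (dairy-type default)."""

    nitrogen_to_protein: float = Field(default=6.38, gt=0)


class ProximateRecord(BaseModel):
    """Composition of 100 g of edible portion of one food."""

    name: str
    food_class: FoodClass
    moisture: float = Field(ge=0, le=100)
    ash: float = Field(ge=0, le=100)
    protein: float = Field(ge=0, le=100)
    fat: float = Field(ge=0, le=100)
    cho: Optional[float] = Field(default=None, ge=0, le=100)
    energy_kcal: Optional[float] = Field(default=None, ge=0)
    cho_source: ChoSource = ChoSource.measured_printed

    @model_validator(mode="after")
    def _closure_if_derived(self) -> "ProximateRecord":
        if self.cho_source is ChoSource.by_difference and self.cho is not None:
            total = self.moisture + self.ash + self.protein + self.fat + self.cho
            if abs(total - 100.0) > _CLOSURE_EPS:
                raise ValueError(
                    f"{self.name}: by-difference CHO must close to 100 g "
                    f"(components sum to {total})"
                )
        return self

    def components(self) -> tuple[float, float, float, float]:
        """The four directly measured components (moisture, ash, protein, fat)."""
        return (self.moisture, self.ash, self.protein, self.fat)


class FindingCode(str, Enum):
    closure_violation = "closure_violation"
    energy_mismatch = "energy_mismatch"
    negative_component = "negative_component"
    missing_field = "missing_field"
    derived_vs_printed_cho_mismatch = "derived_vs_printed_cho_mismatch"


@dataclass(frozen=True)
class ValidationFinding:
    """One detected inconsistency; ``magnitude`` is a signed residual in g or kcal."""

    food_name: str
    code: FindingCode
    magnitude: float
    message: str

    def __post_init__(self) -> None:
        if not math.isfinite(self.magnitude):
            raise ValueError("finding magnitude must be finite")


@dataclass(frozen=True)
class EnergyValue:
    """Unrounded Atwater energy and its integer display form (half-up)."""

    unrounded: float
    display: int


def _require_non_negative(**values: float) -> None:
    for label, value in values.items():
        if value < 0:
            raise InvalidComponent(f"{label} must be >= 0, got {value}")


def cho_by_difference(moisture: float, ash: float, protein: float, fat: float) -> float:
    """Carbohydrate per 100 g as the complement of the other four components.

    Raises
    ------
    InvalidComponent
        If any input is negative.
    NegativeDifference
        If the four components already sum above 100 g, which makes mass
        closure impossible.
    """
    _require_non_negative(moisture=moisture, ash=ash, protein=protein, fat=fat)
    total = moisture + ash + protein + fat
    if total > 100.0 + _CLOSURE_EPS:
        raise NegativeDifference(
            f"components sum to {total} g > 100 g; CHO by difference would be negative"
        )
    return min(100.0 - total, 100.0)


def atwater_energy(
    cho: float,
    protein: float,
    fat: float,
    factors: AtwaterFactors | None = None,
) -> EnergyValue:
    """Energy of 100 g from its macronutrients; display value rounds half-up."""
    _require_non_negative(cho=cho, protein=protein, fat=fat)
    f = factors or AtwaterFactors()
    unrounded = (
        f.cho_kcal_per_g * cho + f.protein_kcal_per_g * protein + f.fat_kcal_per_g * fat
    )
    return EnergyValue(unrounded=unrounded, display=int(round_half_up(unrounded)))


def protein_from_nitrogen(n: float, factor: KjeldahlFactor | None = None) -> float:
    """Crude protein from total Kjeldahl nitrogen."""
    if n < 0:
        raise InvalidComponent(f"nitrogen must be >= 0, got {n}")
    return (factor or KjeldahlFactor()).nitrogen_to_protein * n


def complete_record(
    record: ProximateRecord, factors: AtwaterFactors | None = None
) -> ProximateRecord:
    """Fill missing CHO (by difference) and energy (Atwater display) of a record.

    Present values are never overwritten; a record that already carries both
    CHO and energy is returned unchanged.
    """
    cho = record.cho
    source = record.cho_source
    if cho is None:
        cho = cho_by_difference(record.moisture, record.ash, record.protein, record.fat)
        source = ChoSource.by_difference
    energy = record.energy_kcal
    if energy is None:
        energy = float(atwater_energy(cho, record.protein, record.fat, factors).display)
    if cho is record.cho and energy is record.energy_kcal:
        return record
    return record.model_copy(
        update={"cho": cho, "energy_kcal": energy, "cho_source": source}
    )


def mass_closure_residual(record: ProximateRecord) -> float:
    """Signed gap (g) between the five-component sum and 100 g."""
    if record.cho is None:
        raise MissingField(f"{record.name}: cho is absent; complete the record first")
    return (
        record.moisture + record.ash + record.cho + record.protein + record.fat
    ) - 100.0


def validate_record(
    record: ProximateRecord,
    closure_tol: float = 0.2,
    energy_tol: float = 1.5,
) -> list[ValidationFinding]:
    """Audit one record for internal consistency; an empty list means consistent.

    Findings are reported, never raised: a record with an impossible closure is
    flagged rather than rejected, mirroring how inconsistent printed rows are
    carried through unmodified.
    """
    findings: list[ValidationFinding] = []

    for label in ("moisture", "ash", "protein", "fat", "cho"):
        value = getattr(record, label)
        if value is not None and value < 0:
            findings.append(
                ValidationFinding(
                    record.name,
                    FindingCode.negative_component,
                    float(value),
                    f"{label} is negative ({value} g)",
                )
            )

    if record.cho is None:
        findings.append(
            ValidationFinding(
                record.name, FindingCode.missing_field, 0.0, "cho is absent"
            )
        )
        return findings

    residual = mass_closure_residual(record)
    if abs(residual) > closure_tol:
        findings.append(
            ValidationFinding(
                record.name,
                FindingCode.closure_violation,
                residual,
                f"five components sum to {100 + residual:.2f} g "
                f"(residual {residual:+.2f} g > {closure_tol} g)",
            )
        )

    if record.cho_source is ChoSource.measured_printed:
        # Raw complement (may be negative) so closure-impossible rows still
        # yield a signed gap instead of an exception.
        derived = 100.0 - (record.moisture + record.ash + record.protein + record.fat)
        gap = derived - record.cho
        if abs(gap) > closure_tol:
            findings.append(
                ValidationFinding(
                    record.name,
                    FindingCode.derived_vs_printed_cho_mismatch,
                    gap,
                    f"CHO by difference {derived:.2f} g vs printed {record.cho} g",
                )
            )

    if record.energy_kcal is not None:
        energy = atwater_energy(record.cho, record.protein, record.fat)
        gap = record.energy_kcal - energy.unrounded
        if abs(gap) > energy_tol:
            findings.append(
                ValidationFinding(
                    record.name,
                    FindingCode.energy_mismatch,
                    gap,
                    f"printed energy {record.energy_kcal} kcal vs Atwater "
                    f"{energy.unrounded:.1f} kcal",
                )
            )

    return findings
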