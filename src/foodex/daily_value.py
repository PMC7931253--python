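"""Percent-daily-value profiling and nutrient-content-claim classification.

A 100 g portion is scored against a fixed daily reference (275 g CHO, 50 g
protein, 78 g fat, 2000 kcal).  Reported percentages carry exactly one decimal;
the reporting mode is truncation toward zero by default because that is the
convention the packaged dish table follows (7.15 -> 7.1), with half-up
available for tables that round instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd
from pydantic import BaseModel, Field

from .composition import FindingCode, ProximateRecord, ValidationFinding
from .errors import InvalidComponent, MissingField
from .rounding import round_half_up, truncate

__all__ = [
    "DailyReference",
    "RoundingMode",
    "DvProfile",
    "ClaimLevel",
    "percent_dv",
    "classify_claim",
    "dv_table",
]


class DailyReference(BaseModel):
    """Daily reference intakes used as %DV denominators."""

    cho_g: float = Field(default=275.0, gt=0)
    protein_g: float = Field(default=50.0, gt=0)
    fat_g: float = Field(default=78.0, gt=0)
    energy_kcal: float = Field(default=2000.0, gt=0)


class RoundingMode(str, Enum):
    truncate = "truncate"
    half_up = "half_up"


class ClaimLevel(str, Enum):
    """Label tier: low (<5% DV), good source (5-19%), high (>=20%)."""

    low = "low"
    good_source = "good_source"
    high = "high"


@dataclass(frozen=True)
class DvProfile:
    """%DV of a 100 g portion; ``*_pct`` are the one-decimal reported values."""

    name: str
    cho_pct: float
    protein_pct: float
    fat_pct: float
    energy_pct: float
    rounding_mode: RoundingMode
    # full-precision values retained for downstream arithmetic
    raw_cho_pct: float
    raw_protein_pct: float
    raw_fat_pct: float
    raw_energy_pct: float


def _report(raw: float, mode: RoundingMode) -> float:
    if mode is RoundingMode.truncate:
        return truncate(raw, 1)
    return round_half_up(raw, 1)


def percent_dv(
    record: ProximateRecord,
    ref: DailyReference | None = None,
    mode: RoundingMode = RoundingMode.truncate,
) -> DvProfile:
    """%DV of 100 g of a food for CHO, protein, fat and energy.

    Raises :class:`MissingField` if the record lacks CHO or energy; complete
    the record first (see :func:`foodex.composition.complete_record`).
    """
    if record.cho is None:
        raise MissingField(f"{record.name}: cho is absent")
    if record.energy_kcal is None:
        raise MissingField(f"{record.name}: energy_kcal is absent")
    ref = ref or DailyReference()
    raw = (
        100.0 * record.cho / ref.cho_g,
        100.0 * record.protein / ref.protein_g,
        100.0 * record.fat / ref.fat_g,
        100.0 * record.energy_kcal / ref.energy_kcal,
    )
    reported = tuple(_report(r, mode) for r in raw)
    return DvProfile(
        name=record.name,
        cho_pct=reported[0],
        protein_pct=reported[1],
        fat_pct=reported[2],
        energy_pct=reported[3],
        rounding_mode=mode,
        raw_cho_pct=raw[0],
        raw_protein_pct=raw[1],
        raw_fat_pct=raw[2],
        raw_energy_pct=raw[3],
    )


def classify_claim(pct: float) -> ClaimLevel:
    """Map a %DV value to its claim tier using half-open cut points at 5 and 20."""
    if pct < 0:
        raise InvalidComponent(f"%DV must be >= 0, got {pct}")
    if pct < 5.0:
        return ClaimLevel.low
    if pct < 20.0:
        return ClaimLevel.good_source
    return ClaimLevel.high


def dv_table(
    records: list[ProximateRecord],
    ref: DailyReference | None = None,
    mode: RoundingMode = RoundingMode.truncate,
) -> tuple[pd.DataFrame, list[ValidationFinding]]:
    """Batch %DV profiles with claim tiers, preserving input order.

    Records missing CHO or energy produce a ``missing_field`` finding and a row
    of NA cells instead of aborting the batch.
    """
    rows = []
    findings: list[ValidationFinding] = []
    for record in records:
        try:
            profile = percent_dv(record, ref, mode)
        except MissingField as exc:
            findings.append(
                ValidationFinding(record.name, FindingCode.missing_field, 0.0, str(exc))
            )
            rows.append({"name": record.name})
            continue
        rows.append(
            {
                "name": profile.name,
                "cho_pct": profile.cho_pct,
                "protein_pct": profile.protein_pct,
                "fat_pct": profile.fat_pct,
                "energy_pct": profile.energy_pct,
                "cho_claim": classify_claim(profile.cho_pct).value,
                "protein_claim": classify_claim(profile.protein_pct).value,
                "fat_claim": classify_claim(profile.fat_pct).value,
                "energy_claim": classify_claim(profile.energy_pct).value,
            }
        )
    columns = [
        "name",
        "cho_pct",
        "protein_pct",
        "fat_pct",
        "energy_pct",
        "cho_claim",
        "protein_claim",
        "fat_claim",
        "energy_claim",
    ]
    frame = pd.DataFrame(rows, columns=columns)
    return frame, findings
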