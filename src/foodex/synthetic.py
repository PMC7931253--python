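"""Seeded generator of closure-consistent composition records, plus corruption.

Records are drawn by rejection sampling: the four measured components are drawn
uniformly within class-specific ranges until they sum below 100 g, CHO is set
by difference and energy by the Atwater display value, so every clean record
passes the auditor by construction.  ``corrupt_closure`` then re-introduces the
inconsistency pattern seen in printed sweet rows, at a controlled magnitude.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .composition import (
    AtwaterFactors,
    ChoSource,
    FoodClass,
    ProximateRecord,
    atwater_energy,
    cho_by_difference,
)
from .errors import GenerationFailure, InvalidComponent, MissingField

__all__ = ["GeneratorProfile", "generate_compositions", "corrupt_closure"]

Range = tuple[float, float]

_DISH_RANGES: dict[str, Range] = {
    "moisture": (30.0, 92.0),
    "ash": (0.2, 3.5),
    "protein": (1.0, 30.0),
    "fat": (0.5, 23.0),
}
_SWEET_RANGES: dict[str, Range] = {
    "moisture": (0.5, 56.0),
    "ash": (0.1, 2.0),
    "protein": (2.0, 20.0),
    "fat": (6.0, 43.0),
}


class GeneratorProfile(BaseModel):
    """Sampling profile: class label, per-component ranges and a seed."""

    class_label: FoodClass = FoodClass.dish
    moisture_range: Range = _DISH_RANGES["moisture"]
    ash_range: Range = _DISH_RANGES["ash"]
    protein_range: Range = _DISH_RANGES["protein"]
    fat_range: Range = _DISH_RANGES["fat"]
    seed: int = 0

    @model_validator(mode="after")
    def _ranges_sane(self) -> "GeneratorProfile":
        for label in ("moisture_range", "ash_range", "protein_range", "fat_range"):
            lo, hi = getattr(self, label)
            if not (0.0 <= lo <= hi <= 100.0):
                raise ValueError(f"{label} must satisfy 0 <= min <= max <= 100")
        return self

    @classmethod
    def for_class(cls, class_label: FoodClass | str, seed: int = 0) -> "GeneratorProfile":
        label = FoodClass(class_label)
        ranges = _DISH_RANGES if label is FoodClass.dish else _SWEET_RANGES
        return cls(
            class_label=label,
            moisture_range=ranges["moisture"],
            ash_range=ranges["ash"],
            protein_range=ranges["protein"],
            fat_range=ranges["fat"],
            seed=seed,
        )


def generate_compositions(
    n: int,
    profile: GeneratorProfile | None = None,
    factors: AtwaterFactors | None = None,
    max_retries: int = 1000,
) -> list[ProximateRecord]:
    """Draw ``n`` closure-consistent records; identical seeds give identical lists.

    Rejection sampling (rather than renormalization) keeps the marginal ranges
    honest; a record that cannot close within ``max_retries`` draws raises
    :class:`GenerationFailure`.
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    profile = profile or GeneratorProfile()
    rng = np.random.default_rng(profile.seed)
    ranges = (
        profile.moisture_range,
        profile.ash_range,
        profile.protein_range,
        profile.fat_range,
    )
    records: list[ProximateRecord] = []
    for i in range(n):
        for _ in range(max_retries):
            moisture, ash, protein, fat = (
                float(rng.uniform(lo, hi)) for lo, hi in ranges
            )
            if moisture + ash + protein + fat < 100.0:
                break
        else:
            raise GenerationFailure(
                f"could not close record {i} within {max_retries} draws; "
                "component ranges are incompatible with mass closure"
            )
        cho = cho_by_difference(moisture, ash, protein, fat)
        energy = atwater_energy(cho, protein, fat, factors)
        records.append(
            ProximateRecord(
                name=f"{profile.class_label.value}_{i:04d}",
                food_class=profile.class_label,
                moisture=moisture,
                ash=ash,
                protein=protein,
                fat=fat,
                cho=cho,
                energy_kcal=float(energy.display),
                cho_source=ChoSource.by_difference,
            )
        )
    return records


_Component = Literal["moisture", "ash", "protein", "fat", "cho"]


def corrupt_closure(
    record: ProximateRecord, delta: float, target: _Component = "cho"
) -> ProximateRecord:
    """Shift one component by ``delta`` g without recomputing CHO or energy.

    The output's closure residual equals the input's plus ``delta``.  The copy
    is relabeled ``measured_printed`` since its CHO no longer closes by
    construction.
    """
    value = getattr(record, target)
    if value is None:
        raise MissingField(f"{record.name}: {target} is absent")
    if delta == 0:
        return record
    shifted = value + delta
    if shifted < 0:
        raise InvalidComponent(
            f"{record.name}: shifting {target} by {delta} g drives it to {shifted} g"
        )
    return record.model_copy(
        update={target: shifted, "cho_source": ChoSource.measured_printed}
    )
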