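"""Exchange-list derivation: round-off serving bands, exchange quanta and scaling.

One exchange carries 15 g CHO, 7 g protein or 5 g fat.  A single portion is
classified into 0, 0.5 or 1 serving per macronutrient by banded round-off; the
grams of food yielding exactly one exchange come from ``100 * quantum / amount``
rounded half-up to an integer gram; per-100 g exchange counts are quantized to
quarter units.  Category decomposition (starch vs vegetable vs milk vs meat
tiers) is not computable from proximates — it is accepted as an annotation and
only audited, via :func:`reconcile_categories`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

from pydantic import BaseModel, Field, model_validator

from .composition import AtwaterFactors, ProximateRecord
from .errors import InvalidComponent, MalformedCount, MissingField, OutOfBand, UnknownCategory, ZeroNutrient
from .rounding import round_half_up, round_quarter_up, truncate

__all__ = [
    "ExchangeQuantum",
    "WheelerBands",
    "ServingSpec",
    "ExchangeCategory",
    "ExchangeCount",
    "MacroTriple",
    "CategoryProfile",
    "DEFAULT_CATEGORY_PROFILES",
    "ExchangeListEntry",
    "ServingAmounts",
    "GramsForExchange",
    "wheeler_servings",
    "grams_for_one_exchange",
    "exchanges_per_100g",
    "scale_to_serving",
    "serving_for_one_cho_exchange",
    "reconcile_categories",
    "build_entry",
]


class ExchangeQuantum(BaseModel):
    """Grams of macronutrient carried by one exchange."""

    cho_g_per_exchange: float = Field(default=15.0, gt=0)
    protein_g_per_exchange: float = Field(default=7.0, gt=0)
    fat_g_per_exchange: float = Field(default=5.0, gt=0)


#: one band: (lower bound exclusive unless 0, upper bound inclusive, servings)
Band = tuple[float, float, float]

_DEFAULT_CHO_BANDS: tuple[Band, ...] = ((0.0, 5.0, 0.0), (5.0, 10.0, 0.5), (10.0, 20.0, 1.0))
_DEFAULT_PROTEIN_BANDS: tuple[Band, ...] = ((0.0, 3.0, 0.0), (3.0, 10.0, 1.0))
_DEFAULT_FAT_BANDS: tuple[Band, ...] = ((0.0, 2.0, 0.0), (2.0, 3.5, 0.5), (3.5, 7.0, 1.0))


class WheelerBands(BaseModel):
    """Banded round-off mapping portion grams to 0 / 0.5 / 1 servings.

    The printed bands are stated on integers ("6-10 g", "3 g of fat"); they are
    extended here to continuous half-open intervals ``(lo, hi]`` so fractional
    laboratory values are classifiable.  An amount of exactly 0 maps to 0.
    """

    cho_bands: tuple[Band, ...] = _DEFAULT_CHO_BANDS
    protein_bands: tuple[Band, ...] = _DEFAULT_PROTEIN_BANDS
    fat_bands: tuple[Band, ...] = _DEFAULT_FAT_BANDS

    @model_validator(mode="after")
    def _ordered_disjoint(self) -> "WheelerBands":
        for label in ("cho_bands", "protein_bands", "fat_bands"):
            bands = getattr(self, label)
            prev_hi = 0.0
            for lo, hi, servings in bands:
                if lo != prev_hi or hi <= lo:
                    raise ValueError(f"{label} must be contiguous ordered intervals")
                if servings not in (0.0, 0.5, 1.0):
                    raise ValueError(f"{label} servings must be 0, 0.5 or 1")
                prev_hi = hi
        return self

    def classify(self, nutrient: str, amount: float) -> float:
        if amount < 0:
            raise InvalidComponent(f"{nutrient} amount must be >= 0, got {amount}")
        bands = getattr(self, f"{nutrient}_bands")
        if amount == 0.0:
            return 0.0
        for lo, hi, servings in bands:
            if lo < amount <= hi:
                return servings
        raise OutOfBand(nutrient, amount, bands[-1][1])


class ServingSpec(BaseModel):
    """A serving: integer gram mass plus a household-measure descriptor."""

    grams: int = Field(ge=1)
    household_measure: str = ""


class ExchangeCategory(str, Enum):
    starch = "starch"
    vegetable = "vegetable"
    fat = "fat"
    sugar = "sugar"
    other_cho = "other_cho"
    whole_milk = "whole_milk"
    lean_meat = "lean_meat"
    medium_fat_meat = "medium_fat_meat"
    high_fat_meat = "high_fat_meat"
    reduced_fat_milk_or_meat = "reduced_fat_milk_or_meat"
    protein_generic = "protein_generic"


@dataclass(frozen=True)
class ExchangeCount:
    """(category, count) with count a non-negative multiple of 0.25."""

    category: ExchangeCategory
    count: float

    def __post_init__(self) -> None:
        if self.count < 0 or round(self.count * 4) != self.count * 4:
            raise MalformedCount(
                f"count must be a non-negative multiple of 0.25, got {self.count}"
            )


@dataclass(frozen=True)
class MacroTriple:
    """Grams of CHO / protein / fat (per exchange, per serving, ...)."""

    cho_g: float
    protein_g: float
    fat_g: float


#: per-exchange macro profiles by category.  These are configuration, not
#: measurement: only the starch-CHO / meat-protein / fat quanta (15 / 7 / 5 g)
#: are fixed by the derivation; the rest follow widely used exchange
#: conventions and are overridable.
DEFAULT_CATEGORY_PROFILES: Mapping[ExchangeCategory, MacroTriple] = {
    ExchangeCategory.starch: MacroTriple(15.0, 3.0, 0.0),
    ExchangeCategory.vegetable: MacroTriple(5.0, 2.0, 0.0),
    ExchangeCategory.fat: MacroTriple(0.0, 0.0, 5.0),
    ExchangeCategory.sugar: MacroTriple(5.0, 0.0, 0.0),
    ExchangeCategory.other_cho: MacroTriple(15.0, 0.0, 0.0),
    ExchangeCategory.whole_milk: MacroTriple(12.0, 8.0, 8.0),
    ExchangeCategory.lean_meat: MacroTriple(0.0, 7.0, 3.0),
    ExchangeCategory.medium_fat_meat: MacroTriple(0.0, 7.0, 5.0),
    ExchangeCategory.high_fat_meat: MacroTriple(0.0, 7.0, 8.0),
    ExchangeCategory.reduced_fat_milk_or_meat: MacroTriple(12.0, 8.0, 5.0),
    ExchangeCategory.protein_generic: MacroTriple(0.0, 7.0, 5.0),
}


class CategoryProfile(BaseModel):
    """Configurable per-exchange macro grams for each category."""

    profiles: dict[ExchangeCategory, MacroTriple] = Field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROFILES)
    )

    model_config = {"arbitrary_types_allowed": True}

    def macro(self, category: ExchangeCategory) -> MacroTriple:
        try:
            return self.profiles[category]
        except KeyError:
            raise UnknownCategory(f"no macro profile for category {category!r}") from None


@dataclass(frozen=True)
class ServingAmounts:
    """Per-serving macros (one-decimal truncated) with full-precision twins."""

    cho_g: float
    protein_g: float
    fat_g: float
    energy_kcal: float
    raw_cho_g: float
    raw_protein_g: float
    raw_fat_g: float
    raw_energy_kcal: float


@dataclass(frozen=True)
class GramsForExchange:
    unrounded: float
    serving_g: int


@dataclass(frozen=True)
class ExchangeListEntry:
    """One food's full exchange-list row."""

    name: str
    exchanges_per_100g: tuple[ExchangeCount, ...]
    serving: ServingSpec
    exchanges_per_serving: tuple[ExchangeCount, ...]
    amounts: ServingAmounts


def wheeler_servings(
    cho: float,
    protein: float,
    fat: float,
    bands: WheelerBands | None = None,
) -> tuple[float, float, float]:
    """Round off one portion's macro loads to (0, 0.5, 1) servings each.

    Raises :class:`OutOfBand` when a load exceeds its band ceiling (CHO 20 g,
    protein 10 g, fat 7 g): the portion is too large for single-serving
    classification and should be reduced or expressed per 100 g.
    """
    bands = bands or WheelerBands()
    return (
        bands.classify("cho", cho),
        bands.classify("protein", protein),
        bands.classify("fat", fat),
    )


def grams_for_one_exchange(amount_per_100g: float, quantum_g: float) -> GramsForExchange:
    """Grams of food that carry one exchange of a nutrient.

    ``unrounded = 100 * quantum / amount_per_100g``; the serving rounds half-up
    to an integer gram.
    """
    if amount_per_100g < 0:
        raise InvalidComponent(f"amount must be >= 0, got {amount_per_100g}")
    if amount_per_100g == 0:
        raise ZeroNutrient("no finite serving of a zero nutrient yields an exchange")
    unrounded = 100.0 * quantum_g / amount_per_100g
    return GramsForExchange(unrounded=unrounded, serving_g=int(round_half_up(unrounded)))


def exchanges_per_100g(
    record: ProximateRecord, quanta: ExchangeQuantum | None = None
) -> tuple[float, float, float]:
    """Quarter-quantized (CHO, protein, fat) exchanges carried by 100 g."""
    if record.cho is None:
        raise MissingField(f"{record.name}: cho is absent")
    quanta = quanta or ExchangeQuantum()
    return (
        round_quarter_up(record.cho / quanta.cho_g_per_exchange),
        round_quarter_up(record.protein / quanta.protein_g_per_exchange),
        round_quarter_up(record.fat / quanta.fat_g_per_exchange),
    )


def scale_to_serving(record: ProximateRecord, serving: ServingSpec) -> ServingAmounts:
    """Per-serving macro grams and energy, reported truncated at one decimal."""
    if record.cho is None:
        raise MissingField(f"{record.name}: cho is absent")
    if record.energy_kcal is None:
        raise MissingField(f"{record.name}: energy_kcal is absent")
    factor = serving.grams / 100.0
    raw = (
        record.cho * factor,
        record.protein * factor,
        record.fat * factor,
        record.energy_kcal * factor,
    )
    return ServingAmounts(
        cho_g=truncate(raw[0], 1),
        protein_g=truncate(raw[1], 1),
        fat_g=truncate(raw[2], 1),
        energy_kcal=truncate(raw[3], 1),
        raw_cho_g=raw[0],
        raw_protein_g=raw[1],
        raw_fat_g=raw[2],
        raw_energy_kcal=raw[3],
    )


def serving_for_one_cho_exchange(
    record: ProximateRecord, quanta: ExchangeQuantum | None = None
) -> ServingSpec:
    """Serving sized to one CHO exchange; household measure left to the caller."""
    if record.cho is None:
        raise MissingField(f"{record.name}: cho is absent")
    quanta = quanta or ExchangeQuantum()
    grams = grams_for_one_exchange(record.cho, quanta.cho_g_per_exchange)
    return ServingSpec(grams=grams.serving_g, household_measure="")


def reconcile_categories(
    measured: MacroTriple,
    annotation: Sequence[ExchangeCount],
    profiles: CategoryProfile | None = None,
) -> MacroTriple:
    """Residual macros left unexplained by an exchange-category annotation.

    ``residual = measured - sum(count * category profile)`` per nutrient; a
    perfect annotation yields (0, 0, 0).
    """
    profiles = profiles or CategoryProfile()
    cho = protein = fat = 0.0
    for token in annotation:
        macro = profiles.macro(token.category)
        cho += token.count * macro.cho_g
        protein += token.count * macro.protein_g
        fat += token.count * macro.fat_g
    return MacroTriple(
        cho_g=measured.cho_g - cho,
        protein_g=measured.protein_g - protein,
        fat_g=measured.fat_g - fat,
    )


def _generic_counts(counts: tuple[float, float, float]) -> tuple[ExchangeCount, ...]:
    cho_ex, protein_ex, fat_ex = counts
    tokens = []
    if cho_ex:
        tokens.append(ExchangeCount(ExchangeCategory.other_cho, cho_ex))
    if protein_ex:
        tokens.append(ExchangeCount(ExchangeCategory.protein_generic, protein_ex))
    if fat_ex:
        tokens.append(ExchangeCount(ExchangeCategory.fat, fat_ex))
    return tuple(tokens)


def build_entry(
    record: ProximateRecord,
    quanta: ExchangeQuantum | None = None,
    serving: ServingSpec | None = None,
    annotation_per_100g: Sequence[ExchangeCount] | None = None,
    annotation_per_serving: Sequence[ExchangeCount] | None = None,
    factors: AtwaterFactors | None = None,
) -> ExchangeListEntry:
    """Assemble one exchange-list row for a completed record.

    Without an explicit serving, the food is sized to one CHO exchange.  When
    no category annotation is given, quantized counts are reported against the
    generic macro categories (other_cho / protein_generic / fat).
    """
    quanta = quanta or ExchangeQuantum()
    if serving is None:
        serving = serving_for_one_cho_exchange(record, quanta)
    amounts = scale_to_serving(record, serving)
    per_100g = (
        tuple(annotation_per_100g)
        if annotation_per_100g is not None
        else _generic_counts(exchanges_per_100g(record, quanta))
    )
    if annotation_per_serving is not None:
        per_serving = tuple(annotation_per_serving)
    else:
        per_serving = _generic_counts(
            (
                round_quarter_up(amounts.raw_cho_g / quanta.cho_g_per_exchange),
                round_quarter_up(amounts.raw_protein_g / quanta.protein_g_per_exchange),
                round_quarter_up(amounts.raw_fat_g / quanta.fat_g_per_exchange),
            )
        )
    return ExchangeListEntry(
        name=record.name,
        exchanges_per_100g=per_100g,
        serving=serving,
        exchanges_per_serving=per_serving,
        amounts=amounts,
    )
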