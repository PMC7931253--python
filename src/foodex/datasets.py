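"""Packaged table fixtures, the serving / exchange-string dialects and writers.

Two CSV fixtures ship with the package: ``table2_composition.csv`` (65 foods,
per-100 g proximates, energy and printed %DV cells) and
``table4_exchanges.csv`` (the same 65 foods' exchange strings, serving texts
and per-serving amounts).  Printed values are preserved verbatim — known
inconsistencies are carried as explicit ``flags`` rather than silently
corrected.  The parsers handle the source tables' mixed dialect: decimal
commas inside counts ("1,25 starch", spaced "1, 25 starch"), glued tokens
("1LM", "0.25RFM") and serving texts with or without a "g" unit mark.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .composition import ChoSource, FoodClass, ProximateRecord
from .errors import MalformedCount, SchemaError, UnknownCategory, UnparsableServing
from .exchanges import (
    ExchangeCategory,
    ExchangeCount,
    ExchangeListEntry,
    ServingAmounts,
    ServingSpec,
)

__all__ = [
    "Table2Row",
    "Table4Row",
    "load_table2",
    "load_table4",
    "canonical_name",
    "parse_serving_measure",
    "parse_exchange_string",
    "render_exchange_string",
    "write_exchange_list",
    "read_exchange_list",
]


def _packaged(name: str):
    return resources.files("foodex").joinpath("data", name)


@dataclass(frozen=True)
class Table2Row:
    """One composition-table row: the record plus the printed %DV cells."""

    record: ProximateRecord
    dv_cho: float
    dv_protein: float
    dv_fat: float
    dv_energy: float
    flags: frozenset[str]


@dataclass(frozen=True)
class Table4Row:
    """One exchange-table row as printed, before any recomputation."""

    name: str
    food_class: FoodClass
    exchanges_per_100g_text: str
    serving_text: str
    exchanges_per_serving_text: str
    cho_g: float
    protein_g: float
    fat_g: float
    energy_kcal: float
    flags: frozenset[str]

    @property
    def serving(self) -> ServingSpec:
        return parse_serving_measure(self.serving_text)


# The two source tables spell a handful of names differently; aliases map the
# exchange-table variants onto the composition-table spellings.
_NAME_ALIASES = {
    "borgol bi banadoura": "borgul bi banadoura",
    "hindbe bil zet": "hindbe bi zet",
    "loubi bil zet": "loubia bi zet",
    "mousaka batinjan": "mousaka batinjen",
    "sayadia": "sayadiah",
    "kounafa bil jibn": "kounafa bil jiben",
}


def canonical_name(name: str) -> str:
    """Case-folded, alias-resolved food name used to join the two tables."""
    key = " ".join(name.split()).casefold()
    return _NAME_ALIASES.get(key, key)


def _parse_float(value: str, row: int, column: str, minimum: float | None = 0.0) -> float:
    try:
        number = float(value)
    except ValueError:
        raise SchemaError(f"row {row}, column {column!r}: not a number: {value!r}") from None
    if minimum is not None and number < minimum:
        raise SchemaError(f"row {row}, column {column!r}: negative value {number}")
    return number


def _read_rows(path, required: Sequence[str], label: str) -> list[dict]:
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle)
        header = reader.fieldnames
        if not header:
            raise SchemaError(f"{label}: empty file")
        missing = [column for column in required if column not in header]
        if missing:
            raise SchemaError(f"{label}: missing columns {missing}")
        return list(reader)


_TABLE2_COLUMNS = (
    "name", "food_class", "moisture", "ash", "cho", "protein", "fat",
    "energy", "dv_cho", "dv_protein", "dv_fat", "dv_energy",
)


def load_table2(path: str | Path | None = None) -> list[Table2Row]:
    """Load the packaged composition fixture (or a CSV with the same schema)."""
    source = path if path is not None else _packaged("table2_composition.csv")
    rows = _read_rows(source, _TABLE2_COLUMNS, "table2")
    if not rows:
        raise SchemaError("table2: no data rows")
    out: list[Table2Row] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=2):
        name = row["name"].strip()
        if not name:
            raise SchemaError(f"row {i}: empty name")
        if name in seen:
            raise SchemaError(f"row {i}: duplicate name {name!r}")
        seen.add(name)
        try:
            food_class = FoodClass(row["food_class"].strip())
        except ValueError:
            raise SchemaError(
                f"row {i}, column 'food_class': {row['food_class']!r}"
            ) from None
        numbers = {
            column: _parse_float(row[column], i, column)
            for column in _TABLE2_COLUMNS[2:8]
        }
        # printed %DV cells are audit data and may be absent (e.g. synthetic CSVs)
        for column in _TABLE2_COLUMNS[8:]:
            value = (row[column] or "").strip()
            numbers[column] = _parse_float(value, i, column) if value else float("nan")
        record = ProximateRecord(
            name=name,
            food_class=food_class,
            moisture=numbers["moisture"],
            ash=numbers["ash"],
            protein=numbers["protein"],
            fat=numbers["fat"],
            cho=numbers["cho"],
            energy_kcal=numbers["energy"],
            cho_source=ChoSource.measured_printed,
        )
        flags = frozenset(filter(None, (row.get("flags") or "").split("|")))
        out.append(
            Table2Row(
                record=record,
                dv_cho=numbers["dv_cho"],
                dv_protein=numbers["dv_protein"],
                dv_fat=numbers["dv_fat"],
                dv_energy=numbers["dv_energy"],
                flags=flags,
            )
        )
    return out


_TABLE4_COLUMNS = (
    "name", "food_class", "exchanges_100g", "serving_text",
    "exchanges_serving", "cho", "protein", "fat", "energy",
)


def load_table4(path: str | Path | None = None) -> list[Table4Row]:
    """Load the packaged exchange-list fixture (or a CSV with the same schema)."""
    source = path if path is not None else _packaged("table4_exchanges.csv")
    rows = _read_rows(source, _TABLE4_COLUMNS, "table4")
    if not rows:
        raise SchemaError("table4: no data rows")
    out: list[Table4Row] = []
    for i, row in enumerate(rows, start=2):
        name = row["name"].strip()
        if not name:
            raise SchemaError(f"row {i}: empty name")
        serving = parse_serving_measure(row["serving_text"])
        if serving.grams < 1:
            raise SchemaError(f"row {i}: serving grams must be >= 1")
        out.append(
            Table4Row(
                name=name,
                food_class=FoodClass(row["food_class"].strip()),
                exchanges_per_100g_text=row["exchanges_100g"].strip(),
                serving_text=row["serving_text"].strip(),
                exchanges_per_serving_text=row["exchanges_serving"].strip(),
                cho_g=_parse_float(row["cho"], i, "cho"),
                protein_g=_parse_float(row["protein"], i, "protein"),
                fat_g=_parse_float(row["fat"], i, "fat"),
                energy_kcal=_parse_float(row["energy"], i, "energy"),
                flags=frozenset(filter(None, (row.get("flags") or "").split("|"))),
            )
        )
    return out


_SERVING_RE = re.compile(
    r"^\s*(?P<grams>\d+)\s*(?:g\b)?\s*(?:\((?P<measure>[^)]*)\))?\s*$"
)


def parse_serving_measure(text: str) -> ServingSpec:
    """Parse ``"100 g (1/2 cup)"`` or ``"23 (1 piece)"`` into a ServingSpec.

    Serving texts without a "g" mark are grams by the source table's
    convention.
    """
    match = _SERVING_RE.match(text or "")
    if not match or int(match.group("grams")) < 1:
        raise UnparsableServing(text)
    measure = (match.group("measure") or "").strip()
    return ServingSpec(grams=int(match.group("grams")), household_measure=measure)


_CATEGORY_TOKENS = {
    "starch": ExchangeCategory.starch,
    "vegetable": ExchangeCategory.vegetable,
    "fat": ExchangeCategory.fat,
    "sugar": ExchangeCategory.sugar,
    "other cho": ExchangeCategory.other_cho,
    "wm": ExchangeCategory.whole_milk,
    "whole milk": ExchangeCategory.whole_milk,
    "lm": ExchangeCategory.lean_meat,
    "lean meat": ExchangeCategory.lean_meat,
    "mf": ExchangeCategory.medium_fat_meat,
    "mfm": ExchangeCategory.medium_fat_meat,
    "medium fat meat": ExchangeCategory.medium_fat_meat,
    "hfm": ExchangeCategory.high_fat_meat,
    "high fat meat": ExchangeCategory.high_fat_meat,
    "rfm": ExchangeCategory.reduced_fat_milk_or_meat,
    "reduced fat meat": ExchangeCategory.reduced_fat_milk_or_meat,
    "reduced fat milk": ExchangeCategory.reduced_fat_milk_or_meat,
    "protein": ExchangeCategory.protein_generic,
}

# A comma is a decimal mark iff it sits between digits (optionally spaced, as
# in "1, 25 starch"); separator commas always follow a category word.
_DECIMAL_COMMA_RE = re.compile(r"(?<=\d)\s*,\s*(?=\d)")
_TOKEN_RE = re.compile(r"^\s*(?P<count>\d+(?:\.\d+)?)\s*(?P<category>[A-Za-z][\w\s-]*)\s*$")


def _normalize_category(token: str) -> ExchangeCategory:
    key = " ".join(token.replace("-", " ").replace("_", " ").split()).casefold()
    try:
        return _CATEGORY_TOKENS[key]
    except KeyError:
        raise UnknownCategory(f"unrecognized exchange category token: {token!r}") from None


def parse_exchange_string(text: str) -> list[ExchangeCount]:
    """Parse an exchange cell like ``"1,25 starch, 1 fat"`` into counts."""
    if not text or not text.strip():
        return []
    joined = _DECIMAL_COMMA_RE.sub(".", text)
    tokens: list[ExchangeCount] = []
    for part in joined.split(","):
        if not part.strip():
            continue
        match = _TOKEN_RE.match(part)
        if not match:
            raise MalformedCount(f"cannot parse exchange token: {part.strip()!r}")
        count = float(match.group("count"))
        category = _normalize_category(match.group("category"))
        tokens.append(ExchangeCount(category=category, count=count))
    return tokens


_CANONICAL_CATEGORY = {
    ExchangeCategory.starch: "starch",
    ExchangeCategory.vegetable: "vegetable",
    ExchangeCategory.fat: "fat",
    ExchangeCategory.sugar: "sugar",
    ExchangeCategory.other_cho: "other CHO",
    ExchangeCategory.whole_milk: "WM",
    ExchangeCategory.lean_meat: "LM",
    ExchangeCategory.medium_fat_meat: "MFM",
    ExchangeCategory.high_fat_meat: "HFM",
    ExchangeCategory.reduced_fat_milk_or_meat: "RFM",
    ExchangeCategory.protein_generic: "protein",
}


def _format_count(count: float) -> str:
    return f"{count:g}"


def render_exchange_string(tokens: Iterable[ExchangeCount]) -> str:
    """Canonical dot-decimal text form, the identity target of the parser."""
    return ", ".join(
        f"{_format_count(token.count)} {_CANONICAL_CATEGORY[token.category]}"
        for token in tokens
    )


_ENTRY_COLUMNS = (
    "name", "exchanges_100g", "serving_grams", "household_measure",
    "exchanges_serving", "cho_g", "protein_g", "fat_g", "energy_kcal",
)


def write_exchange_list(
    entries: Sequence[ExchangeListEntry],
    destination: str | Path,
    markdown: str | Path | None = None,
) -> None:
    """Write entries as a deterministic CSV (and optionally a markdown table)."""
    destination = Path(destination)
    with destination.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(_ENTRY_COLUMNS)
        for entry in entries:
            writer.writerow(
                [
                    entry.name,
                    render_exchange_string(entry.exchanges_per_100g),
                    entry.serving.grams,
                    entry.serving.household_measure,
                    render_exchange_string(entry.exchanges_per_serving),
                    f"{entry.amounts.cho_g:g}",
                    f"{entry.amounts.protein_g:g}",
                    f"{entry.amounts.fat_g:g}",
                    f"{entry.amounts.energy_kcal:g}",
                ]
            )
    if markdown is not None:
        _write_markdown(entries, Path(markdown))


def _write_markdown(entries: Sequence[ExchangeListEntry], path: Path) -> None:
    header = (
        "| Food | Exchanges / 100 g | Serving | Exchanges / serving "
        "| CHO g | Protein g | Fat g | Energy kcal |"
    )
    rule = "|" + " --- |" * 8
    lines = [header, rule]
    for entry in entries:
        serving = f"{entry.serving.grams} g"
        if entry.serving.household_measure:
            serving += f" ({entry.serving.household_measure})"
        lines.append(
            "| {} | {} | {} | {} | {:g} | {:g} | {:g} | {:g} |".format(
                entry.name,
                render_exchange_string(entry.exchanges_per_100g),
                serving,
                render_exchange_string(entry.exchanges_per_serving),
                entry.amounts.cho_g,
                entry.amounts.protein_g,
                entry.amounts.fat_g,
                entry.amounts.energy_kcal,
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_exchange_list(path: str | Path) -> list[ExchangeListEntry]:
    """Reload a CSV produced by :func:`write_exchange_list` (round-trip)."""
    rows = _read_rows(path, _ENTRY_COLUMNS, "exchange list")
    entries: list[ExchangeListEntry] = []
    for i, row in enumerate(rows, start=2):
        amounts = ServingAmounts(
            cho_g=_parse_float(row["cho_g"], i, "cho_g"),
            protein_g=_parse_float(row["protein_g"], i, "protein_g"),
            fat_g=_parse_float(row["fat_g"], i, "fat_g"),
            energy_kcal=_parse_float(row["energy_kcal"], i, "energy_kcal"),
            raw_cho_g=float(row["cho_g"]),
            raw_protein_g=float(row["protein_g"]),
            raw_fat_g=float(row["fat_g"]),
            raw_energy_kcal=float(row["energy_kcal"]),
        )
        entries.append(
            ExchangeListEntry(
                name=row["name"],
                exchanges_per_100g=tuple(parse_exchange_string(row["exchanges_100g"])),
                serving=ServingSpec(
                    grams=int(row["serving_grams"]),
                    household_measure=row["household_measure"],
                ),
                exchanges_per_serving=tuple(
                    parse_exchange_string(row["exchanges_serving"])
                ),
                amounts=amounts,
            )
        )
    return entries
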