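"""Data model and I/O for food-composition databanks.

A databank is one row per food or drink item with per-100 g nutrient
content (per 100 ml for drinks, treated as equivalent), a NOVA
food-processing group (minimally processed food MPF, processed culinary
ingredient PCI, processed food PF, ultra-processed food UPF, or EXCLUDED
for items outside the classification such as supplements), and a drink
flag. Items are read from plain CSV (comma separated, UTF-8, "." decimal).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import pandas as pd

__all__ = [
    "NovaGroup",
    "FoodItem",
    "Databank",
    "FilterResult",
    "SchemaError",
    "ParseError",
    "ValidationError",
    "read_databank",
    "write_databank",
    "filter_classifiable",
    "FOPL_MANDATORY",
    "SALT_TO_SODIUM",
]

#: UK convention: salt (NaCl) mass = 2.5 x sodium mass.
SALT_TO_SODIUM = 2.5

#: Nutrients that must be present for an item to be scoreable, plus energy.
FOPL_MANDATORY = ("energy_kcal", "fat_g", "satfat_g", "sugar_g", "salt_g")


class SchemaError(ValueError):
    """A mandatory column is missing from the input file."""


class ParseError(ValueError):
    """A cell could not be parsed; carries the offending row index."""

    def __init__(self, message: str, row: int):
        super().__init__(f"{message} (row {row})")
        self.row = row


class ValidationError(ValueError):
    """An item violates a databank invariant."""


class NovaGroup(str, Enum):
    """NOVA food-processing groups, plus EXCLUDED for unclassifiable items."""

    MPF = "MPF"
    PCI = "PCI"
    PF = "PF"
    UPF = "UPF"
    EXCLUDED = "EXCLUDED"

    @classmethod
    def parse(cls, value) -> "NovaGroup":
        if isinstance(value, NovaGroup):
            return value
        text = str(value).strip().upper()
        # numeric NOVA codes 1-4 are common in coded databanks
        numeric = {"1": cls.MPF, "2": cls.PCI, "3": cls.PF, "4": cls.UPF}
        if text in numeric:
            return numeric[text]
        try:
            return cls[text]
        except KeyError:
            raise ValueError(f"unknown NOVA group {value!r}") from None


_NUTRIENT_FIELDS = (
    "energy_kcal",
    "fat_g",
    "satfat_g",
    "sugar_g",
    "salt_g",
    "sodium_g",
    "protein_g",
    "fibre_g",
    "carb_g",
    "water_g",
)

#: Slack on the mass-balance check, grams; allows rounding and ash content.
_COMPOSITION_LIMIT = 105.0


@dataclass(frozen=True)
class FoodItem:
    """One databank row: identity, NOVA group, drink flag, nutrients per 100 g.

    Nutrient fields are ``None`` when absent from the source file; absent is
    distinct from zero. ``sodium_g`` falls back to ``salt_g / 2.5`` through
    :meth:`sodium` when not recorded.
    """

    item_id: str
    nova_group: NovaGroup
    is_drink: bool
    energy_kcal: float | None = None
    fat_g: float | None = None
    satfat_g: float | None = None
    sugar_g: float | None = None
    salt_g: float | None = None
    sodium_g: float | None = None
    protein_g: float | None = None
    fibre_g: float | None = None
    carb_g: float | None = None
    water_g: float | None = None
    name: str = ""
    subgroup_code: str = ""

    def sodium(self) -> float | None:
        """Sodium g/100 g, derived from salt when not recorded directly."""
        if self.sodium_g is not None:
            return self.sodium_g
        if self.salt_g is not None:
            return self.salt_g / SALT_TO_SODIUM
        return None

    def validate(self) -> None:
        """Raise :class:`ValidationError` on any invariant violation."""
        for name in _NUTRIENT_FIELDS:
            value = getattr(self, name)
            if value is not None and (math.isnan(value) or value < 0):
                raise ValidationError(
                    f"item {self.item_id!r}: {name} must be >= 0, got {value}"
                )
        eps = 1e-9
        if (
            self.satfat_g is not None
            and self.fat_g is not None
            and self.satfat_g > self.fat_g + eps
        ):
            raise ValidationError(
                f"item {self.item_id!r}: saturated fat exceeds total fat"
            )
        if (
            self.sugar_g is not None
            and self.carb_g is not None
            and self.sugar_g > self.carb_g + eps
        ):
            raise ValidationError(
                f"item {self.item_id!r}: sugar exceeds carbohydrate"
            )
        parts = [self.fat_g, self.carb_g, self.protein_g, self.fibre_g,
                 self.water_g, self.salt_g]
        if all(p is not None for p in parts):
            total = sum(parts)
            if total > _COMPOSITION_LIMIT + eps:
                raise ValidationError(
                    f"item {self.item_id!r}: composition sums to {total:.1f} g "
                    f"per 100 g (limit {_COMPOSITION_LIMIT})"
                )

    def has_fopl_nutrients(self) -> bool:
        return all(getattr(self, f) is not None for f in FOPL_MANDATORY)


@dataclass
class Databank:
    """Ordered collection of :class:`FoodItem` with free-text provenance."""

    items: list[FoodItem] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise ValidationError(f"duplicate item ids: {sorted(dupes)[:5]}")

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self):
        return iter(self.items)

    def counts_by_group(self) -> dict[NovaGroup, int]:
        out: dict[NovaGroup, int] = {}
        for it in self.items:
            out[it.nova_group] = out.get(it.nova_group, 0) + 1
        return out

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with canonical column names, absent values as NaN."""
        rows = []
        for it in self.items:
            row = {
                "item_id": it.item_id,
                "name": it.name,
                "subgroup_code": it.subgroup_code,
                "nova_group": it.nova_group.value,
                "is_drink": int(it.is_drink),
            }
            for nf in _NUTRIENT_FIELDS:
                row[nf] = getattr(it, nf)
            rows.append(row)
        cols = ["item_id", "name", "subgroup_code", "nova_group", "is_drink",
                *_NUTRIENT_FIELDS]
        return pd.DataFrame(rows, columns=cols)


@dataclass
class FilterResult:
    """Classifiable subset plus a removal report keyed by reason."""

    databank: Databank
    removed: dict[str, int]


_MANDATORY_COLUMNS = ("item_id", "nova_group", "is_drink", *FOPL_MANDATORY)
_OPTIONAL_COLUMNS = ("name", "subgroup_code", "sodium_g", "protein_g",
                     "fibre_g", "carb_g", "water_g")

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", ""}


def _parse_bool(value, row: int) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in _TRUTHY:
        return True
    if text in _FALSY:
        return False
    raise ParseError(f"cannot parse drink flag {value!r}", row)


def _parse_nutrient(value, column: str, row: int) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if text == "":
        return None
    try:
        parsed = float(text)
    except ValueError:
        raise ParseError(f"non-numeric value {value!r} in column {column}", row)
    if parsed < 0:
        raise ValidationError(
            f"negative value {parsed} in column {column}, row {row}"
        )
    return parsed


def read_databank(path, schema: Mapping[str, str] | None = None) -> Databank:
    """Read a databank CSV.

    Parameters
    ----------
    path
        CSV file with a header row.
    schema
        Optional mapping from canonical column names (``item_id``,
        ``nova_group``, ``is_drink``, ``fat_g``, ...) to the file's column
        names, for databanks using different headers.

    Row order is preserved; nutrients absent from the file (missing column
    or empty cell) are recorded as absent, never as zero.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    schema = dict(schema or {})
    colmap = {canon: schema.get(canon, canon) for canon in
              (*_MANDATORY_COLUMNS, *_OPTIONAL_COLUMNS)}
    for canon in _MANDATORY_COLUMNS:
        if colmap[canon] not in frame.columns:
            raise SchemaError(f"mandatory column {colmap[canon]!r} missing")

    items: list[FoodItem] = []
    for row_idx, rec in enumerate(frame.to_dict(orient="records")):
        def cell(canon: str):
            col = colmap[canon]
            return rec.get(col) if col in frame.columns else None

        try:
            nova = NovaGroup.parse(cell("nova_group"))
        except ValueError as exc:
            raise ParseError(str(exc), row_idx) from None
        nutrients = {
            nf: _parse_nutrient(cell(nf), colmap[nf], row_idx)
            for nf in _NUTRIENT_FIELDS
        }
        # mandatory columns exist, but cells may still be empty; such items
        # are kept here and removed by filter_classifiable with a reason
        item = FoodItem(
            item_id=str(cell("item_id")),
            name=str(cell("name") or ""),
            subgroup_code=str(cell("subgroup_code") or ""),
            nova_group=nova,
            is_drink=_parse_bool(cell("is_drink"), row_idx),
            **nutrients,
        )
        item.validate()
        items.append(item)
    return Databank(items=items, provenance=f"read from {path}")


def write_databank(databank: Databank, path) -> None:
    """Write a databank to CSV with canonical columns (absent -> empty cell)."""
    databank.to_frame().to_csv(path, index=False)


def filter_classifiable(databank: Databank) -> FilterResult:
    """Drop items outside the NOVA classification or missing FOPL nutrients.

    Items coded EXCLUDED (e.g. supplements) are removed with reason
    ``"excluded"``; items lacking any of energy, fat, saturated fat, sugar
    or salt are removed with reason ``"incomplete"`` since traffic-light
    scoring is undefined on them. Idempotent.
    """
    kept: list[FoodItem] = []
    removed = {"excluded": 0, "incomplete": 0}
    for item in databank.items:
        if item.nova_group is NovaGroup.EXCLUDED:
            removed["excluded"] += 1
        elif not item.has_fopl_nutrients():
            removed["incomplete"] += 1
        else:
            kept.append(item)
    return FilterResult(
        databank=Databank(items=kept, provenance=databank.provenance),
        removed=removed,
    )
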