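"""Multiple-traffic-light (MTL) front-of-pack scoring.

Each of fat, saturated fat, total sugar and salt gets a green / amber /
red light against per-100 g (food) or per-100 ml (drink) cut-offs:
green ("low") iff value <= low_max, red ("high") iff value > high_min,
amber otherwise. Composite scores over the four lights:

* ``n_red`` / ``n_green`` counts and any-red / any-green flags;
* a continuous MTL score, green=1 / amber=2 / red=3 summed over the four
  nutrients, ranging 4 (all green) to 12 (all red);
* an 8-level ordinal MTL score: the continuous score with its two most
  extreme values (11 = three reds + one amber, 12 = four reds) merged,
  because such items are rare.

Cut-offs ship as a versioned JSON config so alternative threshold sets
can be swapped in without code changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum
from importlib import resources
from typing import Mapping

import pandas as pd

from .databank import Databank, FoodItem, ValidationError

__all__ = [
    "NUTRIENTS",
    "TrafficLight",
    "Bounds",
    "ThresholdConfig",
    "FOPLProfile",
    "load_thresholds",
    "default_thresholds",
    "assign_light",
    "profile_item",
    "profile_databank",
    "mtl_scores",
]

NUTRIENTS = ("fat", "satfat", "sugar", "salt")

_NUTRIENT_FIELD = {
    "fat": "fat_g",
    "satfat": "satfat_g",
    "sugar": "sugar_g",
    "salt": "salt_g",
}


class TrafficLight(IntEnum):
    """Ordered lights: GREEN < AMBER < RED."""

    GREEN = 1
    AMBER = 2
    RED = 3


@dataclass(frozen=True)
class Bounds:
    """Cut-offs for one nutrient on one basis, g per 100 g (or 100 ml)."""

    low_max: float
    high_min: float

    def __post_init__(self) -> None:
        if not self.low_max < self.high_min:
            raise ValueError(
                f"low_max ({self.low_max}) must be below high_min "
                f"({self.high_min})"
            )


@dataclass(frozen=True)
class ThresholdConfig:
    """Full cut-off table: nutrient x basis (food / drink) -> Bounds."""

    food: Mapping[str, Bounds]
    drink: Mapping[str, Bounds]
    name: str = ""

    def __post_init__(self) -> None:
        for table in (self.food, self.drink):
            missing = set(NUTRIENTS) - set(table)
            if missing:
                raise ValueError(f"thresholds missing for {sorted(missing)}")
        for nutrient in NUTRIENTS:
            if self.drink[nutrient].high_min > self.food[nutrient].high_min:
                raise ValueError(
                    f"drink high_min above food high_min for {nutrient}"
                )

    def bounds(self, nutrient: str, is_drink: bool) -> Bounds:
        table = self.drink if is_drink else self.food
        try:
            return table[nutrient]
        except KeyError:
            raise ValueError(f"unknown nutrient id {nutrient!r}") from None


def load_thresholds(path) -> ThresholdConfig:
    """Load a threshold config from its JSON file format."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return _from_dict(raw)


def _from_dict(raw: dict) -> ThresholdConfig:
    tables: dict[str, dict[str, Bounds]] = {"food": {}, "drink": {}}
    for nutrient, per_basis in raw["thresholds"].items():
        for basis in ("food", "drink"):
            spec = per_basis[basis]
            tables[basis][nutrient] = Bounds(
                low_max=float(spec["low_max"]), high_min=float(spec["high_min"])
            )
    return ThresholdConfig(
        food=tables["food"], drink=tables["drink"], name=raw.get("name", "")
    )


def default_thresholds() -> ThresholdConfig:
    """The UK DH/FSA 2016 front-of-pack cut-offs shipped with the package."""
    raw = json.loads(
        resources.files("mtlnova.data")
        .joinpath("thresholds_fsa_2016.json")
        .read_text(encoding="utf-8")
    )
    return _from_dict(raw)


def assign_light(
    nutrient: str, value: float, is_drink: bool, cfg: ThresholdConfig
) -> TrafficLight:
    """Colour one nutrient value: green iff <= low_max, red iff > high_min.

    The bound itself is "low" (green attainable at the printed cut-off) and
    "high" is strictly above its bound, matching the <= / > phrasing of the
    guidance.
    """
    if value < 0:
        raise ValueError(f"nutrient value must be >= 0, got {value}")
    bounds = cfg.bounds(nutrient, is_drink)
    if value <= bounds.low_max:
        return TrafficLight.GREEN
    if value > bounds.high_min:
        return TrafficLight.RED
    return TrafficLight.AMBER


@dataclass(frozen=True)
class FOPLProfile:
    """Four lights plus every composite score derived from them."""

    lights: tuple[TrafficLight, TrafficLight, TrafficLight, TrafficLight]
    n_red: int
    n_green: int
    any_red: bool
    any_green: bool
    mtl_continuous: int
    mtl_ordinal8: int


def mtl_scores(lights) -> FOPLProfile:
    """Composite scores from a 4-tuple of lights (fat, satfat, sugar, salt)."""
    lights = tuple(TrafficLight(l) for l in lights)
    if len(lights) != len(NUTRIENTS):
        raise ValueError(f"expected {len(NUTRIENTS)} lights, got {len(lights)}")
    n_red = sum(1 for l in lights if l is TrafficLight.RED)
    n_green = sum(1 for l in lights if l is TrafficLight.GREEN)
    continuous = sum(int(l) for l in lights)
    # top two levels (11: RRRA, 12: RRRR) merge into ordinal level 8
    ordinal8 = min(continuous, 11) - 3
    return FOPLProfile(
        lights=lights,
        n_red=n_red,
        n_green=n_green,
        any_red=n_red >= 1,
        any_green=n_green >= 1,
        mtl_continuous=continuous,
        mtl_ordinal8=ordinal8,
    )


def profile_item(item: FoodItem, cfg: ThresholdConfig) -> FOPLProfile:
    """Score one item: four lights on its basis, then composite scores."""
    lights = []
    for nutrient in NUTRIENTS:
        value = getattr(item, _NUTRIENT_FIELD[nutrient])
        if value is None:
            raise ValidationError(
                f"item {item.item_id!r}: missing {nutrient} content"
            )
        lights.append(assign_light(nutrient, value, item.is_drink, cfg))
    return mtl_scores(lights)


def profile_databank(
    databank: Databank, cfg: ThresholdConfig
) -> pd.DataFrame:
    """Profile every item; one row per item, file order preserved.

    Columns: item_id, nova_group, is_drink, the four lights (as
    "green"/"amber"/"red"), n_red, n_green, any_red, any_green,
    mtl_continuous, mtl_ordinal8.
    """
    rows = []
    for item in databank:
        try:
            prof = profile_item(item, cfg)
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"item {item.item_id!r}: {exc}") from exc
        row = {
            "item_id": item.item_id,
            "nova_group": item.nova_group.value,
            "is_drink": item.is_drink,
        }
        for nutrient, light in zip(NUTRIENTS, prof.lights):
            row[f"light_{nutrient}"] = light.name.lower()
        row.update(
            n_red=prof.n_red,
            n_green=prof.n_green,
            any_red=prof.any_red,
            any_green=prof.any_green,
            mtl_continuous=prof.mtl_continuous,
            mtl_ordinal8=prof.mtl_ordinal8,
        )
        rows.append(row)
    columns = ["item_id", "nova_group", "is_drink",
               *(f"light_{n}" for n in NUTRIENTS),
               "n_red", "n_green", "any_red", "any_green",
               "mtl_continuous", "mtl_ordinal8"]
    return pd.DataFrame(rows, columns=columns)
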