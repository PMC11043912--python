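"""Hyper-palatable food (HPF) classification.

A food item (drinks are out of the definition's scope) is hyper-palatable
when it falls in any of three nutrient-combination clusters defined on
energy fractions and sodium mass fraction:

1. fat + sodium:   > 25 % of kcal from fat  AND  >= 0.30 % sodium by weight
2. fat + sugar:    > 20 % of kcal from fat  AND  > 20 % of kcal from sugar
3. carb + sodium:  > 40 % of kcal from carbohydrate AND >= 0.20 % sodium
                   by weight

Energy fractions use 9 kcal/g for fat and 4 kcal/g for sugar and
carbohydrate by default (configurable; some UK tables use 3.75 for
carbohydrate). Zero-energy items (water, black tea) are non-HPF by
definition: their fractions are set to 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import pandas as pd

from .databank import Databank, FoodItem

__all__ = [
    "EnergyFactors",
    "HPFResult",
    "energy_fractions",
    "classify_hpf",
    "classify_databank",
]


@dataclass(frozen=True)
class EnergyFactors:
    """kcal per gram used when converting mass to energy fractions."""

    fat: float = 9.0
    sugar: float = 4.0
    carb: float = 4.0


DEFAULT_FACTORS = EnergyFactors()

# cluster thresholds: (fat fraction, Na % wt), (fat, sugar fractions),
# (carb fraction, Na % wt); > is strict, >= inclusive, as annotated below
FAT_NA_FAT_FRAC = 0.25       # strict >
FAT_NA_NA_PCT = 0.30         # inclusive >=
FAT_SUGAR_FAT_FRAC = 0.20    # strict >
FAT_SUGAR_SUGAR_FRAC = 0.20  # strict >
CARB_NA_CARB_FRAC = 0.40     # strict >
CARB_NA_NA_PCT = 0.20        # inclusive >=


@dataclass(frozen=True)
class HPFResult:
    """Energy fractions, sodium mass fraction and the three cluster flags.

    ``applicable`` is False for drinks, in which case all flags are False.
    ``any_hpf`` is the OR of the three cluster flags.
    """

    item_id: str
    frac_kcal_fat: float
    frac_kcal_sugar: float
    frac_kcal_carb: float | None
    na_pct_weight: float
    cluster_fat_na: bool = False
    cluster_fat_sugar: bool = False
    cluster_carb_na: bool = False
    any_hpf: bool = False
    applicable: bool = True


def energy_fractions(
    item: FoodItem, factors: EnergyFactors = DEFAULT_FACTORS
) -> HPFResult:
    """Fractions of energy from fat, sugar and carbohydrate, plus Na % wt.

    Fractions are 0 when energy is 0. The carbohydrate fraction is ``None``
    when the databank carries no carbohydrate column (cluster 3 then
    evaluates false, with a warning). Sodium comes from the sodium column
    when present, else salt / 2.5. Na % by weight equals sodium g per
    100 g numerically.
    """
    if item.energy_kcal is None or item.fat_g is None or item.sugar_g is None:
        raise ValueError(
            f"item {item.item_id!r}: energy, fat and sugar are required"
        )
    sodium = item.sodium()
    if sodium is None:
        raise ValueError(f"item {item.item_id!r}: no sodium or salt content")
    energy = item.energy_kcal
    if energy == 0:
        frac_fat, frac_sugar = 0.0, 0.0
        frac_carb: float | None = 0.0 if item.carb_g is not None else None
    else:
        frac_fat = factors.fat * item.fat_g / energy
        frac_sugar = factors.sugar * item.sugar_g / energy
        frac_carb = (
            factors.carb * item.carb_g / energy
            if item.carb_g is not None
            else None
        )
    if frac_carb is None:
        warnings.warn(
            f"item {item.item_id!r}: carbohydrate absent; the "
            "carbohydrate+sodium cluster will evaluate false",
            stacklevel=2,
        )
    return HPFResult(
        item_id=item.item_id,
        frac_kcal_fat=frac_fat,
        frac_kcal_sugar=frac_sugar,
        frac_kcal_carb=frac_carb,
        na_pct_weight=sodium,  # g per 100 g == % by weight
        applicable=not item.is_drink,
    )


def classify_hpf(
    item: FoodItem, factors: EnergyFactors = DEFAULT_FACTORS
) -> HPFResult:
    """Evaluate the three hyper-palatability clusters for one item.

    Called on a drink, returns ``applicable=False`` with all flags False.
    """
    result = energy_fractions(item, factors)
    if not result.applicable:
        return result
    c1 = (
        result.frac_kcal_fat > FAT_NA_FAT_FRAC
        and result.na_pct_weight >= FAT_NA_NA_PCT
    )
    c2 = (
        result.frac_kcal_fat > FAT_SUGAR_FAT_FRAC
        and result.frac_kcal_sugar > FAT_SUGAR_SUGAR_FRAC
    )
    c3 = (
        result.frac_kcal_carb is not None
        and result.frac_kcal_carb > CARB_NA_CARB_FRAC
        and result.na_pct_weight >= CARB_NA_NA_PCT
    )
    return replace(
        result,
        cluster_fat_na=c1,
        cluster_fat_sugar=c2,
        cluster_carb_na=c3,
        any_hpf=c1 or c2 or c3,
    )


def classify_databank(
    databank: Databank, factors: EnergyFactors = DEFAULT_FACTORS
) -> pd.DataFrame:
    """Classify every item; one row per item, file order preserved."""
    rows = []
    for item in databank:
        res = classify_hpf(item, factors)
        rows.append(
            {
                "item_id": res.item_id,
                "nova_group": item.nova_group.value,
                "frac_kcal_fat": res.frac_kcal_fat,
                "frac_kcal_sugar": res.frac_kcal_sugar,
                "frac_kcal_carb": res.frac_kcal_carb,
                "na_pct_weight": res.na_pct_weight,
                "cluster_fat_na": res.cluster_fat_na,
                "cluster_fat_sugar": res.cluster_fat_sugar,
                "cluster_carb_na": res.cluster_carb_na,
                "any_hpf": res.any_hpf,
                "applicable": res.applicable,
            }
        )
    return pd.DataFrame(rows)
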