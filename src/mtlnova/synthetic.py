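"""Synthetic food-composition databanks.

Two generators:

* :func:`generate_databank` draws a databank from a scenario of per-group
  log-normal nutrient distributions (nutrient content in real databanks is
  strongly right-skewed), with ultra-processed items shifted above
  minimally processed ones in fat, saturated fat, sugar, salt and energy
  density under the default scenario. Energy is derived from
  macronutrients (9/4/4/2 kcal per g of fat / carbohydrate / protein /
  fibre) unless the scenario specifies it directly; water fills the item
  to 100 g.

* :func:`fixture_printed_counts` builds a deterministic databank of
  archetype items whose traffic-light and hyper-palatability outcomes hit
  a set of target marginal counts per NOVA group exactly — the
  contingency counts a published study reports are thereby reproducible
  without its (non-redistributable) source databank. Archetype nutrient
  values sit mid-band with a wide margin to every default cut-off, so the
  realised outcomes are stable under small threshold perturbations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .databank import Databank, FoodItem, NovaGroup

__all__ = [
    "LogNormalSpec",
    "GroupScenario",
    "ScenarioConfig",
    "GroupFixture",
    "FixtureSpec",
    "FixtureInfeasibleError",
    "default_scenario",
    "generate_databank",
    "PRINTED_COUNTS",
    "fixture_printed_counts",
]

SCENARIO_NUTRIENTS = ("fat", "satfat", "sugar", "carb", "protein", "fibre",
                      "salt")

ENERGY_KCAL_PER_G = {"fat": 9.0, "carb": 4.0, "protein": 4.0, "fibre": 2.0}


@dataclass(frozen=True)
class LogNormalSpec:
    """Right-skewed nutrient distribution: median * exp(sigma * Z)."""

    median: float
    sigma: float

    def __post_init__(self) -> None:
        if self.median < 0 or self.sigma <= 0:
            raise ValueError("median must be >= 0 and sigma > 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.median == 0:
            return np.zeros(n)
        return self.median * np.exp(self.sigma * rng.standard_normal(n))


@dataclass(frozen=True)
class GroupScenario:
    """One NOVA group: item count, drink share, nutrient distributions."""

    n: int
    drink_fraction: float
    nutrients: dict[str, LogNormalSpec]
    energy: LogNormalSpec | None = None  # None: derive from macronutrients

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if not 0 <= self.drink_fraction <= 1:
            raise ValueError("drink_fraction must be in [0, 1]")
        missing = set(SCENARIO_NUTRIENTS) - set(self.nutrients)
        if missing:
            raise ValueError(f"nutrient specs missing: {sorted(missing)}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full scenario: per-group specs, drink dilution factor and seed."""

    groups: dict[str, GroupScenario]
    seed: int = 0
    drink_dilution: float = 0.3  # drinks are mostly water


def default_scenario(seed: int = 0, scale: float = 1.0) -> ScenarioConfig:
    """The default study conditions: 2980 items split 1650/986/283/61
    (UPF/MPF/PF/PCI, i.e. shares 55.4/33.1/9.5/2.0 %), with UPF shifted
    above MPF in fat, saturated fat, sugar, salt and derived energy
    density. ``scale`` shrinks every group count proportionally."""

    def spec(median, sigma):
        return LogNormalSpec(median=median, sigma=sigma)

    def n_of(n):
        return max(1, round(n * scale))

    groups = {
        "MPF": GroupScenario(
            n=n_of(986),
            drink_fraction=0.12,
            nutrients={
                "fat": spec(1.2, 1.3), "satfat": spec(0.4, 1.2),
                "sugar": spec(4.0, 1.2), "carb": spec(8.0, 1.0),
                "protein": spec(3.0, 1.0), "fibre": spec(1.5, 0.9),
                "salt": spec(0.1, 1.3),
            },
        ),
        "PCI": GroupScenario(
            n=n_of(61),
            drink_fraction=0.0,
            nutrients={
                "fat": spec(30.0, 1.8), "satfat": spec(8.0, 1.5),
                "sugar": spec(8.0, 2.2), "carb": spec(10.0, 2.0),
                "protein": spec(0.5, 1.2), "fibre": spec(0.2, 1.0),
                "salt": spec(0.5, 2.5),
            },
        ),
        "PF": GroupScenario(
            n=n_of(283),
            drink_fraction=0.02,
            nutrients={
                "fat": spec(6.0, 1.1), "satfat": spec(2.0, 1.1),
                "sugar": spec(3.5, 1.3), "carb": spec(12.0, 1.0),
                "protein": spec(8.0, 0.9), "fibre": spec(1.0, 1.0),
                "salt": spec(0.7, 1.0),
            },
        ),
        "UPF": GroupScenario(
            n=n_of(1650),
            drink_fraction=0.10,
            nutrients={
                "fat": spec(9.0, 1.0), "satfat": spec(3.0, 1.1),
                "sugar": spec(8.0, 1.2), "carb": spec(20.0, 0.9),
                "protein": spec(5.0, 0.9), "fibre": spec(1.5, 1.0),
                "salt": spec(0.8, 1.0),
            },
        ),
    }
    return ScenarioConfig(groups=groups, seed=seed)


_MAX_RESAMPLES = 1000


def generate_databank(cfg: ScenarioConfig) -> Databank:
    """Draw a synthetic databank; reproducible given the scenario seed.

    Saturated fat is clipped to total fat and sugar to carbohydrate;
    compositions with more than 100 g of solids per 100 g are resampled
    (count recorded in the provenance string). Drinks are the configured
    leading fraction of each group with nutrient draws scaled by the
    drink-dilution factor.
    """
    rng = np.random.default_rng(cfg.seed)
    items: list[FoodItem] = []
    resampled = 0
    for group_name in sorted(cfg.groups):
        scen = cfg.groups[group_name]
        nova = NovaGroup.parse(group_name)
        n_drinks = round(scen.n * scen.drink_fraction)
        for i in range(scen.n):
            is_drink = i < n_drinks
            factor = cfg.drink_dilution if is_drink else 1.0
            for _ in range(_MAX_RESAMPLES):
                draw = {
                    nut: float(scen.nutrients[nut].sample(rng, 1)[0]) * factor
                    for nut in SCENARIO_NUTRIENTS
                }
                draw["satfat"] = min(draw["satfat"], draw["fat"])
                draw["sugar"] = min(draw["sugar"], draw["carb"])
                solids = sum(
                    draw[k] for k in ("fat", "carb", "protein", "fibre",
                                      "salt")
                )
                if solids <= 100.0:
                    break
                resampled += 1
            else:
                raise RuntimeError(
                    f"could not sample a feasible composition for group "
                    f"{group_name} after {_MAX_RESAMPLES} tries"
                )
            water = 100.0 - solids
            if scen.energy is not None:
                energy = float(scen.energy.sample(rng, 1)[0])
            else:
                energy = sum(
                    ENERGY_KCAL_PER_G[k] * draw[k]
                    for k in ("fat", "carb", "protein", "fibre")
                )
            items.append(
                FoodItem(
                    item_id=f"{group_name}-{i:05d}",
                    name=f"synthetic {group_name.lower()} item {i}",
                    subgroup_code="DRK" if is_drink else "FOOD",
                    nova_group=nova,
                    is_drink=is_drink,
                    energy_kcal=round(energy, 2),
                    fat_g=round(draw["fat"], 3),
                    satfat_g=round(min(draw["satfat"], draw["fat"]), 3),
                    sugar_g=round(min(draw["sugar"], draw["carb"]), 3),
                    salt_g=round(draw["salt"], 3),
                    protein_g=round(draw["protein"], 3),
                    fibre_g=round(draw["fibre"], 3),
                    carb_g=round(draw["carb"], 3),
                    water_g=round(water, 3),
                )
            )
    for item in items:
        item.validate()
    return Databank(
        items=items,
        provenance=(
            f"synthetic scenario seed={cfg.seed}; "
            f"{resampled} infeasible compositions resampled"
        ),
    )


# ---------------------------------------------------------------------------
# deterministic printed-counts fixture
# ---------------------------------------------------------------------------


class FixtureInfeasibleError(ValueError):
    """The fixture's target cell counts are mutually inconsistent."""


@dataclass(frozen=True)
class GroupFixture:
    """Target marginal outcome counts for one NOVA group.

    ``hpf_*`` counts partition the group's hyper-palatable food items by
    cluster membership pattern (cluster 1 only, 2 only, 3 only, and the
    1-and-2 overlap); drinks never count toward them.
    """

    n_total: int
    n_any_red: int
    n_no_green: int
    n_no_red_two_green: int
    n_drinks: int = 0
    hpf_c1_only: int = 0
    hpf_c2_only: int = 0
    hpf_c3_only: int = 0
    hpf_c1c2: int = 0

    @property
    def hpf_total(self) -> int:
        return (self.hpf_c1_only + self.hpf_c2_only + self.hpf_c3_only
                + self.hpf_c1c2)


@dataclass(frozen=True)
class FixtureSpec:
    """Per-group target counts, plus unclassifiable padding items.

    ``n_excluded`` items outside the NOVA classification and
    ``n_unlinked`` items with missing nutrient data are appended so that
    databank filtering is exercised end to end.
    """

    groups: dict[str, GroupFixture]
    n_excluded: int = 0
    n_unlinked: int = 0


#: Marginal counts reproducing a published UK databank analysis:
#: 2980 classifiable items (plus 109 excluded and 16 unlinked), any-red /
#: no-green / no-red-two-green margins per NOVA group and hyper-palatable
#: cluster memberships (clusters 642/421/365, any-cluster 1246 of 2665
#: foods, 994 ultra-processed).
PRINTED_COUNTS = FixtureSpec(
    groups={
        "MPF": GroupFixture(
            n_total=986, n_any_red=166, n_no_green=8,
            n_no_red_two_green=738, n_drinks=150,
            hpf_c1_only=60, hpf_c2_only=50, hpf_c3_only=10, hpf_c1c2=6,
        ),
        "PCI": GroupFixture(
            n_total=61, n_any_red=52, n_no_green=11,
            n_no_red_two_green=9, n_drinks=0,
            hpf_c1_only=6, hpf_c2_only=3,
        ),
        "PF": GroupFixture(
            n_total=283, n_any_red=121, n_no_green=20,
            n_no_red_two_green=102, n_drinks=5,
            hpf_c1_only=60, hpf_c2_only=38, hpf_c3_only=13, hpf_c1c2=6,
        ),
        "UPF": GroupFixture(
            n_total=1650, n_any_red=795, n_no_green=231,
            n_no_red_two_green=554, n_drinks=160,
            hpf_c1_only=334, hpf_c2_only=148, hpf_c3_only=342, hpf_c1c2=170,
        ),
    },
    n_excluded=109,
    n_unlinked=16,
)


# Archetype nutrient vectors, g/100 g (energy kcal/100 g). Keyed by
# (light pattern, hpf category). Patterns: P1 = GGGG, P2 = one green +
# three ambers, P3 = one red + three ambers (no green), P4 = one red +
# one green + two ambers. Values sit >= 10 % away from every default
# cut-off. Field order: fat, satfat, sugar, salt, carb, protein, fibre,
# water, energy.
_ARCHETYPES: dict[tuple[str, str], tuple[float, ...]] = {
    ("P1", "none"):  (1.0, 0.3, 3.0, 0.10, 8.0, 2.0, 1.0, 80.0, 100.0),
    ("P1", "c2"):    (2.0, 0.5, 4.0, 0.10, 5.0, 2.0, 1.0, 85.0, 70.0),
    ("P2", "none"):  (5.0, 2.0, 8.0, 0.10, 10.0, 3.0, 1.0, 70.0, 250.0),
    ("P2", "c3"):    (4.0, 2.0, 3.0, 0.60, 60.0, 3.0, 2.0, 25.0, 300.0),
    ("P3", "none"):  (20.0, 3.0, 8.0, 0.40, 10.0, 5.0, 2.0, 40.0, 400.0),
    ("P3", "c1c2"):  (20.0, 3.0, 15.0, 1.00, 16.0, 4.0, 1.0, 40.0, 250.0),
    ("P4", "none"):  (20.0, 3.0, 2.0, 0.40, 8.0, 5.0, 1.0, 50.0, 400.0),
    ("P4", "c1"):    (20.0, 3.0, 2.0, 1.00, 10.0, 5.0, 2.0, 55.0, 300.0),
    ("P4", "c2"):    (10.0, 3.0, 25.0, 0.20, 30.0, 4.0, 1.0, 50.0, 400.0),
    ("P4", "c3"):    (6.0, 6.0, 3.0, 0.60, 60.0, 4.0, 1.0, 25.0, 300.0),
    ("P4", "c1c2"):  (20.0, 1.0, 15.0, 1.00, 16.0, 4.0, 1.0, 40.0, 250.0),
    # all-zero drink: four greens on the drink basis, zero energy
    ("P1", "drink"): (0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 100.0, 0.0),
}


def _allocate(group: str, fx: GroupFixture) -> list[tuple[str, str, int]]:
    """Distribute one group's target margins over archetype cells.

    Pattern capacities follow from the margins: P1 carries the
    no-red-two-green items (drinks included), P2 the remaining no-red
    items, P3 the no-green items (all placed among red-bearing items) and
    P4 the remaining red-bearing items. Hyper-palatable categories are
    then packed into compatible patterns. Raises
    :class:`FixtureInfeasibleError` naming the violated constraint.
    """
    def require(ok: bool, constraint: str) -> None:
        if not ok:
            raise FixtureInfeasibleError(f"group {group}: {constraint}")

    n_no_red = fx.n_total - fx.n_any_red
    require(n_no_red >= 0, "n_any_red exceeds n_total")
    require(fx.n_no_green <= fx.n_any_red,
            "n_no_green exceeds n_any_red (no-green items carry a red)")
    require(fx.n_no_red_two_green <= n_no_red,
            "n_no_red_two_green exceeds the no-red count")
    p1 = fx.n_no_red_two_green
    p2 = n_no_red - p1
    p3 = fx.n_no_green
    p4 = fx.n_any_red - p3
    require(fx.n_drinks <= p1, "drinks exceed the all-green capacity")

    cells: dict[tuple[str, str], int] = {}

    def put(pattern: str, category: str, count: int) -> None:
        if count:
            cells[(pattern, category)] = cells.get((pattern, category), 0) \
                + count

    # drinks are all-green archetypes
    put("P1", "drink", fx.n_drinks)

    # cluster 1+2 overlap: red-no-green archetype first, else red+green
    c1c2_p3 = min(fx.hpf_c1c2, p3)
    put("P3", "c1c2", c1c2_p3)
    c1c2_p4 = fx.hpf_c1c2 - c1c2_p3
    # cluster 1 only and the c1c2 remainder need a red-bearing archetype
    p4_used = c1c2_p4 + fx.hpf_c1_only
    require(p4_used <= p4, "fat+Na hyper-palatable items exceed red capacity")
    put("P4", "c1c2", c1c2_p4)
    put("P4", "c1", fx.hpf_c1_only)
    # cluster 3 only: prefer P4, overflow to the one-green amber pattern
    c3_p4 = min(fx.hpf_c3_only, p4 - p4_used)
    p4_used += c3_p4
    c3_p2 = fx.hpf_c3_only - c3_p4
    require(c3_p2 <= p2, "carb+Na hyper-palatable items exceed capacity")
    put("P4", "c3", c3_p4)
    put("P2", "c3", c3_p2)
    # cluster 2 only: all-green food slots first, overflow to P4
    p1_food = p1 - fx.n_drinks
    c2_p1 = min(fx.hpf_c2_only, p1_food)
    c2_p4 = fx.hpf_c2_only - c2_p1
    require(c2_p4 <= p4 - p4_used,
            "fat+sugar hyper-palatable items exceed capacity")
    p4_used += c2_p4
    put("P1", "c2", c2_p1)
    put("P4", "c2", c2_p4)

    put("P1", "none", p1_food - c2_p1)
    put("P2", "none", p2 - c3_p2)
    put("P3", "none", p3 - c1c2_p3)
    put("P4", "none", p4 - p4_used)
    return [(p, c, n) for (p, c), n in sorted(cells.items())]


def fixture_printed_counts(spec: FixtureSpec = PRINTED_COUNTS) -> Databank:
    """Deterministic databank hitting every target margin exactly."""
    items: list[FoodItem] = []
    for group in sorted(spec.groups):
        fx = spec.groups[group]
        nova = NovaGroup.parse(group)
        counter = 0
        for pattern, category, count in _allocate(group, fx):
            fat, satfat, sugar, salt, carb, protein, fibre, water, energy = \
                _ARCHETYPES[(pattern, category)]
            for _ in range(count):
                items.append(
                    FoodItem(
                        item_id=f"{group}-{counter:05d}",
                        name=f"fixture {group} {pattern}/{category}",
                        subgroup_code=pattern,
                        nova_group=nova,
                        is_drink=category == "drink",
                        energy_kcal=energy,
                        fat_g=fat, satfat_g=satfat, sugar_g=sugar,
                        salt_g=salt, carb_g=carb, protein_g=protein,
                        fibre_g=fibre, water_g=water,
                    )
                )
                counter += 1
    for i in range(spec.n_excluded):
        items.append(
            FoodItem(
                item_id=f"EXC-{i:05d}",
                name="fixture supplement (outside classification)",
                nova_group=NovaGroup.EXCLUDED,
                is_drink=False,
                energy_kcal=10.0, fat_g=0.5, satfat_g=0.1, sugar_g=0.5,
                salt_g=0.01,
            )
        )
    for i in range(spec.n_unlinked):
        items.append(
            FoodItem(
                item_id=f"UNL-{i:05d}",
                name="fixture item without nutrient linkage",
                nova_group=NovaGroup.UPF,
                is_drink=False,
            )
        )
    for item in items:
        item.validate()
    return Databank(items=items, provenance="printed-counts fixture")
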