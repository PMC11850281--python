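"""Food-group taxonomy for dietary-diversity and production-diversity scoring.

The household dietary diversity score (HDDS) is built on 12 standard food
groups.  Three of them — spices/condiments/beverages, sugar/sweets and
oils/fats — carry little nutrient density and are excluded from scoring, so
all diversity scores in this package run over the remaining nine
"nutritious" groups.

A :class:`FoodTaxonomy` maps consumption items to food groups and farm
species to (possibly several) food groups.  Livestock species typically map
to more than one group (cattle produce both meat and milk); non-food cash
crops (cotton, coffee, tea, tobacco) map to no food group at all but still
count as produced species.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

#: The 12 HDDS food groups, in canonical order.
FOOD_GROUPS: tuple[str, ...] = (
    "cereals",
    "legumes_nuts_seeds",
    "vegetables",
    "roots_tubers",
    "fruits",
    "eggs",
    "milk",
    "fish",
    "meat",
    "spices_condiments_beverages",
    "sugar_sweets",
    "oils_fats",
)

#: Low-nutrient-density groups excluded from all diversity scores.
EXCLUDED_GROUPS: frozenset[str] = frozenset(
    {"spices_condiments_beverages", "sugar_sweets", "oils_fats"}
)

#: The 9 groups retained for HDDS / FPD / LPD scoring.
NUTRITIOUS_GROUPS: tuple[str, ...] = tuple(
    g for g in FOOD_GROUPS if g not in EXCLUDED_GROUPS
)


class TaxonomyError(ValueError):
    """Raised when a taxonomy violates its structural invariants."""


@dataclass(frozen=True)
class Species:
    """One crop or livestock species a farm can produce."""

    code: str
    groups: frozenset[str]
    kind: str  # "crop" | "livestock"
    cash_crop: bool = False


@dataclass
class FoodTaxonomy:
    """Registry mapping species and consumption items to food groups."""

    species: dict[str, Species]
    items: dict[str, str]
    groups: tuple[str, ...] = FOOD_GROUPS
    nutritious: tuple[str, ...] = NUTRITIOUS_GROUPS

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if len(self.groups) != 12:
            raise TaxonomyError(f"expected 12 food groups, got {len(self.groups)}")
        if len(self.nutritious) != 9:
            raise TaxonomyError(
                f"expected 9 nutritious groups, got {len(self.nutritious)}"
            )
        if EXCLUDED_GROUPS & set(self.nutritious):
            raise TaxonomyError("excluded groups must not be marked nutritious")
        for sp in self.species.values():
            unknown = sp.groups - set(self.groups)
            if unknown:
                raise TaxonomyError(f"species {sp.code!r} maps to unknown groups {sorted(unknown)}")
            if sp.kind not in ("crop", "livestock"):
                raise TaxonomyError(f"species {sp.code!r} has invalid kind {sp.kind!r}")
            if sp.cash_crop and sp.groups:
                raise TaxonomyError(
                    f"cash-crop species {sp.code!r} must map to zero food groups"
                )
        for item, grp in self.items.items():
            if grp not in self.groups:
                raise TaxonomyError(f"item {item!r} maps to unknown group {grp!r}")

    # ------------------------------------------------------------------
    # tabular views
    # ------------------------------------------------------------------

    def species_group_frame(self) -> pd.DataFrame:
        """Long (species_code, food_group, kind) table; cash crops absent."""
        rows = [
            (sp.code, g, sp.kind)
            for sp in self.species.values()
            for g in sorted(sp.groups)
        ]
        return pd.DataFrame(rows, columns=["species_code", "food_group", "kind"])

    def item_group_frame(self) -> pd.DataFrame:
        rows = sorted(self.items.items())
        return pd.DataFrame(rows, columns=["item_code", "food_group"])

    def items_for_group(self, group: str) -> list[str]:
        return sorted(i for i, g in self.items.items() if g == group)

    def to_frame(self) -> pd.DataFrame:
        """Canonical CSV schema: code, kind, class, groups, cash_crop."""
        rows = []
        for code in sorted(self.species):
            sp = self.species[code]
            rows.append(
                (code, "species", sp.kind, ";".join(sorted(sp.groups)), int(sp.cash_crop))
            )
        for code in sorted(self.items):
            rows.append((code, "item", "item", self.items[code], 0))
        return pd.DataFrame(
            rows, columns=["code", "kind", "class", "groups", "cash_crop"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FoodTaxonomy":
        required = {"code", "kind", "class", "groups", "cash_crop"}
        missing = required - set(df.columns)
        if missing:
            raise TaxonomyError(f"taxonomy table missing columns {sorted(missing)}")
        species: dict[str, Species] = {}
        items: dict[str, str] = {}
        cols = zip(df["code"], df["kind"], df["class"], df["groups"], df["cash_crop"])
        for code, kind, klass, groups, cash in cols:
            code = str(code)
            grps = frozenset(g for g in str(groups).split(";") if g)
            if kind == "species":
                species[code] = Species(
                    code=code, groups=grps, kind=str(klass), cash_crop=bool(int(cash))
                )
            elif kind == "item":
                if len(grps) != 1:
                    raise TaxonomyError(f"item {code!r} must map to exactly one group")
                items[code] = next(iter(grps))
            else:
                raise TaxonomyError(f"unknown taxonomy kind {kind!r} for {code!r}")
        return cls(species=species, items=items)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "FoodTaxonomy":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))


# ----------------------------------------------------------------------
# Default taxonomy
# ----------------------------------------------------------------------

_CROPS: dict[str, str] = {
    # cereals
    "maize": "cereals",
    "sorghum": "cereals",
    "millet": "cereals",
    "rice": "cereals",
    "wheat": "cereals",
    "teff": "cereals",
    "barley": "cereals",
    # legumes, nuts and seeds
    "beans": "legumes_nuts_seeds",
    "cowpea": "legumes_nuts_seeds",
    "groundnut": "legumes_nuts_seeds",
    "soybean": "legumes_nuts_seeds",
    "pigeonpea": "legumes_nuts_seeds",
    "sesame": "legumes_nuts_seeds",
    # vegetables
    "tomato": "vegetables",
    "cabbage": "vegetables",
    "onion": "vegetables",
    "eggplant": "vegetables",
    "okra": "vegetables",
    "leafy_greens": "vegetables",
    "pepper": "vegetables",
    # white roots and tubers
    "cassava": "roots_tubers",
    "sweet_potato": "roots_tubers",
    "potato": "roots_tubers",
    "yam": "roots_tubers",
    "cocoyam": "roots_tubers",
    # fruits
    "banana": "fruits",
    "mango": "fruits",
    "avocado": "fruits",
    "papaya": "fruits",
    "orange": "fruits",
    "pineapple": "fruits",
}

_LIVESTOCK: dict[str, tuple[str, ...]] = {
    "cattle": ("meat", "milk"),
    "goat": ("meat", "milk"),
    "sheep": ("meat",),
    "chicken": ("meat", "eggs"),
    "duck": ("meat", "eggs"),
    "pig": ("meat",),
    "camel": ("meat", "milk"),
    "fish_pond": ("fish",),
}

_CASH_CROPS: tuple[str, ...] = ("cotton", "coffee", "tea", "tobacco", "sugarcane")

_ITEMS: dict[str, str] = {
    "maize_flour": "cereals",
    "rice_grain": "cereals",
    "bread": "cereals",
    "beans_dry": "legumes_nuts_seeds",
    "groundnut_shelled": "legumes_nuts_seeds",
    "tomato_fresh": "vegetables",
    "onion_fresh": "vegetables",
    "greens_fresh": "vegetables",
    "cassava_flour": "roots_tubers",
    "potato_fresh": "roots_tubers",
    "banana_fresh": "fruits",
    "mango_fresh": "fruits",
    "eggs_fresh": "eggs",
    "milk_fresh": "milk",
    "fish_dried": "fish",
    "fish_fresh": "fish",
    "beef": "meat",
    "goat_meat": "meat",
    "chicken_meat": "meat",
    "salt_spices": "spices_condiments_beverages",
    "tea_leaves": "spices_condiments_beverages",
    "sugar": "sugar_sweets",
    "cooking_oil": "oils_fats",
}


def default_taxonomy() -> FoodTaxonomy:
    """Bundled taxonomy: 35 crop/livestock species, 5 cash crops, 23 items."""
    species: dict[str, Species] = {}
    for code, grp in _CROPS.items():
        species[code] = Species(code, frozenset({grp}), "crop")
    for code, grps in _LIVESTOCK.items():
        species[code] = Species(code, frozenset(grps), "livestock")
    for code in _CASH_CROPS:
        species[code] = Species(code, frozenset(), "crop", cash_crop=True)
    return FoodTaxonomy(species=species, items=dict(_ITEMS))
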