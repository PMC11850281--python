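"""Household-wave diversity scores.

Three score families are computed from the raw panel records:

* **HDDS** — the household dietary diversity score: number of distinct
  nutritious food groups (out of 9) consumed over the 7-day recall, in
  total and separately by acquisition source (own production, market
  purchase, other).  The three low-nutrient groups (sugar/sweets,
  oils/fats, spices/condiments/beverages) never count.
* **FPD** — farm production diversity: number of distinct species produced
  (cash crops included) and number of distinct nutritious food groups
  produced (cash crops contribute none), plus crop/livestock splits and a
  cash-crop indicator.
* **Subsistence** — share of total consumption value obtained from own
  production, and a subsistence flag for households with strictly more
  than 50% of value from own production.
"""

from __future__ import annotations

import logging
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .data_model import PanelDataset
from .taxonomy import EXCLUDED_GROUPS, FoodTaxonomy

log = logging.getLogger(__name__)

SUBSISTENCE_THRESHOLD = 0.5

SCORE_COLUMNS: tuple[str, ...] = (
    "household_id",
    "wave",
    "hdds",
    "hdds_own",
    "hdds_market",
    "hdds_other",
    "fpd_species",
    "fpd_groups",
    "crop_groups",
    "livestock_groups",
    "cash_crop",
    "own_value_share",
    "subsistence",
)

_SOURCE_SCORE = {
    "own_production": "hdds_own",
    "purchase": "hdds_market",
    "other": "hdds_other",
}


class HddsResult(NamedTuple):
    hdds: int
    hdds_own: int
    hdds_market: int
    hdds_other: int


class FpdResult(NamedTuple):
    fpd_species: int
    fpd_groups: int
    crop_groups: int
    livestock_groups: int
    cash_crop: int


class ScoreError(ValueError):
    """Raised when a record cannot be resolved against the taxonomy."""


def compute_hdds(
    records: Iterable[tuple[str, str]], taxonomy: FoodTaxonomy
) -> HddsResult:
    """HDDS for one household-wave from (item_code, source) records."""
    by_source: dict[str, set[str]] = {s: set() for s in _SOURCE_SCORE}
    total: set[str] = set()
    for item, source in records:
        try:
            group = taxonomy.items[item]
        except KeyError:
            raise ScoreError(f"unresolvable consumption item {item!r}") from None
        if source not in by_source:
            raise ScoreError(f"unknown consumption source {source!r}")
        if group in EXCLUDED_GROUPS:
            continue
        total.add(group)
        by_source[source].add(group)
    return HddsResult(
        hdds=len(total),
        hdds_own=len(by_source["own_production"]),
        hdds_market=len(by_source["purchase"]),
        hdds_other=len(by_source["other"]),
    )


def compute_fpd(species_codes: Iterable[str], taxonomy: FoodTaxonomy) -> FpdResult:
    """FPD metrics for one farm-wave from its produced species codes."""
    species = set()
    groups: set[str] = set()
    crop_groups: set[str] = set()
    livestock_groups: set[str] = set()
    cash = 0
    for code in species_codes:
        try:
            sp = taxonomy.species[code]
        except KeyError:
            raise ScoreError(f"unresolvable species {code!r}") from None
        species.add(code)
        if sp.cash_crop:
            cash = 1
        nutritious = sp.groups - EXCLUDED_GROUPS
        groups |= nutritious
        if sp.kind == "crop":
            crop_groups |= nutritious
        else:
            livestock_groups |= nutritious
    return FpdResult(
        fpd_species=len(species),
        fpd_groups=len(groups),
        crop_groups=len(crop_groups),
        livestock_groups=len(livestock_groups),
        cash_crop=cash,
    )


def compute_subsistence(
    records: Iterable[tuple[str, float]], threshold: float = SUBSISTENCE_THRESHOLD
) -> tuple[float, int]:
    """Own-production value share and subsistence flag for one household-wave.

    ``records`` are (source, value) pairs.  The flag is 1 only when the
    share strictly exceeds the threshold ("more than 50%").  A zero total
    value is undefined and raises.
    """
    total = 0.0
    own = 0.0
    for source, value in records:
        total += value
        if source == "own_production":
            own += value
    if total <= 0:
        raise ScoreError("zero total consumption value: share undefined")
    share = own / total
    return share, int(share > threshold)


# ----------------------------------------------------------------------
# Vectorized panel scoring
# ----------------------------------------------------------------------


def score_panel(panel: PanelDataset) -> pd.DataFrame:
    """One score row per household-wave, in household/wave order.

    Household-waves with no consumption records score 0 on all HDDS
    components and carry a missing (NaN) value share; non-farm
    household-waves score 0 on all production metrics.
    """
    tax = panel.taxonomy
    keys = panel.households[["household_id", "wave"]].copy()

    # --- consumption side ---------------------------------------------
    cons = panel.consumption
    unknown = set(cons["item_code"]) - set(tax.items) if len(cons) else set()
    if unknown:
        raise ScoreError(f"unresolvable consumption items {sorted(unknown)[:5]}")
    if len(cons):
        c = cons.merge(tax.item_group_frame(), on="item_code", how="left")
        nutritious = c[~c["food_group"].isin(EXCLUDED_GROUPS)]
        hdds = (
            nutritious.drop_duplicates(["household_id", "wave", "food_group"])
            .groupby(["household_id", "wave"], sort=False)
            .size()
            .rename("hdds")
        )
        by_src = (
            nutritious.drop_duplicates(["household_id", "wave", "food_group", "source"])
            .groupby(["household_id", "wave", "source"], sort=False)
            .size()
            .unstack("source", fill_value=0)
        )
        by_src = by_src.rename(columns=_SOURCE_SCORE)
        for col in _SOURCE_SCORE.values():
            if col not in by_src.columns:
                by_src[col] = 0
        value_tot = c.groupby(["household_id", "wave"], sort=False)["value"].sum()
        value_own = (
            c[c["source"] == "own_production"]
            .groupby(["household_id", "wave"], sort=False)["value"]
            .sum()
        )
        cons_scores = pd.concat(
            [hdds, by_src[list(_SOURCE_SCORE.values())]], axis=1
        ).reset_index()
        shares = (
            pd.concat([value_tot.rename("total"), value_own.rename("own")], axis=1)
            .fillna({"own": 0.0})
            .reset_index()
        )
    else:
        cons_scores = pd.DataFrame(
            columns=["household_id", "wave", "hdds", *_SOURCE_SCORE.values()]
        )
        shares = pd.DataFrame(columns=["household_id", "wave", "total", "own"])

    # --- production side ----------------------------------------------
    prod = panel.production
    unknown = set(prod["species_code"]) - set(tax.species) if len(prod) else set()
    if unknown:
        raise ScoreError(f"unresolvable species {sorted(unknown)[:5]}")
    if len(prod):
        n_species = (
            prod.drop_duplicates()
            .groupby(["household_id", "wave"], sort=False)
            .size()
            .rename("fpd_species")
        )
        cash_codes = {c for c, sp in tax.species.items() if sp.cash_crop}
        cash = (
            prod.assign(is_cash=prod["species_code"].isin(cash_codes).astype(int))
            .groupby(["household_id", "wave"], sort=False)["is_cash"]
            .max()
            .rename("cash_crop")
        )
        pg = prod.merge(tax.species_group_frame(), on="species_code", how="inner")
        pg = pg[~pg["food_group"].isin(EXCLUDED_GROUPS)]

        def _group_count(frame: pd.DataFrame, name: str) -> pd.Series:
            return (
                frame.drop_duplicates(["household_id", "wave", "food_group"])
                .groupby(["household_id", "wave"], sort=False)
                .size()
                .rename(name)
            )

        prod_scores = pd.concat(
            [
                n_species,
                _group_count(pg, "fpd_groups"),
                _group_count(pg[pg["kind"] == "crop"], "crop_groups"),
                _group_count(pg[pg["kind"] == "livestock"], "livestock_groups"),
                cash,
            ],
            axis=1,
        ).reset_index()
    else:
        prod_scores = pd.DataFrame(
            columns=[
                "household_id",
                "wave",
                "fpd_species",
                "fpd_groups",
                "crop_groups",
                "livestock_groups",
                "cash_crop",
            ]
        )

    out = keys.merge(cons_scores, on=["household_id", "wave"], how="left")
    out = out.merge(shares, on=["household_id", "wave"], how="left")
    out = out.merge(prod_scores, on=["household_id", "wave"], how="left")

    count_cols = [
        "hdds",
        "hdds_own",
        "hdds_market",
        "hdds_other",
        "fpd_species",
        "fpd_groups",
        "crop_groups",
        "livestock_groups",
        "cash_crop",
    ]
    out[count_cols] = out[count_cols].fillna(0).astype(int)

    with np.errstate(invalid="ignore", divide="ignore"):
        share = out["own"] / out["total"]
    n_undefined = int(share.isna().sum())
    if n_undefined:
        log.info(
            "score_panel: %d household-waves with zero/absent consumption value; "
            "own_value_share left missing",
            n_undefined,
        )
    out["own_value_share"] = share
    out["subsistence"] = np.where(
        share.isna(), np.nan, (share > SUBSISTENCE_THRESHOLD).astype(float)
    )
    out = out.drop(columns=["total", "own"])
    out = out[list(SCORE_COLUMNS)].sort_values(["household_id", "wave"], kind="mergesort")
    return out.reset_index(drop=True)
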