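"""Local and regional production diversity (LPD).

LPD at a spatial scale (village, town or district) in a wave is the number
of distinct nutritious food groups produced by the *sampled* farm
households of that unit — a lower bound on true local diversity, since
non-sampled farms may produce more.  Because the number of sampled farmers
varies across units, every aggregate also carries ``n_farmers`` so models
can control for it.

Village-scale estimation excludes (a) households with a missing village
classification and (b) village-waves with at most one sampled farm
household, where farm-level and village-level diversity would coincide by
construction.
"""

from __future__ import annotations

import logging

import pandas as pd

from .data_model import PanelDataset
from .taxonomy import EXCLUDED_GROUPS

log = logging.getLogger(__name__)

SCALES = ("village", "town", "district")
_UNIT_COLUMN = {"village": "village_id", "town": "town_id", "district": "district_id"}

LPD_COLUMNS = ("scale", "unit_id", "wave", "lpd", "n_farmers", "valid")


def aggregate_lpd(panel: PanelDataset, scale: str) -> pd.DataFrame:
    """Per unit-wave: distinct nutritious food groups produced by sampled
    farms (``lpd``) and the number of sampled farm households
    (``n_farmers``).  Units observed without any sampled farmer get
    ``lpd=0, n_farmers=0, valid=0``."""
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")
    unit = _UNIT_COLUMN[scale]
    hh = panel.households
    known = hh[hh[unit].notna()]
    n_missing = len(hh) - len(known)
    if n_missing:
        log.info("aggregate_lpd(%s): %d observations with missing %s excluded",
                 scale, n_missing, unit)

    units = known[[unit, "wave"]].drop_duplicates().rename(columns={unit: "unit_id"})

    farmers = known[known["is_farmer"] == 1]
    n_farmers = (
        farmers.groupby([unit, "wave"], sort=False)["household_id"]
        .nunique()
        .rename("n_farmers")
        .reset_index()
        .rename(columns={unit: "unit_id"})
    )

    prod = panel.production.merge(
        known[["household_id", "wave", unit]], on=["household_id", "wave"], how="inner"
    )
    groups = prod.merge(
        panel.taxonomy.species_group_frame()[["species_code", "food_group"]],
        on="species_code",
        how="inner",
    )
    groups = groups[~groups["food_group"].isin(EXCLUDED_GROUPS)]
    lpd = (
        groups.drop_duplicates([unit, "wave", "food_group"])
        .groupby([unit, "wave"], sort=False)
        .size()
        .rename("lpd")
        .reset_index()
        .rename(columns={unit: "unit_id"})
    )

    out = units.merge(n_farmers, on=["unit_id", "wave"], how="left")
    out = out.merge(lpd, on=["unit_id", "wave"], how="left")
    out[["n_farmers", "lpd"]] = out[["n_farmers", "lpd"]].fillna(0).astype(int)
    out["scale"] = scale
    out["valid"] = (out["n_farmers"] > 0).astype(int)
    out = out[list(LPD_COLUMNS)].sort_values(["unit_id", "wave"], kind="mergesort")
    return out.reset_index(drop=True)


def apply_village_exclusions(records: pd.DataFrame) -> pd.DataFrame:
    """Mark village-waves with at most one sampled farm household invalid.

    Applied per village-wave: a village can be a singleton in one wave and
    not in another.  No-op at town/district scale.
    """
    out = records.copy()
    if not len(out):
        return out
    singleton = (out["scale"] == "village") & (out["n_farmers"] <= 1)
    if singleton.any():
        log.info("apply_village_exclusions: %d singleton village-waves marked invalid",
                 int(singleton.sum()))
    out.loc[singleton, "valid"] = 0
    return out


def join_lpd_to_households(
    panel: PanelDataset, records: pd.DataFrame, scale: str
) -> pd.DataFrame:
    """Attach the unit-wave ``lpd`` and ``n_farmers`` of the requested
    scale to each household-wave.  Households in invalid units (or with a
    missing unit id) are dropped from the returned estimation frame."""
    if scale not in SCALES:
        raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")
    unit = _UNIT_COLUMN[scale]
    recs = records[records["scale"] == scale]
    if not len(recs):
        raise ValueError(f"no {scale}-scale records supplied")
    hh = panel.households[panel.households[unit].notna()]
    joined = hh.merge(
        recs[["unit_id", "wave", "lpd", "n_farmers", "valid"]].rename(
            columns={"unit_id": unit}
        ),
        on=[unit, "wave"],
        how="inner",
    )
    if len(joined) < len(hh):
        missing = len(hh) - len(joined)
        raise ValueError(
            f"geography mismatch: {missing} household-waves have no {scale} aggregate"
        )
    kept = joined[joined["valid"] == 1].drop(columns=["valid"])
    log.info("join_lpd_to_households(%s): %d of %d household-waves in valid units",
             scale, len(kept), len(joined))
    return kept.reset_index(drop=True)
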