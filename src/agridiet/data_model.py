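"""Panel data container, validation and CSV interchange.

The interchange format is a directory of plain CSV files:

``households.csv``
    One row per household-wave: identifiers, village membership and the
    household covariates used in the regressions.
``geography.csv``
    One row per village: nesting into town/district/country and the
    village-level distance to the nearest urban centre (km).
``consumption.csv``
    7-day food-consumption recall records: one row per household-wave,
    item and acquisition source, with the monetary value consumed.
``production.csv``
    One row per species produced by a farm household in a wave.
``taxonomy.csv``
    The food-group taxonomy (see :mod:`agridiet.taxonomy`).
``retention.csv`` (optional)
    Panel retention indicators per household-wave, used for
    inverse-probability attrition weighting.

All writers emit canonically sorted rows and columns so that outputs are
diffable and the read/write round trip is the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .taxonomy import FoodTaxonomy, default_taxonomy

log = logging.getLogger(__name__)

SOURCES: tuple[str, ...] = ("own_production", "purchase", "other")

#: household covariates (beyond identifiers) carried by households.csv
COVARIATE_COLUMNS: tuple[str, ...] = (
    "head_sex",
    "head_age",
    "head_literate",
    "landholding",
    "phone",
    "motorbike",
    "electricity",
    "offfarm_wage",
    "self_employment",
    "cash_crop",
    "weather_shock",
    "is_farmer",
)

HOUSEHOLD_COLUMNS: tuple[str, ...] = (
    "household_id",
    "country",
    "district_id",
    "town_id",
    "village_id",
    "wave",
) + COVARIATE_COLUMNS

GEOGRAPHY_COLUMNS: tuple[str, ...] = (
    "village_id",
    "town_id",
    "district_id",
    "country",
    "distance_urban",
)

CONSUMPTION_COLUMNS: tuple[str, ...] = (
    "household_id",
    "wave",
    "item_code",
    "source",
    "value",
)

PRODUCTION_COLUMNS: tuple[str, ...] = ("household_id", "wave", "species_code")

RETENTION_COLUMNS: tuple[str, ...] = ("household_id", "wave", "retained")

_BINARY_COLUMNS = (
    "head_sex",
    "head_literate",
    "phone",
    "motorbike",
    "electricity",
    "offfarm_wage",
    "self_employment",
    "cash_crop",
    "weather_shock",
    "is_farmer",
)


class SchemaError(ValueError):
    """A CSV file does not conform to the documented schema."""


class PanelValidationError(ValueError):
    """A dataset violates a declared invariant."""


@dataclass
class PanelDataset:
    """Validated long-format panel of household-wave observations.

    ``households`` carries one row per household-wave including the joined
    village geography (``distance_urban``).  ``wave_calendar`` maps each
    country to the full list of survey waves fielded there; if not given it
    is derived from the observed waves.
    """

    households: pd.DataFrame
    consumption: pd.DataFrame
    production: pd.DataFrame
    taxonomy: FoodTaxonomy
    wave_calendar: dict[str, tuple[int, ...]] = field(default_factory=dict)
    retention: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.wave_calendar:
            self.wave_calendar = derive_wave_calendar(self.households)

    # convenience ------------------------------------------------------

    @property
    def n_observations(self) -> int:
        return len(self.households)

    def observation_keys(self) -> pd.DataFrame:
        return self.households[["household_id", "wave"]]

    def copy(self) -> "PanelDataset":
        return PanelDataset(
            households=self.households.copy(),
            consumption=self.consumption.copy(),
            production=self.production.copy(),
            taxonomy=self.taxonomy,
            wave_calendar=dict(self.wave_calendar),
            retention=None if self.retention is None else self.retention.copy(),
        )


def derive_wave_calendar(households: pd.DataFrame) -> dict[str, tuple[int, ...]]:
    cal = (
        households.groupby("country", sort=True)["wave"]
        .apply(lambda s: tuple(sorted(s.unique())))
        .to_dict()
    )
    return {str(k): tuple(int(w) for w in v) for k, v in cal.items()}


# ----------------------------------------------------------------------
# Validation
# ----------------------------------------------------------------------


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


def validate_panel(panel: PanelDataset) -> None:
    """Check every declared invariant; raise :class:`PanelValidationError`.

    Checks are accumulated so the error message names all problems at once.
    """
    hh = panel.households
    problems: list[str] = []

    _require_columns(hh, HOUSEHOLD_COLUMNS + ("distance_urban",), "households")
    _require_columns(panel.consumption, CONSUMPTION_COLUMNS, "consumption")
    _require_columns(panel.production, PRODUCTION_COLUMNS, "production")

    dup = hh.duplicated(subset=["household_id", "wave"])
    if dup.any():
        problems.append(
            f"households: {int(dup.sum())} duplicate (household_id, wave) keys, "
            f"e.g. {hh.loc[dup, ['household_id', 'wave']].iloc[0].tolist()}"
        )

    # strict geography nesting: each lower unit maps to exactly one parent
    with_village = hh[hh["village_id"].notna()]
    for child, parent in (
        ("village_id", "town_id"),
        ("town_id", "district_id"),
        ("district_id", "country"),
    ):
        src = with_village if child == "village_id" else hh
        n_parents = src.groupby(child, sort=False)[parent].nunique()
        bad = n_parents[n_parents > 1]
        if len(bad):
            problems.append(
                f"geography: {child} values with multiple {parent}: "
                f"{bad.index[:5].tolist()}"
            )

    for col in ("landholding", "distance_urban"):
        neg = hh[col] < 0
        if neg.any():
            problems.append(f"households: {int(neg.sum())} negative {col} values")
    for col in _BINARY_COLUMNS:
        bad = ~hh[col].isin([0, 1])
        if bad.any():
            problems.append(f"households: non-binary values in {col}")

    keys = pd.MultiIndex.from_frame(hh[["household_id", "wave"]])

    cons = panel.consumption
    if len(cons):
        bad_src = ~cons["source"].isin(SOURCES)
        if bad_src.any():
            problems.append(
                f"consumption: invalid sources {sorted(cons.loc[bad_src, 'source'].unique())}"
            )
        if (cons["value"] < 0).any():
            problems.append("consumption: negative values")
        unknown_items = set(cons["item_code"]) - set(panel.taxonomy.items)
        if unknown_items:
            problems.append(f"consumption: unresolvable items {sorted(unknown_items)[:5]}")
        ckeys = pd.MultiIndex.from_frame(cons[["household_id", "wave"]])
        orphan = ~ckeys.isin(keys)
        if orphan.any():
            ex = cons.loc[orphan, ["household_id", "wave"]].iloc[0].tolist()
            problems.append(
                f"consumption: {int(orphan.sum())} rows reference unknown "
                f"household-waves, e.g. {ex}"
            )
        dup = cons.duplicated(subset=["household_id", "wave", "item_code", "source"])
        if dup.any():
            problems.append(f"consumption: {int(dup.sum())} duplicate record keys")

    prod = panel.production
    if len(prod):
        unknown_sp = set(prod["species_code"]) - set(panel.taxonomy.species)
        if unknown_sp:
            problems.append(f"production: unresolvable species {sorted(unknown_sp)[:5]}")
        pkeys = pd.MultiIndex.from_frame(prod[["household_id", "wave"]])
        orphan = ~pkeys.isin(keys)
        if orphan.any():
            ex = prod.loc[orphan, ["household_id", "wave"]].iloc[0].tolist()
            problems.append(
                f"production: {int(orphan.sum())} rows reference unknown "
                f"household-waves, e.g. {ex}"
            )
        dup = prod.duplicated()
        if dup.any():
            problems.append(f"production: {int(dup.sum())} duplicate records")

    if problems:
        raise PanelValidationError("; ".join(problems))


# ----------------------------------------------------------------------
# CSV interchange
# ----------------------------------------------------------------------

_SORT_KEYS = {
    "households": ["country", "district_id", "town_id", "village_id", "household_id", "wave"],
    "geography": ["country", "district_id", "town_id", "village_id"],
    "consumption": ["household_id", "wave", "item_code", "source"],
    "production": ["household_id", "wave", "species_code"],
    "retention": ["household_id", "wave"],
}


def _canonical(df: pd.DataFrame, table: str, columns: tuple[str, ...]) -> pd.DataFrame:
    out = df[list(columns)].sort_values(_SORT_KEYS[table], kind="mergesort")
    return out.reset_index(drop=True)


def write_panel(panel: PanelDataset, path: str | Path) -> list[Path]:
    """Write the interchange CSVs with canonical row/column order."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    hh = panel.households
    geography = (
        hh[hh["village_id"].notna()][list(GEOGRAPHY_COLUMNS)]
        .drop_duplicates(subset=["village_id"])
    )
    tables: dict[str, tuple[pd.DataFrame, tuple[str, ...]]] = {
        "households": (hh, HOUSEHOLD_COLUMNS),
        "geography": (geography, GEOGRAPHY_COLUMNS),
        "consumption": (panel.consumption, CONSUMPTION_COLUMNS),
        "production": (panel.production, PRODUCTION_COLUMNS),
    }
    if panel.retention is not None:
        tables["retention"] = (panel.retention, RETENTION_COLUMNS)
    written: list[Path] = []
    for name, (df, cols) in tables.items():
        f = path / f"{name}.csv"
        _canonical(df, name, cols).to_csv(f, index=False, lineterminator="\n")
        written.append(f)
    f = path / "taxonomy.csv"
    panel.taxonomy.write_csv(f)
    written.append(f)
    return written


def _read_csv(path: Path, columns: tuple[str, ...]) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"missing interchange file {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SchemaError(f"{path}: {exc}") from exc
    _require_columns(df, columns, path.name)
    return df


def read_panel(
    path: str | Path,
    taxonomy: FoodTaxonomy | None = None,
    validate: bool = True,
) -> PanelDataset:
    """Read and validate an interchange directory."""
    path = Path(path)
    if taxonomy is None:
        tax_file = path / "taxonomy.csv"
        taxonomy = FoodTaxonomy.read_csv(tax_file) if tax_file.exists() else default_taxonomy()
    hh = _read_csv(path / "households.csv", HOUSEHOLD_COLUMNS)
    geo = _read_csv(path / "geography.csv", GEOGRAPHY_COLUMNS)
    if "distance_urban" not in hh.columns:
        hh = hh.merge(geo[["village_id", "distance_urban"]], on="village_id", how="left")
    cons = _read_csv(path / "consumption.csv", CONSUMPTION_COLUMNS)
    prod = _read_csv(path / "production.csv", PRODUCTION_COLUMNS)
    retention = None
    if (path / "retention.csv").exists():
        retention = _read_csv(path / "retention.csv", RETENTION_COLUMNS)
    panel = PanelDataset(
        households=hh,
        consumption=cons,
        production=prod,
        taxonomy=taxonomy,
        retention=retention,
    )
    if validate:
        validate_panel(panel)
    return panel


# ----------------------------------------------------------------------
# Sample filters
# ----------------------------------------------------------------------

SAMPLE_RULES = ("all", "farmers_only", "balanced")


def _restrict_to_keys(panel: PanelDataset, hh: pd.DataFrame) -> PanelDataset:
    keys = pd.MultiIndex.from_frame(hh[["household_id", "wave"]])

    def keep(df: pd.DataFrame) -> pd.DataFrame:
        if not len(df):
            return df.copy()
        mask = pd.MultiIndex.from_frame(df[["household_id", "wave"]]).isin(keys)
        return df[mask].reset_index(drop=True)

    return PanelDataset(
        households=hh.reset_index(drop=True),
        consumption=keep(panel.consumption),
        production=keep(panel.production),
        taxonomy=panel.taxonomy,
        wave_calendar=dict(panel.wave_calendar),
        retention=None if panel.retention is None else panel.retention.copy(),
    )


def filter_sample(panel: PanelDataset, rule: str) -> PanelDataset:
    """Restrict the estimation sample.

    ``all``
        identity.
    ``farmers_only``
        keep household-waves with ``is_farmer == 1``.
    ``balanced``
        keep households observed in every wave of their country's calendar.
    """
    if rule not in SAMPLE_RULES:
        raise ValueError(f"unknown sample rule {rule!r}; expected one of {SAMPLE_RULES}")
    hh = panel.households
    if rule == "all":
        return panel.copy()
    if rule == "farmers_only":
        kept = hh[hh["is_farmer"] == 1]
        log.info("filter_sample(farmers_only): kept %d of %d rows", len(kept), len(hh))
        return _restrict_to_keys(panel, kept)
    # balanced
    n_waves = hh.groupby("household_id", sort=False)["wave"].transform("nunique")
    full = hh["country"].map({c: len(w) for c, w in panel.wave_calendar.items()})
    kept = hh[n_waves == full]
    log.info("filter_sample(balanced): kept %d of %d rows", len(kept), len(hh))
    return _restrict_to_keys(panel, kept)


def trim_outliers(
    panel: PanelDataset, lower: float = 0.01, upper: float = 0.99
) -> PanelDataset:
    """Drop household-waves whose total consumption value is outside the
    [lower, upper] quantiles within country-wave.  Off by default in the
    pipeline; inert on clean synthetic data."""
    totals = (
        panel.consumption.groupby(["household_id", "wave"], sort=False)["value"]
        .sum()
        .rename("total_value")
        .reset_index()
    )
    hh = panel.households.merge(totals, on=["household_id", "wave"], how="left")
    hh["total_value"] = hh["total_value"].fillna(0.0)
    grp = hh.groupby(["country", "wave"], sort=False)["total_value"]
    lo = grp.transform(lambda s: s.quantile(lower))
    hi = grp.transform(lambda s: s.quantile(upper))
    kept = hh[(hh["total_value"] >= lo) & (hh["total_value"] <= hi)]
    log.info("trim_outliers: dropped %d of %d rows", len(hh) - len(kept), len(hh))
    return _restrict_to_keys(panel, kept.drop(columns=["total_value"]))
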