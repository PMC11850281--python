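"""Synthetic LSMS-style household panel generator.

Emulates the statistical structure of multi-country living-standards
panels: households nested in villages ⊂ towns ⊂ districts ⊂ countries,
2–7 survey waves per country, farm production and 7-day food-consumption
records, household-level unobserved heterogeneity correlated with farm
production diversity (the endogeneity that CRE/FE estimation must
absorb), and monotone panel attrition.

Default calibration anchors (pooled):

* mean village distance to the nearest urban centre ≈ 31 km,
* ≈ 7 sampled farm households per village,
* ≥ 75% of farms below 2 ha of land,
* mean species per farm-wave ≈ 5.55,
* mean HDDS ≈ 5.66 and mean own-production value share ≈ 33%
  (structural mode).

Two outcome modes: ``structural`` builds an integer HDDS through an
explicit consumption mechanism (used for descriptive calibration);
``linear`` additionally writes a continuous latent diet index that
follows the estimating equation exactly — intercept, production-diversity
effects, covariate effects, household effect and i.i.d. noise — so
estimator verification is not attenuated by integer censoring.

Reproducibility: one root seed; child streams per table are derived with
fixed ``SeedSequence`` spawn keys, so adding a table never perturbs the
draws of another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import PanelDataset
from .taxonomy import (
    EXCLUDED_GROUPS,
    FoodTaxonomy,
    NUTRITIOUS_GROUPS,
    default_taxonomy,
)

log = logging.getLogger(__name__)

COUNTRY_CODES = ("ET", "MW", "NE", "NG", "TZ", "UG")

#: per-table child-stream spawn keys (fixed; see module docstring)
_STREAMS = {
    "geography": 0,
    "households": 1,
    "production": 2,
    "consumption": 3,
    "attrition": 4,
    "latent": 5,
}

#: relative prevalence of species in farm production (sampling weights)
DEFAULT_SPECIES_WEIGHTS: dict[str, float] = {
    # cereals
    "maize": 10.0, "sorghum": 3.0, "millet": 2.5, "rice": 2.0,
    "wheat": 1.2, "teff": 1.2, "barley": 1.0,
    # legumes
    "beans": 5.0, "cowpea": 2.0, "groundnut": 3.0, "soybean": 1.0,
    "pigeonpea": 1.0, "sesame": 1.0,
    # vegetables
    "tomato": 2.0, "cabbage": 1.5, "onion": 1.5, "eggplant": 1.0,
    "okra": 1.0, "leafy_greens": 2.0, "pepper": 1.0,
    # roots and tubers
    "cassava": 3.0, "sweet_potato": 2.5, "potato": 1.5, "yam": 1.5,
    "cocoyam": 0.8,
    # fruits
    "banana": 2.5, "mango": 1.5, "avocado": 1.0, "papaya": 0.8,
    "orange": 0.8, "pineapple": 0.6,
    # livestock
    "cattle": 4.0, "goat": 4.0, "sheep": 2.5, "chicken": 6.0,
    "duck": 0.8, "pig": 1.5, "camel": 0.4, "fish_pond": 0.6,
    # non-food cash crops
    "cotton": 1.2, "coffee": 1.2, "tea": 0.6, "tobacco": 0.8,
    "sugarcane": 1.0,
}

#: baseline market-purchase probability per nutritious food group
DEFAULT_MARKET_PROBS: dict[str, float] = {
    "cereals": 0.92,
    "legumes_nuts_seeds": 0.55,
    "vegetables": 0.85,
    "roots_tubers": 0.45,
    "fruits": 0.35,
    "eggs": 0.25,
    "milk": 0.30,
    "fish": 0.45,
    "meat": 0.40,
}

#: market-purchase probability for the excluded (non-scored) groups
EXCLUDED_MARKET_PROBS: dict[str, float] = {
    "spices_condiments_beverages": 0.90,
    "sugar_sweets": 0.50,
    "oils_fats": 0.80,
}

DEFAULT_TRUE_DELTA: dict[str, float] = {
    "head_sex": 0.10,
    "head_age": 0.002,
    "head_literate": 0.30,
    "landholding": 0.01,
    "phone": 0.25,
    "motorbike": 0.10,
    "electricity": 0.20,
    "offfarm_wage": 0.20,
    "self_employment": 0.15,
    "cash_crop": 0.20,
    "weather_shock": -0.15,
    "distance_urban": -0.01,
}

_COVARIATE_MARGINALS: dict[str, float] = {
    "head_sex": 0.25,       # share of female-headed households
    "head_literate": 0.60,
    "phone": 0.50,
    "motorbike": 0.15,
    "electricity": 0.30,
    "offfarm_wage": 0.30,
    "self_employment": 0.25,
}

_TIME_VARYING_BINARY = ("phone", "motorbike", "electricity", "offfarm_wage", "self_employment")
_PERSISTENCE = 0.88  # per-wave probability a binary covariate keeps its state


@dataclass
class AttritionConfig:
    """Monotone dropout: from each wave after the first, a household drops
    out permanently with probability logistic in its baseline covariates
    (optionally in the latent household effect, for non-ignorable
    scenarios used in attrition-correction tests)."""

    base_rate: float = 0.06
    covariate_slopes: Mapping[str, float] = field(default_factory=dict)
    c_slope: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.base_rate <= 1.0:
            raise ValueError("attrition base_rate must be in [0, 1]")


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic panel; defaults are the calibrated
    study conditions (see module docstring)."""

    seed: int = 42
    n_countries: int = 6
    districts_per_country: int = 14
    towns_per_district: int = 10
    villages_per_town: int = 12
    households_per_village: int = 9
    waves_per_country: tuple[int, ...] = (3, 4, 2, 4, 5, 7)
    farming_share: float = 0.78
    landholding_mu: float = -0.2
    landholding_sigma: float = 1.0
    landholding_c_corr: float = 0.3
    distance_shape: float = 2.0
    distance_scale: float = 15.5   # gamma mean = shape * scale = 31 km
    sigma_c: float = 0.8
    kappa: float = 0.25
    species_mean: float = 5.55
    species_dispersion: float = 3.2   # negative-binomial size
    own_consumption_prob: float = 0.55
    market_logit_shift: float = 0.0
    market_wealth_slope: float = 0.50
    market_distance_slope: float = -0.35
    market_c_slope: float = 0.15
    other_source_prob: float = 0.071
    subsistence_share_target: float = 0.3314
    share_concentration: float = 2.5
    value_sigma: float = 0.6
    true_alpha: float = 4.0
    true_beta_species: float = 0.0
    true_beta_groups: float = 0.0
    true_beta_interaction: float = 0.0
    true_delta: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_DELTA)
    )
    sigma_eps: float = 1.2
    attrition: AttritionConfig = field(default_factory=AttritionConfig)
    outcome_mode: str = "structural"
    species_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_WEIGHTS)
    )
    market_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARKET_PROBS)
    )

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        rates = {
            "farming_share": self.farming_share,
            "own_consumption_prob": self.own_consumption_prob,
            "other_source_prob": self.other_source_prob,
            "subsistence_share_target": self.subsistence_share_target,
        }
        for name, v in rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name, v in (("sigma_c", self.sigma_c), ("sigma_eps", self.sigma_eps)):
            if v < 0:
                raise ValueError(f"{name} must be non-negative")
        waves = self._waves()
        if min(waves) < 2:
            raise ValueError("waves_per_country must be >= 2 for every country")
        if self.outcome_mode not in ("structural", "linear"):
            raise ValueError(f"unknown outcome_mode {self.outcome_mode!r}")
        self.attrition.validate()

    def _waves(self) -> tuple[int, ...]:
        w = self.waves_per_country
        if isinstance(w, int):
            w = (w,)
        reps = -(-self.n_countries // len(w))
        return (tuple(w) * reps)[: self.n_countries]

    def countries(self) -> tuple[str, ...]:
        codes = list(COUNTRY_CODES)
        while len(codes) < self.n_countries:
            codes.append(f"C{len(codes) + 1}")
        return tuple(codes[: self.n_countries])

    def rng(self, stream: str) -> np.random.Generator:
        key = _STREAMS[stream]
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(key,))
        )


def recovery_config(
    seed: int,
    true_beta_species: float = 0.0,
    true_beta_groups: float = 0.0,
    true_beta_interaction: float = 0.0,
    waves: int = 3,
) -> GeneratorConfig:
    """Linear-mode configuration for coefficient-recovery experiments:
    ~2,880 households (6 countries × 480), a common wave count, kappa>0
    confounding, no attrition."""
    return GeneratorConfig(
        seed=seed,
        districts_per_country=2,
        towns_per_district=2,
        villages_per_town=4,
        households_per_village=30,
        waves_per_country=(waves,),
        outcome_mode="linear",
        true_beta_species=true_beta_species,
        true_beta_groups=true_beta_groups,
        true_beta_interaction=true_beta_interaction,
        attrition=AttritionConfig(base_rate=0.0),
    )


# ----------------------------------------------------------------------
# Geography
# ----------------------------------------------------------------------


def generate_geography(config: GeneratorConfig) -> pd.DataFrame:
    """Strictly nested village table with gamma-distributed distance to
    the nearest urban centre (default mean 31 km)."""
    rng = config.rng("geography")
    rows = []
    for country in config.countries():
        for d in range(1, config.districts_per_country + 1):
            district = f"{country}-D{d:02d}"
            for t in range(1, config.towns_per_district + 1):
                town = f"{district}-T{t:02d}"
                for v in range(1, config.villages_per_town + 1):
                    rows.append((country, district, town, f"{town}-V{v:02d}"))
    geo = pd.DataFrame(rows, columns=["country", "district_id", "town_id", "village_id"])
    geo["distance_urban"] = rng.gamma(
        config.distance_shape, config.distance_scale, size=len(geo)
    ).round(2)
    return geo


# ----------------------------------------------------------------------
# Households
# ----------------------------------------------------------------------


def generate_households(
    config: GeneratorConfig, geography: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Household-wave observations (before attrition) plus the latent
    truth base (one row per household with its effect c_i).

    Covariates: binary assets/employment follow a sticky Markov chain
    across waves (persistence 0.88); weather shocks are i.i.d. per wave;
    head characteristics and landholding are fixed at baseline.
    Landholding is lognormal, correlated with c_i, and calibrated so that
    over 75% of farms fall below 2 ha at the defaults.
    """
    rng = config.rng("households")
    waves = dict(zip(config.countries(), config._waves()))

    hh_base = geography.loc[
        geography.index.repeat(config.households_per_village)
    ].reset_index(drop=True)
    n = len(hh_base)
    within = np.concatenate(
        [np.arange(1, config.households_per_village + 1)] * len(geography)
    )
    hh_base["household_id"] = hh_base["village_id"] + "-H" + pd.Series(within).astype(str).str.zfill(3)

    c_i = rng.normal(0.0, config.sigma_c, size=n)
    is_farmer = (rng.random(n) < config.farming_share).astype(int)

    z_c = c_i / config.sigma_c if config.sigma_c > 0 else np.zeros(n)
    rho = config.landholding_c_corr
    z_land = rho * z_c + np.sqrt(max(1 - rho**2, 0.0)) * rng.normal(size=n)
    land = np.exp(config.landholding_mu + config.landholding_sigma * z_land)
    hh_base["landholding"] = np.where(is_farmer == 1, land.round(3), 0.0)
    hh_base["is_farmer"] = is_farmer
    hh_base["head_sex"] = (rng.random(n) < _COVARIATE_MARGINALS["head_sex"]).astype(int)
    hh_base["head_age"] = np.clip(rng.normal(45, 15, size=n), 18, 95).round(0)
    hh_base["head_literate"] = (
        rng.random(n) < _COVARIATE_MARGINALS["head_literate"]
    ).astype(int)

    truth_base = hh_base[["household_id"]].copy()
    truth_base["c_i"] = c_i

    max_waves = max(waves.values())
    # sticky binary chains simulated over the maximum horizon
    chains: dict[str, np.ndarray] = {}
    for col in _TIME_VARYING_BINARY:
        p = _COVARIATE_MARGINALS[col]
        states = np.empty((n, max_waves), dtype=np.int8)
        states[:, 0] = rng.random(n) < p
        for t in range(1, max_waves):
            keep = rng.random(n) < _PERSISTENCE
            redraw = rng.random(n) < p
            states[:, t] = np.where(keep, states[:, t - 1], redraw)
        chains[col] = states
    shock = (rng.random((n, max_waves)) < 0.2).astype(np.int8)

    n_waves = hh_base["country"].map(waves).to_numpy()
    obs = hh_base.loc[hh_base.index.repeat(n_waves)].reset_index(drop=True)
    wave_idx = np.concatenate([np.arange(w) for w in n_waves])
    row_idx = np.repeat(np.arange(n), n_waves)
    obs["wave"] = wave_idx + 1
    for col in _TIME_VARYING_BINARY:
        obs[col] = chains[col][row_idx, wave_idx]
    obs["weather_shock"] = shock[row_idx, wave_idx]
    obs["cash_crop"] = 0  # filled from production
    return obs, truth_base


# ----------------------------------------------------------------------
# Production
# ----------------------------------------------------------------------


def generate_production(
    config: GeneratorConfig,
    households: pd.DataFrame,
    truth_base: pd.DataFrame,
    taxonomy: FoodTaxonomy | None = None,
) -> pd.DataFrame:
    """Species records per farm-wave.

    The species count is 1 + NegBin with mean ``species_mean - 1``; the
    household effect c_i shifts the log-mean by ``kappa * c_i`` (with a
    lognormal mean correction so the pooled mean stays on target) —
    this is the confounding channel the panel estimators must absorb.
    Species are drawn without replacement with prevalence weights
    (weighted Gumbel top-k).
    """
    taxonomy = taxonomy or default_taxonomy()
    rng = config.rng("production")
    farm = households[households["is_farmer"] == 1][["household_id", "wave"]].copy()
    if not len(farm):
        return pd.DataFrame(columns=["household_id", "wave", "species_code"])
    c_map = truth_base.set_index("household_id")["c_i"]
    c = farm["household_id"].map(c_map).to_numpy()

    base_mu = config.species_mean - 1.0
    mu = base_mu * np.exp(config.kappa * c - 0.5 * (config.kappa * config.sigma_c) ** 2)
    r = config.species_dispersion
    counts = 1 + rng.negative_binomial(r, r / (r + mu))

    codes = sorted(config.species_weights)
    unknown = set(codes) - set(taxonomy.species)
    if unknown:
        raise ValueError(f"species weights reference unknown species {sorted(unknown)}")
    w = np.array([config.species_weights[c] for c in codes], dtype=float)
    n_species = len(codes)
    counts = np.minimum(counts, n_species)

    # weighted sampling without replacement: Gumbel top-k per farm-wave
    keys = np.log(w)[None, :] + rng.gumbel(size=(len(farm), n_species))
    order = np.argsort(-keys, axis=1)
    total = counts.sum()
    row_of = np.repeat(np.arange(len(farm)), counts)
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    within = np.arange(total) - offsets[row_of]
    chosen = order[row_of, within]

    code_arr = np.array(codes)
    out = pd.DataFrame(
        {
            "household_id": farm["household_id"].to_numpy()[row_of],
            "wave": farm["wave"].to_numpy()[row_of],
            "species_code": code_arr[chosen],
        }
    )
    return out


def attach_cash_crop_flag(
    households: pd.DataFrame, production: pd.DataFrame, taxonomy: FoodTaxonomy
) -> pd.DataFrame:
    """Set the cash_crop covariate from the production records."""
    cash_codes = {c for c, sp in taxonomy.species.items() if sp.cash_crop}
    if not len(production):
        out = households.copy()
        out["cash_crop"] = 0
        return out
    flag = (
        production.assign(f=production["species_code"].isin(cash_codes).astype(int))
        .groupby(["household_id", "wave"], sort=False)["f"]
        .max()
        .rename("cash_crop_flag")
        .reset_index()
    )
    out = households.merge(flag, on=["household_id", "wave"], how="left")
    out["cash_crop"] = out["cash_crop_flag"].fillna(0).astype(int)
    return out.drop(columns=["cash_crop_flag"])


# ----------------------------------------------------------------------
# Consumption and outcomes
# ----------------------------------------------------------------------


def _produced_group_matrix(
    production: pd.DataFrame, taxonomy: FoodTaxonomy, keys: pd.DataFrame
) -> np.ndarray:
    """(n_obs × 9) indicator of nutritious food groups produced."""
    mat = np.zeros((len(keys), len(NUTRITIOUS_GROUPS)), dtype=bool)
    if not len(production):
        return mat
    key_index = pd.MultiIndex.from_frame(keys[["household_id", "wave"]])
    pg = production.merge(
        taxonomy.species_group_frame()[["species_code", "food_group"]],
        on="species_code",
        how="inner",
    )
    pg = pg[~pg["food_group"].isin(EXCLUDED_GROUPS)].drop_duplicates(
        ["household_id", "wave", "food_group"]
    )
    rows = key_index.get_indexer(pd.MultiIndex.from_frame(pg[["household_id", "wave"]]))
    gidx = {g: j for j, g in enumerate(NUTRITIOUS_GROUPS)}
    cols = pg["food_group"].map(gidx).to_numpy()
    ok = rows >= 0
    mat[rows[ok], cols[ok]] = True
    return mat


def generate_consumption(
    config: GeneratorConfig,
    households: pd.DataFrame,
    production: pd.DataFrame,
    truth_base: pd.DataFrame,
    taxonomy: FoodTaxonomy | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Consumption records and the household-wave truth table.

    Structural mechanism: a produced nutritious group is consumed from own
    production with probability ``own_consumption_prob``; market purchase
    of each group follows a logit in a wealth index, distance to town and
    (weakly) the household effect; "other" sources are rare and uniform.
    Monetary values are lognormal, with own-production values scaled so
    the pooled own-value share centres on ``subsistence_share_target``.

    In linear mode the truth table additionally carries the continuous
    latent diet index α + β_s·species + β_g·groups + β_int·groups·distance
    + δ'X + c_i + ε.
    """
    taxonomy = taxonomy or default_taxonomy()
    rng = config.rng("consumption")
    obs = households.reset_index(drop=True)
    n = len(obs)
    n_groups = len(NUTRITIOUS_GROUPS)

    produced = _produced_group_matrix(production, taxonomy, obs)

    # own-production consumption
    own = produced & (rng.random((n, n_groups)) < config.own_consumption_prob)

    # market purchases
    wealth = (
        obs["phone"].to_numpy() + obs["motorbike"].to_numpy() + obs["electricity"].to_numpy()
    ).astype(float)
    wealth_z = (wealth - 0.95) / 0.9  # approximate standardization at defaults
    dist_mean = config.distance_shape * config.distance_scale
    dist_sd = np.sqrt(config.distance_shape) * config.distance_scale
    dist_z = (obs["distance_urban"].to_numpy() - dist_mean) / dist_sd
    c = obs["household_id"].map(truth_base.set_index("household_id")["c_i"]).to_numpy()
    shift = (
        config.market_logit_shift
        + config.market_wealth_slope * wealth_z
        + config.market_distance_slope * dist_z
        + config.market_c_slope * c
    )
    base_logit = np.array(
        [np.log(p / (1 - p)) for p in (config.market_probs[g] for g in NUTRITIOUS_GROUPS)]
    )
    p_mkt = 1.0 / (1.0 + np.exp(-(base_logit[None, :] + shift[:, None])))
    market = rng.random((n, n_groups)) < p_mkt

    other = rng.random((n, n_groups)) < config.other_source_prob

    frames = []
    sigma_v = config.value_sigma
    group_items = {g: taxonomy.items_for_group(g) for g in taxonomy.groups}

    def emit(mask: np.ndarray, groups: tuple[str, ...], source: str) -> None:
        rows, cols = np.nonzero(mask)
        if not len(rows):
            return
        items = np.empty(len(rows), dtype=object)
        for j, g in enumerate(groups):
            sel = cols == j
            k = int(sel.sum())
            if k:
                choices = group_items[g]
                items[sel] = np.array(choices, dtype=object)[
                    rng.integers(0, len(choices), size=k)
                ]
        frames.append(
            pd.DataFrame(
                {
                    "household_id": obs["household_id"].to_numpy()[rows],
                    "wave": obs["wave"].to_numpy()[rows],
                    "item_code": items,
                    "source": source,
                    "value": np.exp(rng.normal(0.0, sigma_v, size=len(rows))).round(4),
                }
            )
        )

    emit(own, NUTRITIOUS_GROUPS, "own_production")
    emit(market, NUTRITIOUS_GROUPS, "purchase")
    emit(other, NUTRITIOUS_GROUPS, "other")
    # excluded groups arrive via purchase only; never scored but carry value
    excl = tuple(sorted(EXCLUDED_GROUPS))
    p_excl = np.array([EXCLUDED_MARKET_PROBS[g] for g in excl])
    excl_mask = rng.random((n, len(excl))) < p_excl[None, :]
    emit(excl_mask, excl, "purchase")

    cons = pd.concat(frames, ignore_index=True)
    # collapse duplicate (household, wave, item, source) rows (two groups can
    # share an item only within a group, so duplicates arise from item reuse)
    cons = (
        cons.groupby(["household_id", "wave", "item_code", "source"], sort=False)[
            "value"
        ]
        .sum()
        .reset_index()
    )

    # scale own values so the pooled own share centres on the target
    key = ["household_id", "wave"]
    totals = cons.pivot_table(
        index=key, columns="source", values="value", aggfunc="sum", fill_value=0.0
    )
    own_tot = totals.get("own_production", pd.Series(0.0, index=totals.index))
    nonown_tot = totals.sum(axis=1) - own_tot
    any_records = totals.sum(axis=1) > 0
    has_own = own_tot > 0
    f = float(has_own.sum()) / max(int(any_records.sum()), 1)
    m = float(np.clip(config.subsistence_share_target / max(f, 1e-9), 0.02, 0.95))
    nu = config.share_concentration
    s = rng.beta(m * nu, (1 - m) * nu, size=len(totals))
    scalable = has_own & (nonown_tot > 0)
    factor = pd.Series(1.0, index=totals.index)
    factor[scalable] = (
        s[scalable.to_numpy()] / (1 - s[scalable.to_numpy()])
    ) * nonown_tot[scalable] / own_tot[scalable]
    fmap = cons.set_index(key).index.map(factor)
    is_own = (cons["source"] == "own_production").to_numpy()
    cons.loc[is_own, "value"] = (
        cons.loc[is_own, "value"] * np.asarray(fmap, dtype=float)[is_own]
    ).round(6)

    # truth table -------------------------------------------------------
    truth = obs[["household_id", "wave"]].copy()
    truth["c_i"] = c
    sp_counts = (
        production.groupby(key, sort=False)["species_code"].nunique()
        if len(production)
        else pd.Series(dtype=int)
    )
    truth["fpd_species"] = (
        pd.MultiIndex.from_frame(truth[key]).map(sp_counts).fillna(0).astype(int)
        if len(sp_counts)
        else 0
    )
    truth["fpd_groups"] = produced.sum(axis=1).astype(int)
    if config.outcome_mode == "linear":
        lat_rng = config.rng("latent")
        xb = np.zeros(n)
        for col, delta in config.true_delta.items():
            xb += delta * obs[col].to_numpy(dtype=float)
        latent = (
            config.true_alpha
            + config.true_beta_species * truth["fpd_species"].to_numpy()
            + config.true_beta_groups * truth["fpd_groups"].to_numpy()
            + config.true_beta_interaction
            * truth["fpd_groups"].to_numpy()
            * obs["distance_urban"].to_numpy()
            + xb
            + c
            + lat_rng.normal(0.0, config.sigma_eps, size=n)
        )
        truth["latent_hdds"] = latent
    else:
        truth["latent_hdds"] = np.nan
    return cons, truth


# ----------------------------------------------------------------------
# Attrition
# ----------------------------------------------------------------------


def apply_attrition(
    config: GeneratorConfig,
    households: pd.DataFrame,
    truth_base: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop households permanently from a wave onward; returns the reduced
    observation table and the full retention-indicator table."""
    att = config.attrition
    rng = config.rng("attrition")
    first = households.sort_values(["household_id", "wave"]).drop_duplicates(
        "household_id"
    )
    ids = first["household_id"].to_numpy()
    n = len(ids)

    if att.base_rate <= 0:
        hazard_logit = np.full(n, -np.inf)
    elif att.base_rate >= 1:
        hazard_logit = np.full(n, np.inf)
    else:
        hazard_logit = np.full(n, np.log(att.base_rate / (1 - att.base_rate)))
    for col, slope in att.covariate_slopes.items():
        hazard_logit = hazard_logit + slope * first[col].to_numpy(dtype=float)
    if att.c_slope:
        c = first["household_id"].map(
            truth_base.set_index("household_id")["c_i"]
        ).to_numpy()
        hazard_logit = hazard_logit + att.c_slope * c
    with np.errstate(over="ignore"):
        hazard = 1.0 / (1.0 + np.exp(-hazard_logit))

    n_waves = first["country"].map(
        dict(zip(config.countries(), config._waves()))
    ).to_numpy()
    max_w = int(n_waves.max())
    u = rng.random((n, max_w))
    drop_from = np.full(n, np.iinfo(np.int32).max)
    for t in range(1, max_w):  # wave index t (0-based); wave 1 always observed
        newly = (u[:, t] < hazard) & (t < n_waves) & (drop_from > t)
        drop_from[newly] = t

    last_wave = np.minimum(drop_from, n_waves)  # retained waves: 1..last_wave
    keep_map = pd.Series(last_wave, index=ids)
    kept = households[
        households["wave"] <= households["household_id"].map(keep_map)
    ].reset_index(drop=True)

    # full retention table over each household's calendar
    rows = np.repeat(np.arange(n), n_waves)
    wv = np.concatenate([np.arange(1, w + 1) for w in n_waves])
    retention = pd.DataFrame(
        {
            "household_id": ids[rows],
            "wave": wv,
            "retained": (wv <= last_wave[rows]).astype(int),
        }
    )
    return kept, retention


# ----------------------------------------------------------------------
# Orchestration
# ----------------------------------------------------------------------


def generate_panel(
    config: GeneratorConfig, taxonomy: FoodTaxonomy | None = None
) -> tuple[PanelDataset, pd.DataFrame]:
    """Generate a complete synthetic panel plus its truth table."""
    taxonomy = taxonomy or default_taxonomy()
    geography = generate_geography(config)
    households, truth_base = generate_households(config, geography)
    households, retention = apply_attrition(config, households, truth_base)
    production = generate_production(config, households, truth_base, taxonomy)
    households = attach_cash_crop_flag(households, production, taxonomy)
    consumption, truth = generate_consumption(
        config, households, production, truth_base, taxonomy
    )
    calendar = {
        c: tuple(range(1, w + 1))
        for c, w in zip(config.countries(), config._waves())
    }
    panel = PanelDataset(
        households=households,
        consumption=consumption,
        production=production,
        taxonomy=taxonomy,
        wave_calendar=calendar,
        retention=retention,
    )
    return panel, truth
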