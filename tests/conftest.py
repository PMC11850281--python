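"""Shared fixtures: a hand-built 3-household panel and small generated panels."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from agridiet.data_model import PanelDataset
from agridiet.pipeline import X_COLUMNS
from agridiet.scores import score_panel
from agridiet.synthetic import AttritionConfig, GeneratorConfig, generate_panel
from agridiet.taxonomy import default_taxonomy

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def _hh_row(hid, village, wave=1, farmer=1, **kw):
    row = {
        "household_id": hid,
        "country": "ET",
        "district_id": "ET-D01",
        "town_id": "ET-D01-T01",
        "village_id": village,
        "wave": wave,
        "head_sex": 0,
        "head_age": 40.0,
        "head_literate": 1,
        "landholding": 1.0 if farmer else 0.0,
        "phone": 1,
        "motorbike": 0,
        "electricity": 0,
        "offfarm_wage": 0,
        "self_employment": 0,
        "cash_crop": 0,
        "weather_shock": 0,
        "is_farmer": farmer,
        "distance_urban": 25.0,
    }
    row.update(kw)
    return row


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture()
def tiny_panel(taxonomy):
    """Three households, one wave, seven consumption rows.

    H1: farmer (maize, beans, cotton), subsistence share 0.6.
    H2: farmer (cattle, goat), share exactly 0.5 (boundary case).
    H3: non-farmer, purchases only.
    """
    households = pd.DataFrame(
        [
            _hh_row("H1", "ET-D01-T01-V01", cash_crop=1),
            _hh_row("H2", "ET-D01-T01-V01"),
            _hh_row("H3", "ET-D01-T01-V02", farmer=0),
        ]
    )
    consumption = pd.DataFrame(
        [
            ("H1", 1, "maize_flour", "purchase", 30.0),
            ("H1", 1, "beans_dry", "own_production", 60.0),
            ("H1", 1, "sugar", "purchase", 10.0),
            ("H2", 1, "milk_fresh", "own_production", 50.0),
            ("H2", 1, "beef", "purchase", 50.0),
            ("H3", 1, "bread", "purchase", 20.0),
            ("H3", 1, "tomato_fresh", "purchase", 5.0),
        ],
        columns=["household_id", "wave", "item_code", "source", "value"],
    )
    production = pd.DataFrame(
        [
            ("H1", 1, "maize"),
            ("H1", 1, "beans"),
            ("H1", 1, "cotton"),
            ("H2", 1, "cattle"),
            ("H2", 1, "goat"),
        ],
        columns=["household_id", "wave", "species_code"],
    )
    return PanelDataset(
        households=households,
        consumption=consumption,
        production=production,
        taxonomy=taxonomy,
    )


@pytest.fixture(scope="session")
def small_panel():
    """Small structural panel: 6 countries x 108 households, 2-7 waves."""
    cfg = GeneratorConfig(
        seed=3,
        districts_per_country=2,
        towns_per_district=2,
        villages_per_town=3,
        households_per_village=9,
    )
    return generate_panel(cfg)


@pytest.fixture(scope="session")
def small_scores(small_panel):
    panel, _ = small_panel
    return score_panel(panel)


def make_linear_frame(seed, **config_kw):
    """Generated linear-mode panel merged into one model frame."""
    from agridiet.synthetic import recovery_config

    cfg = recovery_config(seed, **config_kw)
    panel, truth = generate_panel(cfg)
    scores = score_panel(panel)
    df = panel.households.merge(
        scores, on=["household_id", "wave"], suffixes=("_hh", "")
    ).merge(truth[["household_id", "wave", "latent_hdds"]], on=["household_id", "wave"])
    return panel, df


@pytest.fixture(scope="session")
def linear_frame():
    """One linear-mode frame with known true species coefficient 0.044."""
    return make_linear_frame(101, true_beta_species=0.044)[1]
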