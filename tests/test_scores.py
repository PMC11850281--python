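import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from agridiet.scores import (
    ScoreError,
    compute_fpd,
    compute_hdds,
    compute_subsistence,
    score_panel,
)
from agridiet.taxonomy import EXCLUDED_GROUPS, NUTRITIOUS_GROUPS, default_taxonomy

TAX = default_taxonomy()
ITEMS = sorted(TAX.items)
SPECIES = sorted(TAX.species)
SOURCES = ("own_production", "purchase", "other")


# ----------------------------------------------------------------------
# compute_hdds
# ----------------------------------------------------------------------


def test_hdds_excludes_low_nutrient_groups():
    records = [("maize_flour", "purchase"), ("beans_dry", "own_production"), ("sugar", "purchase")]
    r = compute_hdds(records, TAX)
    assert (r.hdds, r.hdds_own, r.hdds_market, r.hdds_other) == (2, 1, 1, 0)


def test_hdds_empty():
    assert compute_hdds([], TAX) == (0, 0, 0, 0)


def test_hdds_unresolvable_item_names_code():
    with pytest.raises(ScoreError, match="mystery_meat"):
        compute_hdds([("mystery_meat", "purchase")], TAX)


def _brute_force_hdds(records):
    """Independent set-union oracle over the raw records."""
    nutritious = set(NUTRITIOUS_GROUPS)
    total = {TAX.items[i] for i, _ in records if TAX.items[i] in nutritious}
    per_source = {
        s: {TAX.items[i] for i, src in records if src == s and TAX.items[i] in nutritious}
        for s in SOURCES
    }
    return (
        len(total),
        len(per_source["own_production"]),
        len(per_source["purchase"]),
        len(per_source["other"]),
    )


def test_hdds_matches_set_union_oracle_on_random_fixture():
    rng = np.random.default_rng(0)
    records = [
        (ITEMS[rng.integers(len(ITEMS))], SOURCES[rng.integers(3)]) for _ in range(60)
    ]
    assert tuple(compute_hdds(records, TAX)) == _brute_force_hdds(records)


@given(
    st.lists(
        st.tuples(st.sampled_from(ITEMS), st.sampled_from(SOURCES)), max_size=40
    )
)
def test_hdds_invariant_to_duplication_and_order(records):
    base = compute_hdds(records, TAX)
    doubled = compute_hdds(records + records[::-1], TAX)
    assert base == doubled
    # source components bound the total: max component <= hdds <= sum
    assert max(base.hdds_own, base.hdds_market, base.hdds_other) <= base.hdds
    assert base.hdds <= base.hdds_own + base.hdds_market + base.hdds_other


@given(
    st.lists(st.tuples(st.sampled_from(ITEMS), st.sampled_from(SOURCES)), max_size=20),
    st.sampled_from([i for i in ITEMS if TAX.items[i] not in EXCLUDED_GROUPS]),
)
def test_hdds_monotone_under_new_record(records, new_item):
    before = compute_hdds(records, TAX)
    after = compute_hdds(records + [(new_item, "purchase")], TAX)
    assert after.hdds >= before.hdds


# ----------------------------------------------------------------------
# compute_fpd
# ----------------------------------------------------------------------


def test_fpd_counts_cash_crops_as_species_not_groups():
    r = compute_fpd(["maize", "sorghum", "cattle", "cotton"], TAX)
    # cattle -> {meat, milk}; maize+sorghum -> cereals; cotton -> nothing
    assert r.fpd_species == 4
    assert r.fpd_groups == 3
    assert r.crop_groups == 1
    assert r.livestock_groups == 2
    assert r.cash_crop == 1


def test_fpd_empty_is_all_zero():
    assert tuple(compute_fpd([], TAX)) == (0, 0, 0, 0, 0)


def test_fpd_matches_union_oracle_on_random_species():
    rng = np.random.default_rng(1)
    for _ in range(20):
        codes = list(rng.choice(SPECIES, size=12, replace=False))
        r = compute_fpd(codes, TAX)
        groups = set().union(*(TAX.species[c].groups for c in codes)) - EXCLUDED_GROUPS
        assert r.fpd_species == len(set(codes))
        assert r.fpd_groups == len(groups)


def test_fpd_groups_vs_species_regimes():
    # single-group crops: groups <= species
    r = compute_fpd(["maize", "sorghum", "beans"], TAX)
    assert r.fpd_groups <= r.fpd_species
    # one multi-group livestock species: groups can exceed species
    r = compute_fpd(["cattle"], TAX)
    assert r.fpd_groups == 2 > r.fpd_species == 1


# ----------------------------------------------------------------------
# compute_subsistence
# ----------------------------------------------------------------------


def test_subsistence_share_and_flag():
    share, flag = compute_subsistence([("own_production", 60.0), ("purchase", 40.0)])
    assert share == pytest.approx(0.6)
    assert flag == 1


def test_subsistence_boundary_is_strict():
    share, flag = compute_subsistence([("own_production", 50.0), ("purchase", 50.0)])
    assert share == pytest.approx(0.5)
    assert flag == 0  # strictly "more than 50%"


def test_subsistence_zero_total_raises():
    with pytest.raises(ScoreError, match="zero total"):
        compute_subsistence([("purchase", 0.0)])


def test_subsistence_matches_plain_ratio_on_fixture():
    rng = np.random.default_rng(2)
    for _ in range(20):
        recs = [(SOURCES[rng.integers(3)], float(rng.gamma(2, 10))) for _ in range(8)]
        share, _ = compute_subsistence(recs)
        own = sum(v for s, v in recs if s == "own_production")
        assert share == pytest.approx(own / sum(v for _, v in recs))


# ----------------------------------------------------------------------
# score_panel
# ----------------------------------------------------------------------


def test_score_panel_tiny_fixture_golden(tiny_panel):
    sc = score_panel(tiny_panel).set_index("household_id")
    assert sc.loc["H1", ["hdds", "hdds_own", "hdds_market"]].tolist() == [2, 1, 1]
    assert sc.loc["H1", "fpd_species"] == 3
    assert sc.loc["H1", "fpd_groups"] == 2
    assert sc.loc["H1", "cash_crop"] == 1
    assert sc.loc["H1", "own_value_share"] == pytest.approx(0.6)
    assert sc.loc["H1", "subsistence"] == 1
    assert sc.loc["H2", "subsistence"] == 0  # boundary: exactly 0.5
    assert sc.loc["H2", "livestock_groups"] == 2
    # non-farmer: production metrics zero, consumption unaffected
    assert sc.loc["H3", ["fpd_species", "fpd_groups", "cash_crop"]].tolist() == [0, 0, 0]
    assert sc.loc["H3", "hdds"] == 2


def test_score_panel_matches_per_record_functions(small_panel):
    """Vectorized scorer equals the scalar reference implementations."""
    panel, _ = small_panel
    sc = score_panel(panel).set_index(["household_id", "wave"])
    cons = panel.consumption.groupby(["household_id", "wave"])
    prod = panel.production.groupby(["household_id", "wave"])
    rng = np.random.default_rng(3)
    keys = sc.index.to_list()
    for key in [keys[i] for i in rng.choice(len(keys), size=50, replace=False)]:
        try:
            crecs = cons.get_group(key)
        except KeyError:
            crecs = None
        expected = (
            compute_hdds(zip(crecs.item_code, crecs.source), TAX)
            if crecs is not None
            else (0, 0, 0, 0)
        )
        got = tuple(sc.loc[key, ["hdds", "hdds_own", "hdds_market", "hdds_other"]])
        assert got == tuple(expected)
        try:
            precs = prod.get_group(key)
            exp_fpd = compute_fpd(precs.species_code, TAX)
        except KeyError:
            exp_fpd = (0, 0, 0, 0, 0)
        got_fpd = tuple(
            sc.loc[
                key,
                ["fpd_species", "fpd_groups", "crop_groups", "livestock_groups", "cash_crop"],
            ]
        )
        assert got_fpd == tuple(exp_fpd)
        if crecs is not None and crecs.value.sum() > 0:
            share, _ = compute_subsistence(zip(crecs.source, crecs.value))
            assert sc.loc[key, "own_value_share"] == pytest.approx(share)


def test_score_panel_invariants_hold(small_scores):
    sc = small_scores
    comp_max = sc[["hdds_own", "hdds_market", "hdds_other"]].max(axis=1)
    comp_sum = sc[["hdds_own", "hdds_market", "hdds_other"]].sum(axis=1)
    assert (comp_max <= sc.hdds).all()
    assert (sc.hdds <= comp_sum).all()
    assert sc.hdds.between(0, 9).all()
    assert sc.fpd_groups.between(0, 9).all()
    defined = sc.own_value_share.dropna()
    assert defined.between(0, 1).all()
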