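"""Defined-daily-dose arithmetic and aggregation."""

import math
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pigamu as pg
from pigamu.quantification import QuantificationError, record_ndddch

AC = pg.AgeCategory


def rec(farm, product, qty, cat, year=2017):
    return pg.UsageRecord(farm, product, qty, cat, year)


@pytest.mark.parametrize(
    "amount, dose, weight, expected",
    [
        (8000, 20, 12, 8000 / 240),  # 33.333... weaner-weight example
        (2200, 10, 220, 1.0),
        (0, 5, 50, 0.0),
    ],
)
def test_record_ndddch_hand_values(amount, dose, weight, expected):
    assert record_ndddch(amount, dose, weight) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("dose, weight", [(0, 12), (-1, 12), (20, 0), (20, -5)])
def test_record_ndddch_domain_errors(dose, weight):
    with pytest.raises(ValueError):
        record_ndddch(100, dose, weight)


def test_quantify_single_record(formulary):
    # 80 ml of 100 mg/ml amoxicillin to weaners: 8000 mg, dose 20, weight 12
    amu = pg.quantify([rec("f1", "amoxi_inject", 80, AC.WEANER)], formulary)
    assert len(amu.by_class) == 1
    row = amu.by_class.iloc[0]
    assert row["mass_mg"] == pytest.approx(8000)
    assert row["ndddch"] == pytest.approx(8000 / 240, rel=1e-12)
    assert row["antimicrobial_class"] == "penicillins"


def test_quantify_order_independent(formulary):
    records = [
        rec("f1", "amoxi_inject", 80, AC.WEANER),
        rec("f1", "sulfatrim_premix", 10, AC.WEANER),
        rec("f2", "tula_inject", 5, AC.SOW),
        rec("f1", "amoxi_inject", 20, AC.PIGLET),
    ]
    shuffled = records[:]
    random.Random(0).shuffle(shuffled)
    a = pg.quantify(records, formulary).by_class
    b = pg.quantify(shuffled, formulary).by_class
    pd.testing.assert_frame_equal(a, b)


def test_quantify_empty_records(formulary):
    amu = pg.quantify([], formulary)
    assert amu.total_ndddch() == 0
    assert amu.total_mass_mg() == 0


def test_quantify_matches_brute_force_oracle(formulary):
    """<=5 records vs a one-record-at-a-time hand computation."""
    records = [
        rec("f1", "amoxi_inject", 12.5, AC.PIGLET),
        rec("f1", "sulfatrim_premix", 3.2, AC.WEANER),
        rec("f1", "sulfatrim_premix", 1.8, AC.WEANER),
        rec("f2", "colistin_oral", 7.0, AC.PIGLET),
        rec("f2", "ceftiofur_inject", 0.4, AC.SOW),
    ]
    expected: dict[tuple, list[float]] = {}
    for r in records:
        weight = formulary.standard_weight(r.age_category)
        for comp in formulary.products[r.product_id].components:
            amount = comp.concentration_mg_per_unit * r.quantity
            dose = formulary.lookup_dddch(comp.ingredient, comp.route)
            cls = formulary.class_of(comp.ingredient, comp.route)
            key = (r.farm_id, r.age_category.value, cls)
            expected.setdefault(key, [0.0, 0.0])
            expected[key][0] += amount
            expected[key][1] += amount / (dose * weight)
    amu = pg.quantify(records, formulary)
    got = amu.by_class.set_index(["farm_id", "age_category", "antimicrobial_class"])
    assert len(got) == len(expected)
    for key, (mass, nd) in expected.items():
        assert got.loc[key, "mass_mg"] == pytest.approx(mass, rel=1e-12)
        assert got.loc[key, "ndddch"] == pytest.approx(nd, rel=1e-12)


@settings(max_examples=30, deadline=None)
@given(scale=st.floats(min_value=0.1, max_value=100, allow_nan=False))
def test_quantify_scale_equivariance(formulary, scale):
    records = [
        rec("f1", "amoxi_inject", 10, AC.PIGLET),
        rec("f1", "sulfatrim_premix", 4, AC.WEANER),
    ]
    scaled = [rec(r.farm_id, r.product_id, r.quantity * scale, r.age_category) for r in records]
    a = pg.quantify(records, formulary).by_class
    b = pg.quantify(scaled, formulary).by_class
    np.testing.assert_allclose(b["mass_mg"], a["mass_mg"] * scale, rtol=1e-12)
    np.testing.assert_allclose(b["ndddch"], a["ndddch"] * scale, rtol=1e-12)


def test_quantify_conservation(small_cohort):
    """Class sums -> category sums -> farm totals -> population total."""
    _, amu = small_cohort
    per_cat = amu.by_class.groupby(["farm_id", "age_category"])["ndddch"].sum()
    per_farm = per_cat.groupby("farm_id").sum()
    assert per_farm.sum() == pytest.approx(amu.total_ndddch(), rel=1e-9)
    totals = amu.farm_totals.set_index("farm_id")["total_ndddch"]
    pd.testing.assert_series_equal(
        per_farm.sort_index(), totals.sort_index(), check_names=False, rtol=1e-9
    )


def test_quantify_unknown_product_raises_or_reports(formulary):
    bad = [rec("f1", "mystery", 5, AC.SOW)]
    with pytest.raises(QuantificationError, match="farm f1"):
        pg.quantify(bad, formulary)
    amu = pg.quantify(bad, formulary, on_error="report")
    assert len(amu.excluded) == 1 and amu.excluded[0][0].product_id == "mystery"


def test_quantify_year_filter(formulary):
    records = [
        rec("f1", "amoxi_inject", 10, AC.PIGLET, year=2017),
        rec("f1", "amoxi_inject", 99, AC.PIGLET, year=2016),
    ]
    amu = pg.quantify(records, formulary, year=2017)
    assert amu.n_year_filtered == 1
    assert amu.total_mass_mg() == pytest.approx(1000)


def census(farm, piglet=0, weaner=0, fattener=0, sow=0):
    return pg.FarmCensus(farm, {
        AC.PIGLET: piglet, AC.WEANER: weaner, AC.FATTENER: fattener, AC.SOW: sow,
    })


def test_per_animal_year_hand_division(formulary):
    # 1000 nDDDch in weaners over 2000 produced weaners -> 0.5 per animal
    # 1000 nDDDch = 240,000 mg amoxicillin (dose 20 x weight 12) = 2400 ml
    amu = pg.quantify([rec("f1", "amoxi_inject", 2400, AC.WEANER)], formulary)
    pg.per_animal_year(amu, [census("f1", piglet=10, weaner=2000, fattener=10, sow=10)])
    per = amu.per_animal.set_index("age_category")
    assert per.loc["weaner", "ndddch_per_animal_year"] == pytest.approx(0.5, rel=1e-12)
    assert per.loc["piglet", "ndddch_per_animal_year"] == 0.0  # zero usage, positive count


def test_per_animal_farm_total_is_sum_of_categories():
    # per-animal category values 0.5 / 0.7 / 0.04 / 2.1 sum to 3.34
    values = {"piglet": 0.5, "weaner": 0.7, "fattener": 0.04, "sow": 2.1}
    assert math.fsum(values.values()) == pytest.approx(3.34, rel=1e-12)


def test_per_animal_zero_count_with_usage_is_missing(formulary):
    amu = pg.quantify([rec("f1", "amoxi_inject", 10, AC.FATTENER)], formulary)
    pg.per_animal_year(amu, [census("f1", piglet=1, weaner=1, fattener=0, sow=1)])
    per = amu.per_animal.set_index("age_category")
    assert np.isnan(per.loc["fattener", "ndddch_per_animal_year"])
    # the undefined category propagates to the farm total
    assert np.isnan(amu.farm_totals["total_ndddch_per_animal_year"].iloc[0])


def test_per_animal_missing_census_raises(formulary):
    amu = pg.quantify([rec("f1", "amoxi_inject", 1, AC.SOW)], formulary)
    with pytest.raises(ValueError, match="f1"):
        pg.per_animal_year(amu, [census("f2", sow=10)])


def test_zero_usage_farms_stay_in_denominators(formulary):
    amu = pg.quantify([rec("f1", "amoxi_inject", 10, AC.SOW)], formulary)
    pg.per_animal_year(
        amu, [census("f1", 1, 1, 1, 10), census("f2", 100, 100, 100, 10)]
    )
    assert set(amu.farm_totals["farm_id"]) == {"f1", "f2"}
    f2 = amu.farm_totals.set_index("farm_id").loc["f2"]
    assert f2["total_ndddch_per_animal_year"] == 0.0
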