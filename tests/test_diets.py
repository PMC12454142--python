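"""Diet engine: calorie conservation, group allocation, scenario footprints."""

import numpy as np
import pandas as pd
import pytest

import lifecost as lc
from lifecost import (DietSpec, ImpactValue, baseline_spec, build_diet,
                      compare_diets, diet_footprint, reference_diets)
from lifecost.diets import REFERENCE_DIET_FRACTIONS, DietError

ENERGY = pd.Series({"grain": 3400.0, "veg": 400.0, "legume": 3300.0,
                    "beef": 2500.0, "dairy": 640.0, "pork": 2000.0,
                    "sugar": 3870.0, "coffee": 900.0})
GROUPS = pd.Series({"grain": "grains_roots", "veg": "fruit_veg",
                    "legume": "legumes_nuts", "beef": "ruminant_meat",
                    "dairy": "dairy_eggs", "pork": "poultry_pig",
                    "sugar": "sugar_other", "coffee": "sugar_other"})
BASELINE_KG = pd.Series({"grain": 0.35, "veg": 0.40, "legume": 0.05,
                         "beef": 0.06, "dairy": 0.55, "pork": 0.18,
                         "sugar": 0.18, "coffee": 0.02})
HELD = frozenset({"coffee"})


def _total_kcal(intake: pd.Series) -> float:
    return float((intake * ENERGY).sum())


def test_reference_diet_fractions_sum_to_one():
    for name, fracs in REFERENCE_DIET_FRACTIONS.items():
        assert sum(fracs.values()) == pytest.approx(1.0, abs=1e-12), name


def test_all_reference_diets_conserve_calories():
    base_total = _total_kcal(BASELINE_KG)
    for spec in reference_diets(total_energy=base_total, held_constant=HELD):
        intake = build_diet(spec, BASELINE_KG, ENERGY, GROUPS)
        assert _total_kcal(intake) == pytest.approx(base_total, rel=1e-9)


def test_identity_spec_reproduces_baseline():
    spec = baseline_spec("id", BASELINE_KG, ENERGY, GROUPS, HELD)
    intake = build_diet(spec, BASELINE_KG, ENERGY, GROUPS)
    np.testing.assert_allclose(intake.reindex(BASELINE_KG.index), BASELINE_KG,
                               rtol=1e-9)


def test_vegan_spec_zeroes_animal_groups():
    spec = DietSpec("vegan", REFERENCE_DIET_FRACTIONS["plant_based_eatwell"],
                    total_energy=3000.0, held_constant=HELD)
    intake = build_diet(spec, BASELINE_KG, ENERGY, GROUPS)
    assert intake["beef"] == 0.0
    assert intake["dairy"] == 0.0
    assert intake["pork"] == 0.0
    assert intake["coffee"] == BASELINE_KG["coffee"]  # held constant


def test_within_group_allocation_follows_baseline_ratios():
    """Two grains with baseline kcal 2:1 receive scenario kcal 2:1."""
    energy = pd.Series({"wheat": 3400.0, "rice": 3400.0})
    groups = pd.Series({"wheat": "grains_roots", "rice": "grains_roots"})
    base = pd.Series({"wheat": 0.2, "rice": 0.1})
    fracs = {g: 0.0 for g in lc.FOOD_GROUPS}
    fracs["grains_roots"] = 1.0
    intake = build_diet(DietSpec("all-grain", fracs, 3000.0), base, energy, groups)
    assert intake["wheat"] / intake["rice"] == pytest.approx(2.0, rel=1e-9)


def test_held_constant_commodities_identical_across_diets():
    base_total = _total_kcal(BASELINE_KG)
    intakes = [build_diet(s, BASELINE_KG, ENERGY, GROUPS)
               for s in reference_diets(base_total, HELD)]
    for intake in intakes:
        assert intake["coffee"] == BASELINE_KG["coffee"]


def test_positive_fraction_with_empty_group_errors():
    energy = pd.Series({"wheat": 3400.0})
    groups = pd.Series({"wheat": "grains_roots"})
    base = pd.Series({"wheat": 0.3})
    fracs = {g: 0.0 for g in lc.FOOD_GROUPS}
    fracs["ruminant_meat"] = 0.5
    fracs["grains_roots"] = 0.5
    with pytest.raises(DietError, match="ruminant_meat"):
        build_diet(DietSpec("bad", fracs, 2000.0), base, energy, groups)


def test_bad_specs_rejected():
    with pytest.raises(DietError):
        DietSpec("s", {"grains_roots": 0.7})  # does not sum to 1
    with pytest.raises(DietError):
        DietSpec("s", {"grains_roots": 1.2, "fruit_veg": -0.2})
    with pytest.raises(DietError):
        DietSpec("s", {"grains_roots": 1.0}, total_energy=0.0)


IMPACTS = {
    "grain": ImpactValue(3e-11, "grain", "C00", basis="consumption"),
    "veg": ImpactValue(2e-11, "veg", "C00", basis="consumption"),
    "legume": ImpactValue(4e-11, "legume", "C00", basis="consumption"),
    "beef": ImpactValue(1e-8, "beef", "C00", basis="consumption"),
    "dairy": ImpactValue(1e-10, "dairy", "C00", basis="consumption"),
    "pork": ImpactValue(3e-10, "pork", "C00", basis="consumption"),
    "sugar": ImpactValue(1e-11, "sugar", "C00", basis="consumption"),
    "coffee": ImpactValue(9e-10, "coffee", "C00", basis="consumption"),
}


def test_footprint_arithmetic_and_sugar_omission():
    intake = pd.Series({"grain": 0.5, "sugar": 0.3})
    total, by_group = diet_footprint(intake, IMPACTS, GROUPS,
                                     sugar_commodities={"sugar"})
    assert total == pytest.approx(0.5 * 3e-11, rel=1e-12)
    assert by_group.get("sugar_other", 0.0) == 0.0
    zero_total, _ = diet_footprint(
        intake, {k: ImpactValue(0.0, k, "C00") for k in intake.index}, GROUPS)
    assert zero_total == 0.0


def test_sugar_gets_calories_but_no_impact():
    base_total = _total_kcal(BASELINE_KG)
    spec = DietSpec("b", REFERENCE_DIET_FRACTIONS["baseline"], base_total, HELD)
    intake = build_diet(spec, BASELINE_KG, ENERGY, GROUPS)
    assert intake["sugar"] > 0
    total, by_group = diet_footprint(intake, IMPACTS, GROUPS,
                                     sugar_commodities={"sugar"})
    # only coffee (held constant, non-sugar) contributes to sugar_other here
    assert by_group["sugar_other"] == pytest.approx(
        intake["coffee"] * IMPACTS["coffee"].value, rel=1e-12)
    assert total > 0


def test_energy_shift_from_worst_to_best_group_lowers_footprint():
    """Moving 1% of energy from the highest to the lowest impact-per-kcal group helps."""
    base_total = _total_kcal(BASELINE_KG)
    fracs = dict(REFERENCE_DIET_FRACTIONS["baseline"])
    shifted = dict(fracs)
    shifted["ruminant_meat"] -= 0.01  # max dE per kcal under IMPACTS
    shifted["grains_roots"] += 0.01  # min dE per kcal among impact-bearing groups
    t0, _ = diet_footprint(
        build_diet(DietSpec("a", fracs, base_total, HELD), BASELINE_KG, ENERGY, GROUPS),
        IMPACTS, GROUPS, {"sugar"})
    t1, _ = diet_footprint(
        build_diet(DietSpec("b", shifted, base_total, HELD), BASELINE_KG, ENERGY, GROUPS),
        IMPACTS, GROUPS, {"sugar"})
    assert t1 < t0


def test_compare_diets_ordering_under_dominant_ruminant_impact():
    """baseline > planetary-health > vegetarian >= vegan when ruminants dominate."""
    base_total = _total_kcal(BASELINE_KG)
    specs = [baseline_spec("baseline_observed", BASELINE_KG, ENERGY, GROUPS, HELD)]
    specs += reference_diets(total_energy=specs[0].total_energy, held_constant=HELD)
    table = compare_diets(specs, BASELINE_KG, ENERGY, GROUPS, IMPACTS, {"sugar"})
    by = table.set_index("diet")["de_per_day"]
    assert by["baseline"] > by["eat_lancet"] > by["vegetarian_eatwell"]
    assert by["vegetarian_eatwell"] >= by["plant_based_eatwell"]
    assert table.set_index("diet")["ratio_to_baseline"]["baseline_observed"] == 1.0


def test_footprint_ratio_invariant_under_layer_rescaling():
    """Scaling every impact by k leaves diet ratios unchanged."""
    base_total = _total_kcal(BASELINE_KG)
    specs = [baseline_spec("base", BASELINE_KG, ENERGY, GROUPS, HELD)]
    specs += reference_diets(specs[0].total_energy, HELD)
    t1 = compare_diets(specs, BASELINE_KG, ENERGY, GROUPS, IMPACTS, {"sugar"})
    scaled = {k: ImpactValue(v.value * 8.0, k, "C00") for k, v in IMPACTS.items()}
    t2 = compare_diets(specs, BASELINE_KG, ENERGY, GROUPS, scaled, {"sugar"})
    np.testing.assert_allclose(t1["ratio_to_baseline"], t2["ratio_to_baseline"],
                               rtol=1e-12)
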