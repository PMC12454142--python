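"""Calorie-conserving diet scenarios and their footprints.

A diet scenario assigns fractions of total daily energy to food groups (fruit
and vegetables; legumes, beans and nuts; grains, roots and starchy
carbohydrates; dairy and eggs; ruminant meat; poultry and pig meat; sugar and
other). Scenario intakes keep each group's constituent commodities in the
ratios the baseline diet consumes them, and every scenario carries exactly
the baseline's total calories, so comparisons isolate composition, not
quantity. Stimulants and spices contribute almost nothing calorically and are
held constant across scenarios: their baseline calories are subtracted from
the allocatable budget before the group fractions are applied. Sugar receives
calories but contributes zero impact (its supply chain cannot be traced
reliably).

The shipped reference scenarios are a Western-style baseline
(3,911 kcal/day), an EAT–Lancet-style planetary-health pattern, and
vegetarian and plant-based ("Eatwell") patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .spatial import ImpactValue
from .tables import FOOD_GROUPS

BASELINE_DAILY_KCAL = 3911.0


class DietError(ValueError):
    """A diet spec cannot be realised against the baseline consumption."""


@dataclass
class DietSpec:
    """Food-group energy fractions plus total daily energy.

    ``group_fractions`` maps food group → fraction of (allocatable) energy;
    fractions must be non-negative and sum to 1. ``held_constant`` commodities
    (stimulants, spices) are excluded from group allocation and keep their
    baseline intake.
    """

    name: str
    group_fractions: dict[str, float]
    total_energy: float = BASELINE_DAILY_KCAL  # kcal/person/day
    held_constant: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        for g, f in self.group_fractions.items():
            if g not in FOOD_GROUPS:
                raise DietError(f"diet {self.name!r}: unknown food group {g!r}")
            if f < 0:
                raise DietError(f"diet {self.name!r}: negative fraction for {g!r}")
        s = sum(self.group_fractions.values())
        if abs(s - 1.0) > 1e-9:
            raise DietError(f"diet {self.name!r}: group fractions sum to {s}, not 1")
        if self.total_energy <= 0:
            raise DietError(f"diet {self.name!r}: total energy must be > 0")


# group-fraction rows of the shipped reference scenarios (percent of calories):
# fruit&veg / legumes&nuts / grains&roots / dairy&eggs / ruminant / poultry&pig / sugar&other
REFERENCE_DIET_FRACTIONS: dict[str, dict[str, float]] = {
    "baseline": {
        "fruit_veg": 0.06, "legumes_nuts": 0.12, "grains_roots": 0.35,
        "dairy_eggs": 0.13, "ruminant_meat": 0.04, "poultry_pig": 0.10,
        "sugar_other": 0.20,
    },
    "eat_lancet": {
        "fruit_veg": 0.12, "legumes_nuts": 0.23, "grains_roots": 0.43,
        "dairy_eggs": 0.08, "ruminant_meat": 0.01, "poultry_pig": 0.05,
        "sugar_other": 0.08,
    },
    "vegetarian_eatwell": {
        "fruit_veg": 0.40, "legumes_nuts": 0.10, "grains_roots": 0.35,
        "dairy_eggs": 0.15, "ruminant_meat": 0.0, "poultry_pig": 0.0,
        "sugar_other": 0.0,
    },
    "plant_based_eatwell": {
        "fruit_veg": 0.40, "legumes_nuts": 0.25, "grains_roots": 0.35,
        "dairy_eggs": 0.0, "ruminant_meat": 0.0, "poultry_pig": 0.0,
        "sugar_other": 0.0,
    },
}


def reference_diets(
    total_energy: float = BASELINE_DAILY_KCAL, held_constant: frozenset[str] = frozenset()
) -> list[DietSpec]:
    """The four shipped scenarios at a common total energy."""
    return [
        DietSpec(name=name, group_fractions=dict(fracs), total_energy=total_energy,
                 held_constant=held_constant)
        for name, fracs in REFERENCE_DIET_FRACTIONS.items()
    ]


def baseline_spec(
    name: str,
    baseline_kg_per_day: pd.Series,
    energy_density: pd.Series,
    group_map: pd.Series,
    held_constant: frozenset[str] = frozenset(),
) -> DietSpec:
    """Express a baseline consumption basket as a DietSpec (identity spec).

    Fractions are computed over the allocatable budget (total minus
    held-constant calories), so building this spec reproduces the baseline.
    """
    kcal = baseline_kg_per_day * energy_density.reindex(baseline_kg_per_day.index)
    total = float(kcal.sum())
    held = float(kcal.reindex(list(held_constant)).fillna(0.0).sum()) if held_constant else 0.0
    budget = total - held
    if budget <= 0:
        raise DietError("baseline has no allocatable calories")
    fractions = {g: 0.0 for g in FOOD_GROUPS}
    for commodity, k in kcal.items():
        if commodity in held_constant:
            continue
        fractions[str(group_map[commodity])] += float(k) / budget
    return DietSpec(name=name, group_fractions=fractions, total_energy=total,
                    held_constant=held_constant)


def build_diet(
    spec: DietSpec,
    baseline_kg_per_day: pd.Series,
    energy_density: pd.Series,
    group_map: pd.Series,
) -> pd.Series:
    """Commodity-level intakes (kg/person/day) realising a diet spec.

    Group energy budgets are ``fraction × (total − held-constant kcal)``;
    within a group, commodity energies keep their baseline proportions;
    held-constant commodities copy the baseline. Total calories (including
    held-constant) equal ``spec.total_energy`` exactly.
    """
    idx = baseline_kg_per_day.index
    e = energy_density.reindex(idx)
    if (e <= 0).any() or e.isna().any():
        bad = list(idx[(e.isna()) | (e <= 0)])
        raise DietError(f"non-positive or missing energy density for {bad}")
    base_kcal = baseline_kg_per_day * e
    held_kcal = float(base_kcal.reindex([c for c in spec.held_constant if c in idx]).sum())
    budget = spec.total_energy - held_kcal
    if budget < 0:
        raise DietError(
            f"diet {spec.name!r}: held-constant calories ({held_kcal:.0f}) exceed "
            f"total energy ({spec.total_energy:.0f})"
        )
    intake = pd.Series(0.0, index=idx)
    for c in spec.held_constant:
        if c in idx:
            intake[c] = baseline_kg_per_day[c]
    for group, fraction in spec.group_fractions.items():
        members = [c for c in idx
                   if str(group_map.get(c)) == group and c not in spec.held_constant]
        group_base = float(base_kcal.reindex(members).sum())
        if fraction > 0 and group_base <= 0:
            raise DietError(
                f"diet {spec.name!r}: group {group!r} has energy fraction "
                f"{fraction:.2%} but no baseline consumption to apportion"
            )
        if group_base <= 0:
            continue
        group_kcal = fraction * budget
        for c in members:
            intake[c] = group_kcal * (float(base_kcal[c]) / group_base) / float(e[c])
    return intake


def diet_footprint(
    intakes_kg_per_day: pd.Series,
    impacts: dict[str, ImpactValue],
    group_map: pd.Series,
    sugar_commodities: set[str] = frozenset(),
) -> tuple[float, dict[str, float]]:
    """dE/person/day of a diet, with its food-group decomposition.

    Sugar commodities are allocated calories like any other but contribute
    zero impact.
    """
    total = 0.0
    by_group: dict[str, float] = {}
    for commodity, kg in intakes_kg_per_day.items():
        if kg <= 0 or commodity in sugar_commodities:
            continue
        if commodity not in impacts:
            raise KeyError(f"no impact value for diet commodity {commodity!r}")
        contrib = kg * impacts[commodity].value
        total += contrib
        group = str(group_map.get(commodity, "other"))
        by_group[group] = by_group.get(group, 0.0) + contrib
    return total, by_group


def compare_diets(
    specs: list[DietSpec],
    baseline_kg_per_day: pd.Series,
    energy_density: pd.Series,
    group_map: pd.Series,
    impacts: dict[str, ImpactValue],
    sugar_commodities: set[str] = frozenset(),
) -> pd.DataFrame:
    """Footprints of several diets against the same baseline sourcing.

    Returns one row per diet: total dE/person/day, ratio to the first spec
    (the baseline), and per-group impacts. Provenance is the consumer
    country's current sourcing throughout — a scenario changes what is eaten,
    not where it comes from.
    """
    rows = []
    baseline_total: float | None = None
    for spec in specs:
        intake = build_diet(spec, baseline_kg_per_day, energy_density, group_map)
        total, by_group = diet_footprint(intake, impacts, group_map, sugar_commodities)
        if baseline_total is None:
            baseline_total = total
        row: dict[str, float | str] = {
            "diet": spec.name,
            "kcal_per_day": spec.total_energy,
            "de_per_day": total,
            "ratio_to_baseline": total / baseline_total if baseline_total > 0 else float("nan"),
        }
        for g in FOOD_GROUPS:
            row[f"de_{g}"] = by_group.get(g, 0.0)
        rows.append(row)
    return pd.DataFrame(rows)
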