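"""End-to-end pipeline: world → impacts → provenance → footprints → diets.

Stages form a DAG: vegetal production impacts feed the re-export correction,
whose consumption-basis feed-crop impacts enter the livestock attribution;
animal products are then themselves traded and provenance-corrected before
per-capita footprints and diet scenarios are assembled. Each stage's CSV is
written atomically and a manifest records the config echo, seed and config
hash, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diets as diets_mod
from .footprints import (FootprintRecord, implied_land_and_marginality,
                         import_domestic_split, per_capita_footprint)
from .livestock import animal_production_impact, grazing_life_density
from .provenance import consumption_perkg_impact, provenance_shares
from .spatial import (ImpactValue, national_production_impact,
                      weighted_distribution)
from .synthetic import ConfigError, SyntheticWorld, WorldConfig, generate_world
from .tables import FOOD_GROUPS

log = logging.getLogger("lifecost")

ALL_STAGES = ("production", "consumption", "footprints", "diets")


@dataclass
class PipelineConfig:
    """One reproducible pipeline run."""

    world: WorldConfig = field(default_factory=WorldConfig)
    out_dir: str = "out"
    stages: tuple[str, ...] = ALL_STAGES
    include_sugar: bool = False
    diet_country: str | None = None  # default: first country
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ConfigError(f"unknown stages {unknown}")
        # dependency closure: later stages need every earlier one
        wanted = max(ALL_STAGES.index(s) for s in self.stages)
        self.stages = ALL_STAGES[: wanted + 1]


@dataclass
class PipelineResult:
    world: SyntheticWorld
    production_impacts: dict[str, dict[str, ImpactValue]]  # commodity -> country -> value
    shares: dict[str, pd.DataFrame]  # commodity -> consumer × origin
    consumption_impacts: dict[str, dict[str, ImpactValue]]
    distributions: pd.DataFrame
    footprints: dict[str, FootprintRecord]
    land_per_kg: pd.DataFrame  # country × commodity, km²·yr per kg
    diet_totals: pd.DataFrame | None = None
    diet_detail: pd.DataFrame | None = None


def _vegetal_production_impacts(world: SyntheticWorld) -> dict[str, dict[str, ImpactValue]]:
    life = world.layers["life_density"]
    cidx = world.country_index
    out: dict[str, dict[str, ImpactValue]] = {}
    for c in world.vegetal:
        by_country: dict[str, ImpactValue] = {}
        for code, country in enumerate(world.countries):
            v = national_production_impact(
                c, country, cidx, code, life,
                world.layers[f"production:{c}"], world.layers[f"harvested_area:{c}"],
                cell_weighting=world.config.cell_weighting,
            )
            if v is not None:
                by_country[country] = v
        out[c] = by_country
    return out


def _consumption_for(
    world: SyntheticWorld,
    commodities: list[str],
    production_impacts: dict[str, dict[str, ImpactValue]],
    shares: dict[str, pd.DataFrame],
    consumption: dict[str, dict[str, ImpactValue]],
) -> None:
    for c in commodities:
        s = provenance_shares(world.tables.production[c], world.tables.trade[c])
        shares[c] = s
        by_country: dict[str, ImpactValue] = {}
        for consumer in s.index:
            by_country[consumer] = consumption_perkg_impact(
                c, consumer, s.loc[consumer], production_impacts[c])
        consumption[c] = by_country


def _animal_production_impacts(
    world: SyntheticWorld, consumption: dict[str, dict[str, ImpactValue]]
) -> dict[str, dict[str, ImpactValue]]:
    life = world.layers["life_density"]
    pasture = world.layers["pasture_frac"]
    cidx = world.country_index
    out: dict[str, dict[str, ImpactValue]] = {a: {} for a in world.animal}
    for a in world.animal:
        dens_layer = world.layers[f"livestock_density:{a}"]
        for code, country in enumerate(world.countries):
            if world.tables.production.loc[country, a] <= 0:
                continue  # defined-absent
            g = world.feed.grazing(country, a)
            gdens = grazing_life_density(
                life, pasture, dens_layer, cidx, code,
                aggregation=world.config.grazing_aggregation,
            ) if g > 0 else None
            feed_row = world.feed.feed_row(country, a)
            feed_impacts = {f: consumption[f][country] for f in feed_row
                            if feed_row[f] > 0 and f in consumption
                            and country in consumption[f]}
            out[a][country] = animal_production_impact(
                a, country, gdens, g, feed_row, feed_impacts)
    return out


def _global_distributions(
    world: SyntheticWorld, production_impacts: dict[str, dict[str, ImpactValue]]
) -> pd.DataFrame:
    rows = []
    pooled: dict[str, tuple[list[float], list[float]]] = {g: ([], []) for g in FOOD_GROUPS}
    for c in world.tables.commodities:
        vals, weights = [], []
        for country, v in production_impacts.get(c, {}).items():
            mass = float(world.tables.production.loc[country, c])
            if mass > 0:
                vals.append(v.value)
                weights.append(mass)
        if not vals:
            continue
        d = weighted_distribution(vals, weights)
        rows.append({"name": c, "level": "commodity", "q10": d.q10, "q50": d.q50, "q90": d.q90})
        group = world.feed.commodities[c].group
        pooled[group][0].extend(vals)
        pooled[group][1].extend(weights)
    for g in FOOD_GROUPS:
        vals, weights = pooled[g]
        if not vals:
            continue
        d = weighted_distribution(vals, weights)
        rows.append({"name": g, "level": "group", "q10": d.q10, "q50": d.q50, "q90": d.q90})
    return pd.DataFrame(rows)


def _land_per_kg(world: SyntheticWorld) -> pd.DataFrame:
    """km²·yr of land behind one kg of each commodity in each country."""
    cidx = world.country_index
    n = len(world.countries)
    out = pd.DataFrame(np.nan, index=world.countries, columns=world.tables.commodities)
    for c in world.vegetal:
        area = np.bincount(cidx.ravel(),
                           weights=world.layers[f"harvested_area:{c}"].values.ravel(),
                           minlength=n)
        prod_kg = world.tables.production[c].values * 1000.0
        out[c] = np.divide(area, prod_kg, out=np.full(n, np.nan), where=prod_kg > 0)
    for a in world.animal:
        for i, country in enumerate(world.countries):
            if world.tables.production.loc[country, a] <= 0:
                continue
            feed_row = world.feed.feed_row(country, a)
            feed_land = sum(req * out.loc[country, f]
                            for f, req in feed_row.items()
                            if req > 0 and pd.notna(out.loc[country, f]))
            out.loc[country, a] = world.feed.grazing(country, a) + feed_land
    return out


def compute_all(
    world: SyntheticWorld,
    include_sugar: bool = False,
    diet_country: str | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
) -> PipelineResult:
    """Run the analysis stages on a world and return all in-memory results."""
    production = _vegetal_production_impacts(world)
    shares: dict[str, pd.DataFrame] = {}
    consumption: dict[str, dict[str, ImpactValue]] = {}
    result = PipelineResult(
        world=world, production_impacts=production, shares=shares,
        consumption_impacts=consumption, distributions=pd.DataFrame(),
        footprints={}, land_per_kg=pd.DataFrame(),
    )
    if "consumption" not in stages:
        result.distributions = _global_distributions(world, production)
        return result

    _consumption_for(world, world.vegetal, production, shares, consumption)
    animal = _animal_production_impacts(world, consumption)
    production.update(animal)
    _consumption_for(world, world.animal, production, shares, consumption)
    result.distributions = _global_distributions(world, production)

    if "footprints" not in stages:
        return result
    excluded = set() if include_sugar else {
        c.name for c in world.commodities if c.is_sugar}
    group_map = world.feed.group_map
    land = _land_per_kg(world)
    result.land_per_kg = land
    for country in world.countries:
        supply = world.tables.food_per_capita.loc[country]
        impacts = {c: consumption[c][country] for c in consumption
                   if country in consumption[c]}
        rec = per_capita_footprint(country, supply, impacts, group_map, excluded)
        masses = supply[[c for c in supply.index if c not in excluded]]
        rec.implied_land_km2, _warn = implied_land_and_marginality(
            masses, land.loc[country])
        result.footprints[country] = rec

    if "diets" not in stages:
        return result
    country = diet_country or world.countries[0]
    if country not in world.countries:
        raise ConfigError(f"diet country {country!r} is not in the world")
    held = frozenset(c.name for c in world.commodities if c.is_stimulant_or_spice)
    sugar = {c.name for c in world.commodities if c.is_sugar}
    base_kg_day = world.tables.food_per_capita.loc[country] / 365.0
    energy = world.feed.energy_density
    base = diets_mod.baseline_spec("baseline_observed", base_kg_day, energy,
                                   group_map, held)
    base_kcal = base_kg_day * energy.reindex(base_kg_day.index)
    group_kcal = base_kcal.groupby(group_map.reindex(base_kcal.index)).sum()
    specs = [base]
    for spec in diets_mod.reference_diets(total_energy=base.total_energy,
                                          held_constant=held):
        unmet = [g for g, f in spec.group_fractions.items()
                 if f > 0 and group_kcal.get(g, 0.0) <= 0]
        if unmet:
            log.warning("diet %s skipped for %s: no baseline consumption in %s",
                        spec.name, country, unmet)
            continue
        specs.append(spec)
    impacts = {c: consumption[c][country] for c in consumption
               if country in consumption[c]}
    result.diet_totals = diets_mod.compare_diets(
        specs, base_kg_day, energy, group_map, impacts,
        sugar_commodities=set() if include_sugar else sugar)
    detail_rows = []
    for spec in specs:
        intake = diets_mod.build_diet(spec, base_kg_day, energy, group_map)
        kcal = intake * energy.reindex(intake.index)
        _, by_group = diets_mod.diet_footprint(
            intake, impacts, group_map,
            sugar_commodities=set() if include_sugar else sugar)
        for g in FOOD_GROUPS:
            members = [c for c in intake.index if group_map.get(c) == g]
            detail_rows.append({
                "diet": spec.name, "group": g,
                "kcal": float(kcal.reindex(members).sum()),
                "kg": float(intake.reindex(members).sum()),
                "de_per_day": by_group.get(g, 0.0),
            })
    result.diet_detail = pd.DataFrame(detail_rows)
    return result


def _atomic_write(frame: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    frame.to_csv(tmp, index=False)
    os.replace(tmp, path)


def _impacts_frame(impacts: dict[str, dict[str, ImpactValue]]) -> pd.DataFrame:
    rows = []
    for c in sorted(impacts):
        for country in sorted(impacts[c]):
            v = impacts[c][country]
            rows.append({
                "commodity": c, "country": country, "impact_de_per_kg": v.value,
                "crop": v.components.get("crop", 0.0),
                "grazing": v.components.get("grazing", 0.0),
                "feed": v.components.get("feed", 0.0),
                "basis": v.basis,
            })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the configured stages and write the output bundle."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    # the manifest echoes the scientific configuration, not the run location
    cfg_dict.pop("out_dir", None)
    cfg_dict.pop("log_level", None)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()
    log.info("pipeline start: seed=%s hash=%s", config.world.seed, cfg_hash)

    world = generate_world(config.world)
    result = compute_all(world, include_sugar=config.include_sugar,
                         diet_country=config.diet_country, stages=config.stages)

    _atomic_write(_impacts_frame(
        {c: v for c, v in result.production_impacts.items()}), out / "production_impacts.csv")
    _atomic_write(result.distributions, out / "global_distributions.csv")
    if result.consumption_impacts:
        _atomic_write(_impacts_frame(result.consumption_impacts),
                      out / "consumption_impacts.csv")
        prov_rows = [
            {"commodity": c, "consumer": consumer, "origin": origin, "share": share}
            for c in sorted(result.shares)
            for consumer in result.shares[c].index
            for origin, share in result.shares[c].loc[consumer].items()
            if share > 0
        ]
        _atomic_write(pd.DataFrame(prov_rows), out / "provenance.csv")
    if result.footprints:
        group_rows, summary_rows = [], []
        for country in sorted(result.footprints):
            rec = result.footprints[country]
            for g, v in sorted(rec.by_group.items()):
                group_rows.append({"country": country, "group": g, "de_per_capita_yr": v})
            split = import_domestic_split(rec)
            summary_rows.append({
                "country": country, "total_de_per_capita_yr": rec.total,
                "domestic_share": split[0] if split else float("nan"),
                "imported_share": split[1] if split else float("nan"),
                "implied_land_km2": rec.implied_land_km2,
            })
        _atomic_write(pd.DataFrame(group_rows), out / "footprint_groups.csv")
        _atomic_write(pd.DataFrame(summary_rows), out / "footprint_summary.csv")
    if result.diet_totals is not None:
        _atomic_write(result.diet_totals, out / "diet_totals.csv")
        _atomic_write(result.diet_detail, out / "diet_comparison.csv")

    manifest = {"seed": config.world.seed, "config": cfg_dict, "config_hash": cfg_hash}
    tmp = out / "run_manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, sort_keys=True, indent=2, default=str))
    os.replace(tmp, out / "run_manifest.json")
    log.info("pipeline done: %s", out)
    return result
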