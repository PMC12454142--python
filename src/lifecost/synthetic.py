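"""Seeded synthetic worlds for testing the footprint pipeline end to end.

A synthetic world bundles everything the analysis consumes for the real
Earth — an extinction-density ("restore") raster derived from overlapping
species ranges, per-commodity production/yield rasters, pasture and livestock
layers, and exactly balanced FAO-style production/trade/food-supply tables —
on a small abstract equal-area grid. The generator is deterministic under
(config, seed): every random draw comes from a named substream of the single
configured seed, so adding a new draw to one stage never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .grids import RasterGrid
from .life import SpeciesDef, life_restore_density
from .tables import CommodityDef, FeedNutritionTables, SupplyTradeTables


class ConfigError(ValueError):
    """Inconsistent world configuration."""


# role parameter tables: yields in t/km², energy in kcal/kg, protein g/g
_VEGETAL_ROLES = ("grain", "vegetable", "legume", "sugar", "stimulant", "fruit", "root", "oilcrop")
_ANIMAL_ROLES = ("ruminant_meat", "poultry_meat", "dairy")
_FEED_ROLES = ("grain", "legume", "oilcrop")

_ROLE_GROUP = {
    "grain": "grains_roots",
    "root": "grains_roots",
    "vegetable": "fruit_veg",
    "fruit": "fruit_veg",
    "legume": "legumes_nuts",
    "sugar": "sugar_other",
    "stimulant": "sugar_other",
    "oilcrop": "sugar_other",
    "ruminant_meat": "ruminant_meat",
    "poultry_meat": "poultry_pig",
    "dairy": "dairy_eggs",
}
_ROLE_ENERGY = {
    "grain": 3400.0, "vegetable": 400.0, "legume": 3300.0, "sugar": 3870.0,
    "stimulant": 900.0, "fruit": 550.0, "root": 900.0, "oilcrop": 4000.0,
    "ruminant_meat": 2500.0, "poultry_meat": 1700.0, "dairy": 640.0,
}
_ROLE_PROTEIN = {
    "grain": 0.12, "vegetable": 0.02, "legume": 0.24, "sugar": 0.0,
    "stimulant": 0.12, "fruit": 0.008, "root": 0.02, "oilcrop": 0.20,
    "ruminant_meat": 0.26, "poultry_meat": 0.19, "dairy": 0.034,
}
_ROLE_YIELD = {  # national mean yields, t/km² (1 t/ha = 100 t/km²)
    "grain": 400.0, "vegetable": 2000.0, "legume": 180.0, "sugar": 5000.0,
    "stimulant": 80.0, "fruit": 1200.0, "root": 2500.0, "oilcrop": 250.0,
}
# livestock: mean stocking density (head/km²), offtake (t product/head/yr),
# total feed requirement (kg feed / kg product), whether the animal grazes
_ROLE_LIVESTOCK = {
    "ruminant_meat": dict(density=20.0, out_rate=0.08, feed_total=5.0, grazes=True),
    "poultry_meat": dict(density=400.0, out_rate=0.012, feed_total=2.2, grazes=False),
    "dairy": dict(density=15.0, out_rate=2.0, feed_total=0.7, grazes=True),
}


@dataclass
class WorldConfig:
    """Parameters of a synthetic world.

    The grid is abstract equal-area: ``grid_rows × grid_cols`` cells of
    ``cell_area`` km² each, partitioned into ``n_countries`` contiguous
    territories. Row 0 plays the role of high latitude; when
    ``tropics_gradient`` is set, species richness and endemism increase
    toward the last ("equatorial") rows, which raises restore densities there.
    """

    grid_rows: int = 40
    grid_cols: int = 40
    cell_area: float = 100.0  # km² per cell
    n_countries: int = 6
    n_commodities: int = 10
    n_animal_commodities: int = 3
    n_species: int = 120
    z: float = 0.25  # extinction power-law exponent
    seed: int = 0
    tropics_gradient: bool = True
    endemic_fraction: float = 0.35
    endemic_range_cells: int = 6
    ag_tolerant_fraction: float = 0.25  # species tolerating cropland
    pasture_tolerant_fraction: float = 0.35
    trade_mode: str = "random"  # random | autarky | reexport_chain
    trade_intensity: float = 0.3
    ensure_cover: bool = False  # add range-tiling species so richness >= 1 everywhere
    cell_weighting: str = "production"  # production | area
    grazing_aggregation: str = "median"  # median | mean

    def __post_init__(self) -> None:
        for name in ("grid_rows", "grid_cols", "n_countries", "n_commodities", "n_species"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_animal_commodities < 0:
            raise ConfigError("n_animal_commodities must be >= 0")
        if self.n_animal_commodities > self.n_commodities:
            raise ConfigError("more animal commodities than total commodities")
        if self.n_animal_commodities == self.n_commodities and self.n_commodities > 0:
            raise ConfigError("animal commodities need at least one vegetal feed crop")
        if self.z <= 0:
            raise ConfigError("power-law exponent z must be > 0")
        if self.cell_area <= 0:
            raise ConfigError("cell_area must be > 0")
        if self.n_countries > self.grid_rows * self.grid_cols:
            raise ConfigError("more countries than grid cells")
        for name in ("endemic_fraction", "ag_tolerant_fraction", "pasture_tolerant_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.trade_mode not in ("random", "autarky", "reexport_chain"):
            raise ConfigError(f"unknown trade_mode {self.trade_mode!r}")
        if self.cell_weighting not in ("production", "area"):
            raise ConfigError(f"unknown cell_weighting {self.cell_weighting!r}")
        if self.grazing_aggregation not in ("median", "mean"):
            raise ConfigError(f"unknown grazing_aggregation {self.grazing_aggregation!r}")


def _rng(config: WorldConfig, stream: str) -> np.random.Generator:
    """Named RNG substream derived from the world seed."""
    return np.random.default_rng(
        np.random.SeedSequence([config.seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])
    )


def build_commodities(config: WorldConfig) -> list[CommodityDef]:
    """Commodity roster: vegetal roles first, then animal roles (cycled)."""
    n_veg = config.n_commodities - config.n_animal_commodities
    defs: list[CommodityDef] = []
    for k in range(n_veg):
        role = _VEGETAL_ROLES[k % len(_VEGETAL_ROLES)]
        defs.append(CommodityDef(
            name=f"{role}_{k}",
            role=role,
            group=_ROLE_GROUP[role],
            is_sugar=role == "sugar",
            is_stimulant_or_spice=role == "stimulant",
            energy_density=_ROLE_ENERGY[role],
            protein_fraction=_ROLE_PROTEIN[role],
        ))
    for k in range(config.n_animal_commodities):
        role = _ANIMAL_ROLES[k % len(_ANIMAL_ROLES)]
        defs.append(CommodityDef(
            name=f"{role}_{n_veg + k}",
            role=role,
            group=_ROLE_GROUP[role],
            is_animal=True,
            is_ruminant=_ROLE_LIVESTOCK[role]["grazes"],
            energy_density=_ROLE_ENERGY[role],
            protein_fraction=_ROLE_PROTEIN[role],
        ))
    return defs


@dataclass
class SyntheticWorld:
    """All layers and tables of one generated world."""

    config: WorldConfig
    countries: list[str]
    commodities: list[CommodityDef]
    species: list[SpeciesDef]
    layers: dict[str, RasterGrid]
    tables: SupplyTradeTables
    feed: FeedNutritionTables

    @property
    def vegetal(self) -> list[str]:
        return [c.name for c in self.commodities if not c.is_animal]

    @property
    def animal(self) -> list[str]:
        return [c.name for c in self.commodities if c.is_animal]

    @property
    def country_index(self) -> np.ndarray:
        return self.layers["country_id"].values.astype(np.int64)

    def landcover(self) -> dict[str, np.ndarray]:
        return {
            "natural": self.layers["natural_frac"].values,
            "cropland": self.layers["cropland_frac"].values,
            "pasture": self.layers["pasture_frac"].values,
        }


def _country_map(config: WorldConfig) -> np.ndarray:
    """Partition the flattened grid into contiguous equal-ish territories."""
    n_cells = config.grid_rows * config.grid_cols
    flat = np.arange(n_cells) * config.n_countries // n_cells
    return flat.reshape(config.grid_rows, config.grid_cols).astype(np.float64)


def _landcover_totals(config: WorldConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(natural, cropland_total, pasture) area fractions; sum <= 1, natural >= 0.4."""
    rng = _rng(config, "landcover")
    shape = (config.grid_rows, config.grid_cols)
    ag_total = 0.15 + 0.45 * rng.random(shape)
    pasture_share = 0.25 + 0.40 * rng.random(shape)
    pasture = ag_total * pasture_share
    cropland = ag_total - pasture
    natural = 1.0 - ag_total
    return natural, cropland, pasture


def generate_species_set(
    config: WorldConfig, landcover: dict[str, np.ndarray] | None = None
) -> list[SpeciesDef]:
    """Draw a mixture of narrow- (endemic) and wide-ranged species.

    Ranges are rectangular blocks; a configurable fraction of species tolerate
    cropland and/or pasture as habitat, the rest depend on natural cover.
    Current AOH is derived from the supplied land-cover fractions (generated
    internally, from the same seed substream the world uses, when omitted).
    With ``tropics_gradient`` range centres concentrate toward the
    high-row ("equatorial") edge of the grid.
    """
    if landcover is None:
        natural, cropland, pasture = _landcover_totals(config)
    else:
        natural = np.asarray(landcover["natural"], dtype=np.float64)
        cropland = np.asarray(landcover["cropland"], dtype=np.float64)
        pasture = np.asarray(landcover["pasture"], dtype=np.float64)
    rng = _rng(config, "species")
    rows, cols = config.grid_rows, config.grid_cols
    species: list[SpeciesDef] = []

    def make(mask: np.ndarray, crop_ok: bool, pasture_ok: bool, sid: str) -> SpeciesDef:
        cells = int(mask.sum())
        a0 = cells * config.cell_area
        per_cell = natural.copy()
        if crop_ok:
            per_cell = per_cell + cropland
        if pasture_ok:
            per_cell = per_cell + pasture
        a = float(per_cell[mask].sum()) * config.cell_area
        return SpeciesDef(
            id=sid,
            range_mask=mask,
            pristine_aoh=a0,
            suitability={"natural": True, "cropland": crop_ok, "pasture": pasture_ok},
            current_aoh=min(a, a0),
        )

    for s in range(config.n_species):
        endemic = rng.random() < config.endemic_fraction
        if config.tropics_gradient:
            r0 = int(rng.triangular(0, rows - 1, rows - 1)) if rows > 1 else 0
        else:
            r0 = int(rng.integers(rows))
        c0 = int(rng.integers(cols))
        if endemic:
            target = int(rng.integers(1, config.endemic_range_cells + 1))
            h = max(1, int(np.sqrt(target)))
            w = max(1, target // h)
        else:
            h = max(2, int(rows * (0.3 + 0.4 * rng.random())))
            w = max(2, int(cols * (0.3 + 0.4 * rng.random())))
        mask = np.zeros((rows, cols), dtype=bool)
        mask[max(0, r0 - h // 2): r0 + (h + 1) // 2, max(0, c0 - w // 2): c0 + (w + 1) // 2] = True
        crop_ok = bool(rng.random() < config.ag_tolerant_fraction)
        pasture_ok = bool(rng.random() < config.pasture_tolerant_fraction)
        species.append(make(mask, crop_ok, pasture_ok, f"sp_{s}"))

    if config.ensure_cover:
        # tile the grid so every cell is covered by at least one range
        t = max(1, int(np.sqrt(config.endemic_range_cells)))
        k = 0
        for r in range(0, rows, t):
            for c in range(0, cols, t):
                mask = np.zeros((rows, cols), dtype=bool)
                mask[r:r + t, c:c + t] = True
                species.append(make(mask, False, False, f"cover_{k}"))
                k += 1
    return species


def generate_supply_and_trade(
    config: WorldConfig,
    commodities: list[CommodityDef] | None = None,
    production: pd.DataFrame | None = None,
    feed_requirement: pd.DataFrame | None = None,
    population: pd.Series | None = None,
) -> SupplyTradeTables:
    """Generate balanced FAO-style tables for a world.

    When called standalone (no production table), national production is drawn
    directly from the same distributions the raster stage uses in aggregate,
    so the tables are self-consistent but carry no raster counterpart. Within
    :func:`generate_world` the raster-derived production is passed in, making
    table and raster sums identical by construction.
    """
    commodities = commodities or build_commodities(config)
    countries = [f"C{i:02d}" for i in range(config.n_countries)]
    names = [c.name for c in commodities]
    rng = _rng(config, "trade")

    if production is None:
        prng = _rng(config, "standalone_production")
        production = pd.DataFrame(
            prng.lognormal(np.log(1e4), 0.5, size=(len(countries), len(names))),
            index=countries, columns=names,
        )
        if config.trade_mode == "reexport_chain":
            production.iloc[-1, 0] = 0.0
    if population is None:
        perng = _rng(config, "population")
        cells = config.grid_rows * config.grid_cols
        base = cells / config.n_countries * 1000.0
        population = pd.Series(
            base * perng.lognormal(0.0, 0.3, size=len(countries)), index=countries
        )

    # bilateral trade, drawn from production so exports never exceed supply
    trade: dict[str, pd.DataFrame] = {}
    n = len(countries)
    for c in names:
        t = np.zeros((n, n))
        if config.trade_mode != "autarky" and n > 1:
            for i in range(n):
                p_i = float(production.loc[countries[i], c])
                if p_i <= 0:
                    continue
                n_partners = int(rng.integers(1, min(3, n)))
                partners = rng.choice([j for j in range(n) if j != i], size=n_partners,
                                      replace=False)
                frac = config.trade_intensity * rng.random()
                for j in partners:
                    t[i, j] += p_i * frac / n_partners
        trade[c] = pd.DataFrame(t, index=countries, columns=countries)

    if config.trade_mode == "reexport_chain" and n > 1:
        # last country is a pure re-export hub for the first commodity
        c0 = names[0]
        t = trade[c0].values
        hub = n - 1
        t[hub, :] = 0.0
        for i in range(n - 1):
            p_i = float(production.loc[countries[i], c0])
            t[i, hub] += 0.15 * p_i
        t[hub, 0] = 0.7 * t[:, hub].sum()
        trade[c0] = pd.DataFrame(t, index=countries, columns=countries)

    # feed requirements (may be supplied by the livestock stage)
    veg = [c.name for c in commodities if not c.is_animal]
    animals = [c.name for c in commodities if c.is_animal]
    feed_crops = [c.name for c in commodities if c.role in _FEED_ROLES] or veg[:1]
    if feed_requirement is None:
        frng = _rng(config, "feed")
        rows = []
        for i in countries:
            for c in commodities:
                if not c.is_animal:
                    continue
                total = _ROLE_LIVESTOCK[c.role]["feed_total"] * frng.lognormal(0.0, 0.1)
                split = frng.dirichlet(np.full(len(feed_crops), 3.0))
                for f, s in zip(feed_crops, split):
                    rows.append((i, c.name, f, total * s))
        feed_requirement = pd.DataFrame(rows, columns=["country", "animal", "feed", "value"])

    # cap feed draw at 80% of domestic supply of each feed crop, then balance
    feed_use = pd.DataFrame(0.0, index=countries, columns=names)
    fr = feed_requirement.copy()
    for i in countries:
        for f in feed_crops:
            d = float(production.loc[i, f] + trade[f][i].sum() - trade[f].loc[i].sum())
            sel = (fr["country"] == i) & (fr["feed"] == f)
            tot = float(sum(
                fr.loc[sel & (fr["animal"] == a), "value"].sum() * production.loc[i, a]
                for a in animals
            ))
            if tot > 0.8 * d and tot > 0:
                fr.loc[sel, "value"] *= max(0.0, 0.8 * d) / tot
                tot = max(0.0, 0.8 * d)
            feed_use.loc[i, f] = tot

    food_pc = pd.DataFrame(0.0, index=countries, columns=names)
    for c in names:
        dom = production[c] + pd.DataFrame(trade[c]).sum(axis=0) - pd.DataFrame(trade[c]).sum(axis=1)
        food = dom - feed_use[c]
        food_pc[c] = food.clip(lower=0.0) * 1000.0 / population

    tables = SupplyTradeTables(
        countries=countries, commodities=names, production=production, trade=trade,
        feed_use=feed_use, food_per_capita=food_pc, population=population,
    )
    tables._feed_requirement = fr  # type: ignore[attr-defined]  # handed to generate_world
    return tables


def generate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a complete, mutually consistent synthetic world."""
    commodities = build_commodities(config)
    countries = [f"C{i:02d}" for i in range(config.n_countries)]
    names = [c.name for c in commodities]
    veg = [c.name for c in commodities if not c.is_animal]
    animals = [c for c in commodities if c.is_animal]
    rows, cols = config.grid_rows, config.grid_cols
    shape = (rows, cols)
    area = config.cell_area

    country_map = _country_map(config)
    cidx = country_map.astype(np.int64)
    natural, cropland, pasture = _landcover_totals(config)

    # per-country crop mix over vegetal commodities
    mix_rng = _rng(config, "cropmix")
    mix = mix_rng.dirichlet(np.full(len(veg), 2.0), size=config.n_countries)
    if config.trade_mode == "reexport_chain" and config.n_countries > 1 and veg:
        hub = config.n_countries - 1
        mix[hub, 0] = 0.0
        if mix[hub].sum() > 0:
            mix[hub] /= mix[hub].sum()

    layers: dict[str, RasterGrid] = {
        "country_id": RasterGrid("country_id", country_map, units="country-id"),
        "natural_frac": RasterGrid("natural_frac", natural, units="fraction"),
        "cropland_frac": RasterGrid("cropland_frac", cropland, units="fraction"),
        "pasture_frac": RasterGrid("pasture_frac", pasture, units="fraction"),
    }

    yrng = _rng(config, "yield")
    production_tbl = pd.DataFrame(0.0, index=countries, columns=names)
    for k, c in enumerate(veg):
        role = next(cd.role for cd in commodities if cd.name == c)
        crop_frac = cropland * mix[cidx, k]
        base = _ROLE_YIELD[role] * yrng.lognormal(0.0, 0.3, size=config.n_countries)
        cell_mult = yrng.lognormal(0.0, 0.15, size=shape)
        yield_map = base[cidx] * cell_mult  # t/km²
        harvested = crop_frac * area
        prod = harvested * yield_map
        layers[f"crop_frac:{c}"] = RasterGrid(f"crop_frac:{c}", crop_frac, units="fraction")
        layers[f"yield:{c}"] = RasterGrid(f"yield:{c}", yield_map, units="t/km2")
        layers[f"harvested_area:{c}"] = RasterGrid(f"harvested_area:{c}", harvested, units="km2")
        layers[f"production:{c}"] = RasterGrid(f"production:{c}", prod, units="t/yr")
        production_tbl[c] = pd.Series(
            np.bincount(cidx.ravel(), weights=prod.ravel(), minlength=config.n_countries),
            index=countries,
        )

    # livestock layers; ruminants live on pasture, monogastrics on any farmed land
    lrng = _rng(config, "livestock")
    ruminant_names = [a.name for a in animals if a.is_ruminant]
    dens_stack: dict[str, np.ndarray] = {}
    for a in animals:
        p = _ROLE_LIVESTOCK[a.role]
        base = p["density"] * lrng.lognormal(0.0, 0.3, size=config.n_countries)
        cell_mult = lrng.lognormal(0.0, 0.2, size=shape)
        land = pasture if p["grazes"] else (pasture + cropland)
        dens = np.where(land > 0, base[cidx] * cell_mult, 0.0)
        dens_stack[a.name] = dens
        prod = dens * land * area * p["out_rate"]
        layers[f"livestock_density:{a.name}"] = RasterGrid(
            f"livestock_density:{a.name}", dens, units="head/km2")
        layers[f"production:{a.name}"] = RasterGrid(f"production:{a.name}", prod, units="t/yr")
        production_tbl[a.name] = pd.Series(
            np.bincount(cidx.ravel(), weights=prod.ravel(), minlength=config.n_countries),
            index=countries,
        )

    # grazing requirement: pasture area shared among ruminants by local density
    grazing_req = pd.DataFrame(0.0, index=countries, columns=[a.name for a in animals])
    if ruminant_names:
        total_rum = np.sum([dens_stack[a] for a in ruminant_names], axis=0)
        for a in ruminant_names:
            share = np.divide(dens_stack[a], total_rum,
                              out=np.zeros(shape), where=total_rum > 0)
            used = share * pasture * area
            used_by_country = np.bincount(cidx.ravel(), weights=used.ravel(),
                                          minlength=config.n_countries)
            p_kg = production_tbl[a].values * 1000.0
            grazing_req[a] = np.divide(used_by_country, p_kg,
                                       out=np.zeros_like(used_by_country), where=p_kg > 0)

    # species and the extinction-density layer
    landcover = {"natural": natural, "cropland": cropland, "pasture": pasture}
    species = generate_species_set(config, landcover)
    layers["life_density"] = life_restore_density(species, landcover, area, config.z)

    tables = generate_supply_and_trade(config, commodities, production=production_tbl)
    feed_requirement = tables._feed_requirement  # type: ignore[attr-defined]
    feed = FeedNutritionTables(
        commodities={c.name: c for c in commodities},
        feed_requirement=feed_requirement,
        grazing_requirement=grazing_req,
    )
    tables.validate()
    return SyntheticWorld(
        config=config, countries=countries, commodities=commodities,
        species=species, layers=layers, tables=tables, feed=feed,
    )
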