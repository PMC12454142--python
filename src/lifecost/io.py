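"""Readers and writers: TIFF rasters, long-format CSV tables, YAML configs.

Rasters are single-band float64 TIFFs with an embedded ``GDAL_NODATA`` tag
(−9999) and a JSON description carrying the layer name and units; synthetic
worlds use an identity transform so no georeferencing is stored. Supply and
trade tables use one long CSV with columns ``country, commodity, element,
value, unit``; trade appears as ``export_to:<iso>`` rows on the origin
country (``import_from:<iso>`` rows on the destination are accepted on read).
"""

from __future__ import annotations

import dataclasses
import json
import os
import re
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .grids import NODATA, RasterGrid
from .synthetic import SyntheticWorld, WorldConfig
from .tables import CommodityDef, FeedNutritionTables, SupplyTradeTables

_GDAL_NODATA_TAG = 42113
_ELEMENT_RE = re.compile(
    r"^(production|feed|food_per_capita|population"
    r"|import_from:[A-Za-z0-9_]+|export_to:[A-Za-z0-9_]+)$"
)

TABLE_COLUMNS = ["country", "commodity", "element", "value", "unit"]


class SchemaError(ValueError):
    """A CSV table violates the long-format schema."""


def write_raster(path: str | Path, grid: RasterGrid) -> None:
    meta = json.dumps({"name": grid.name, "units": grid.units, "nodata": grid.nodata})
    tifffile.imwrite(
        str(path),
        grid.values.astype(np.float64),
        description=meta,
        extratags=[(_GDAL_NODATA_TAG, "s", 0, str(grid.nodata), True)],
    )


def read_raster(path: str | Path) -> RasterGrid:
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(np.float64)
        desc = page.tags.get("ImageDescription")
        name, units, nodata = Path(path).stem, "", NODATA
        if desc is not None:
            try:
                meta = json.loads(desc.value)
                name = meta.get("name", name)
                units = meta.get("units", units)
                nodata = float(meta.get("nodata", nodata))
            except (json.JSONDecodeError, TypeError):
                pass
    return RasterGrid(name, values, units=units, nodata=nodata)


def _atomic_to_csv(frame: pd.DataFrame, path: Path) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    frame.to_csv(tmp, index=False)
    os.replace(tmp, path)


def write_tables(tables: SupplyTradeTables, path: str | Path) -> None:
    """Serialise supply/trade tables to one long-format CSV."""
    rows: list[tuple[str, str, str, float, str]] = []
    for i in tables.countries:
        for c in tables.commodities:
            rows.append((i, c, "production", float(tables.production.loc[i, c]), "t/yr"))
            rows.append((i, c, "feed", float(tables.feed_use.loc[i, c]), "t/yr"))
            rows.append((i, c, "food_per_capita",
                         float(tables.food_per_capita.loc[i, c]), "kg/person/yr"))
            for j in tables.countries:
                flow = float(tables.trade[c].loc[i, j])
                if flow > 0:
                    rows.append((i, c, f"export_to:{j}", flow, "t/yr"))
        rows.append((i, "-", "population", float(tables.population[i]), "persons"))
    _atomic_to_csv(pd.DataFrame(rows, columns=TABLE_COLUMNS), Path(path))


def read_tables(path: str | Path) -> SupplyTradeTables:
    """Parse the long-format CSV back into SupplyTradeTables."""
    df = pd.read_csv(path, dtype={"country": str, "commodity": str, "element": str})
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for idx, el in df["element"].items():
        if not _ELEMENT_RE.match(str(el)):
            raise SchemaError(f"{path}: row {idx + 2}: unknown element {el!r}")
    countries = sorted(df["country"].unique())
    commodities = sorted(c for c in df["commodity"].unique() if c != "-")

    def pivot(element: str) -> pd.DataFrame:
        sel = df[df["element"] == element]
        out = pd.DataFrame(0.0, index=countries, columns=commodities)
        for r in sel.itertuples():
            out.loc[r.country, r.commodity] = float(r.value)
        return out

    trade = {c: pd.DataFrame(0.0, index=countries, columns=countries) for c in commodities}
    for r in df.itertuples():
        el = str(r.element)
        if el.startswith("export_to:"):
            dest = el.split(":", 1)[1]
            if dest not in trade[r.commodity].columns:
                raise SchemaError(f"{path}: row {r.Index + 2}: unknown destination {dest!r}")
            trade[r.commodity].loc[r.country, dest] += float(r.value)
        elif el.startswith("import_from:"):
            origin = el.split(":", 1)[1]
            if origin not in trade[r.commodity].index:
                raise SchemaError(f"{path}: row {r.Index + 2}: unknown origin {origin!r}")
            # mirror form: only fill pairs not already covered by export rows
            if trade[r.commodity].loc[origin, r.country] == 0:
                trade[r.commodity].loc[origin, r.country] = float(r.value)
    pop_rows = df[df["element"] == "population"].set_index("country")["value"]
    population = pop_rows.reindex(countries).astype(float)
    return SupplyTradeTables(
        countries=countries, commodities=commodities,
        production=pivot("production"), trade=trade, feed_use=pivot("feed"),
        food_per_capita=pivot("food_per_capita"), population=population,
    )


def write_feed_tables(feed: FeedNutritionTables, out_dir: str | Path) -> None:
    out = Path(out_dir)
    _atomic_to_csv(feed.feed_requirement, out / "feed_requirement.csv")
    g = feed.grazing_requirement.reset_index(names="country").melt(
        id_vars="country", var_name="animal", value_name="value")
    _atomic_to_csv(g, out / "grazing_requirement.csv")
    rows = [dataclasses.asdict(c) for c in feed.commodities.values()]
    _atomic_to_csv(pd.DataFrame(rows), out / "nutrition.csv")


def read_feed_tables(out_dir: str | Path) -> FeedNutritionTables:
    out = Path(out_dir)
    fr = pd.read_csv(out / "feed_requirement.csv")
    g = pd.read_csv(out / "grazing_requirement.csv").pivot(
        index="country", columns="animal", values="value")
    nut = pd.read_csv(out / "nutrition.csv")
    commodities = {
        r["name"]: CommodityDef(**{k: r[k] for k in (
            "name", "role", "group", "is_animal", "is_ruminant", "is_sugar",
            "is_stimulant_or_spice", "energy_density", "protein_fraction")})
        for _, r in nut.iterrows()
    }
    return FeedNutritionTables(commodities=commodities, feed_requirement=fr,
                               grazing_requirement=g)


def _safe(name: str) -> str:
    return name.replace(":", "__")


def write_world(world: SyntheticWorld, out_dir: str | Path) -> None:
    """Serialise a full synthetic world (rasters, tables, species, config)."""
    out = Path(out_dir)
    (out / "rasters").mkdir(parents=True, exist_ok=True)
    for name, grid in sorted(world.layers.items()):
        write_raster(out / "rasters" / f"{_safe(name)}.tif", grid)
    write_tables(world.tables, out / "supply_trade.csv")
    write_feed_tables(world.feed, out)
    rows = []
    for sp in world.species:
        packed = np.packbits(sp.range_mask.astype(np.uint8)).tobytes().hex()
        rows.append({
            "id": sp.id, "pristine_aoh": sp.pristine_aoh, "current_aoh": sp.current_aoh,
            "natural": sp.suitability["natural"], "cropland": sp.suitability["cropland"],
            "pasture": sp.suitability["pasture"], "range_hex": packed,
        })
    _atomic_to_csv(pd.DataFrame(rows), out / "species.csv")
    write_config(world.config, out / "config.yaml")


def write_config(config: WorldConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def read_config(path: str | Path) -> WorldConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return WorldConfig(**data)
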