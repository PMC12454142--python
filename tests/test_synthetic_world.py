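"""Generator consistency: determinism, balance, raster/table agreement."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import lifecost as lc
from lifecost.life import species_richness
from lifecost.synthetic import ConfigError, build_commodities


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        lc.WorldConfig(n_commodities=2, n_animal_commodities=3)
    with pytest.raises(ConfigError):
        lc.WorldConfig(n_commodities=2, n_animal_commodities=2)
    with pytest.raises(ConfigError):
        lc.WorldConfig(z=0.0)
    with pytest.raises(ConfigError):
        lc.WorldConfig(n_species=0)
    with pytest.raises(ConfigError):
        lc.WorldConfig(trade_mode="barter")


def test_world_is_deterministic_under_seed(tmp_path):
    cfg = lc.WorldConfig(grid_rows=8, grid_cols=8, n_countries=2, n_commodities=6,
                         n_animal_commodities=1, n_species=20, seed=42)
    w1 = lc.generate_world(cfg)
    w2 = lc.generate_world(cfg)
    from lifecost.io import write_world
    write_world(w1, tmp_path / "a")
    write_world(w2, tmp_path / "b")
    for f1 in sorted((tmp_path / "a").rglob("*")):
        if f1.is_file():
            f2 = tmp_path / "b" / f1.relative_to(tmp_path / "a")
            assert f1.read_bytes() == f2.read_bytes(), f1.name


def test_different_seeds_differ():
    cfg = lc.WorldConfig(grid_rows=8, grid_cols=8, n_countries=2, n_species=20, seed=1)
    w1 = lc.generate_world(cfg)
    w2 = lc.generate_world(dataclasses.replace(cfg, seed=2))
    assert not np.array_equal(w1.layers["life_density"].values,
                              w2.layers["life_density"].values)


def test_raster_sums_match_production_table(small_world):
    cidx = small_world.country_index
    for c in small_world.tables.commodities:
        prod = small_world.layers[f"production:{c}"].values
        sums = np.bincount(cidx.ravel(), weights=prod.ravel(),
                           minlength=len(small_world.countries))
        table = small_world.tables.production[c].to_numpy()
        np.testing.assert_allclose(sums, table, rtol=1e-9)


def test_supply_balance_audit(small_world):
    """Independent audit: P + imports − exports − feed − food = 0 per country."""
    t = small_world.tables
    for c in t.commodities:
        trade = t.trade[c]
        for i in t.countries:
            inflow = float(t.production.loc[i, c]) + float(trade[i].sum())
            outflow = float(trade.loc[i].sum()) + float(t.feed_use.loc[i, c])
            food = float(t.food_per_capita.loc[i, c]) * float(t.population[i]) / 1000.0
            assert inflow - outflow - food == pytest.approx(0.0, abs=1e-6 * (inflow + 1))
            assert food >= 0


def test_autarky_mode_has_no_trade(autarky_world):
    t = autarky_world.tables
    for c in t.commodities:
        assert (t.trade[c].values == 0).all()
        food = t.domestic_use(c) - t.feed_use[c]
        np.testing.assert_allclose(
            t.food_per_capita[c] * t.population / 1000.0, food, rtol=1e-9)


def test_reexport_mode_creates_pure_reexporter():
    cfg = lc.WorldConfig(grid_rows=10, grid_cols=10, n_countries=4, n_commodities=6,
                         n_animal_commodities=1, n_species=20, seed=9,
                         trade_mode="reexport_chain")
    w = lc.generate_world(cfg)
    c0 = w.vegetal[0]
    hub = w.countries[-1]
    assert w.tables.production.loc[hub, c0] == 0.0
    assert w.tables.exports(c0)[hub] > 0.0


def test_tropics_gradient_raises_equatorial_density():
    cfg = lc.WorldConfig(grid_rows=30, grid_cols=20, n_countries=3, n_species=150,
                         seed=21, tropics_gradient=True)
    w = lc.generate_world(cfg)
    dens = w.layers["life_density"].values
    third = cfg.grid_rows // 3
    high_lat = dens[:third].mean()  # row 0 plays the pole
    low_lat = dens[-third:].mean()  # last rows play the equator
    assert low_lat > high_lat


def test_endemic_fraction_one_bounds_all_ranges():
    cfg = lc.WorldConfig(grid_rows=12, grid_cols=12, n_species=30, seed=3,
                         endemic_fraction=1.0, endemic_range_cells=4)
    species = lc.generate_species_set(cfg)
    assert all(sp.range_mask.sum() <= 4 for sp in species)


def test_species_set_reproducible_and_consistent():
    cfg = lc.WorldConfig(grid_rows=10, grid_cols=10, n_species=25, seed=8)
    s1 = lc.generate_species_set(cfg)
    s2 = lc.generate_species_set(cfg)
    for a, b in zip(s1, s2):
        assert a.id == b.id
        assert np.array_equal(a.range_mask, b.range_mask)
        assert a.current_aoh == b.current_aoh
        assert 0 < a.current_aoh <= a.pristine_aoh
        assert a.pristine_aoh <= a.range_mask.sum() * cfg.cell_area + 1e-9


def test_ensure_cover_tiles_grid_with_ranges():
    cfg = lc.WorldConfig(grid_rows=9, grid_cols=9, n_species=5, seed=2,
                         ensure_cover=True)
    species = lc.generate_species_set(cfg)
    richness = species_richness(species, (9, 9))
    assert richness.min() >= 1


def test_landcover_fractions_valid(small_world):
    nat = small_world.layers["natural_frac"].values
    crop = small_world.layers["cropland_frac"].values
    past = small_world.layers["pasture_frac"].values
    total = nat + crop + past
    assert (total <= 1 + 1e-12).all()
    assert (nat > 0).all() and (crop >= 0).all() and (past >= 0).all()
    per_crop = sum(small_world.layers[f"crop_frac:{c}"].values
                   for c in small_world.vegetal)
    np.testing.assert_allclose(per_crop, crop, rtol=1e-9)


def test_commodity_roster_covers_all_groups():
    defs = build_commodities(lc.WorldConfig(n_commodities=10, n_animal_commodities=3))
    groups = {c.group for c in defs}
    assert groups == set(lc.FOOD_GROUPS)
    assert any(c.is_sugar for c in defs)
    assert any(c.is_stimulant_or_spice for c in defs)
    assert sum(c.is_animal for c in defs) == 3
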