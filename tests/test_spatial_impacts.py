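"""Per-kg production impacts: cell arithmetic, national medians, scaling laws."""

import numpy as np
import pytest

import lifecost as lc
from conftest import expansion_quantile
from lifecost import (ImpactValue, RasterGrid, cell_perkg_impacts,
                      global_commodity_distribution, national_production_impact,
                      protein_adjusted_impact)


def _grids(density, production, area):
    return (
        RasterGrid("life_density", density, units="dE/km2"),
        RasterGrid("production", production, units="t/yr"),
        RasterGrid("harvested_area", area, units="km2"),
    )


def test_zero_density_gives_zero_impacts():
    d, p, a = _grids(np.zeros((3, 3)), np.full((3, 3), 5.0), np.full((3, 3), 2.0))
    out = cell_perkg_impacts(d, p, a)
    assert (out.values[out.valid_mask] == 0).all()


def test_uniform_field_equals_density_over_yield():
    """Uniform density d and yield y (t/km²) => every cell d / (1000 y)."""
    dens, y = 4e-4, 400.0
    area = np.full((2, 2), 10.0)
    prod = area * y
    d, p, a = _grids(np.full((2, 2), dens), prod, area)
    out = cell_perkg_impacts(d, p, a)
    np.testing.assert_allclose(out.values, dens / (y * 1000.0), rtol=1e-12)


def test_doubling_yield_halves_impacts():
    rng = np.random.default_rng(1)
    dens = rng.uniform(1e-5, 1e-3, (4, 4))
    area = rng.uniform(1.0, 20.0, (4, 4))
    prod = area * rng.uniform(100.0, 500.0, (4, 4))
    base = cell_perkg_impacts(*_grids(dens, prod, area)).values
    doubled = cell_perkg_impacts(*_grids(dens, 2.0 * prod, area)).values
    np.testing.assert_array_equal(doubled, base / 2.0)


def test_production_without_area_is_a_data_error():
    d, p, a = _grids(np.zeros((1, 2)), np.array([[1.0, 0.0]]), np.zeros((1, 2)))
    with pytest.raises(ValueError, match="zero harvested area"):
        cell_perkg_impacts(d, p, a)


def test_negative_inputs_rejected():
    d, p, a = _grids(np.zeros((1, 1)), np.array([[-1.0]]), np.array([[1.0]]))
    with pytest.raises(ValueError):
        cell_perkg_impacts(d, p, a)


def _national(dens, prod, area, cidx=None, code=0, weighting="production"):
    cidx = np.zeros_like(prod, dtype=np.int64) if cidx is None else cidx
    return national_production_impact(
        "crop", "C00", cidx, code, *_grids(dens, prod, area),
        cell_weighting=weighting)


def test_single_producing_cell_is_the_median():
    dens = np.array([[2e-4, 0.0]])
    prod = np.array([[10.0, 0.0]])
    area = np.array([[5.0, 0.0]])
    v = _national(dens, prod, area)
    assert v.value == 2e-4 * 5.0 / (10.0 * 1000.0)
    assert v.components == {"crop": v.value, "grazing": 0.0, "feed": 0.0}


def test_mass_weighted_median_matches_expansion_oracle():
    """Two cells with 99:1 production mass: the heavy cell owns the median."""
    dens = np.array([[1e-4, 1e-3]])
    area = np.array([[1.0, 1.0]])
    prod = np.array([[99.0, 1.0]])
    v = _national(dens, prod, area)
    cell_vals = dens[0] * area[0] / (prod[0] * 1000.0)
    assert v.value == expansion_quantile(cell_vals, prod[0].astype(int), 0.5)
    assert v.value == cell_vals[0]


def test_zero_national_production_is_defined_absent():
    dens = np.full((1, 2), 1e-4)
    prod = np.zeros((1, 2))
    area = np.zeros((1, 2))
    assert _national(dens, prod, area) is None


def test_area_weighting_convention_is_supported():
    dens = np.array([[1e-4, 1e-3]])
    area = np.array([[99.0, 1.0]])
    prod = np.array([[1.0, 99.0]])  # mass concentrated in the high-impact cell
    by_mass = _national(dens, prod, area, weighting="production")
    by_area = _national(dens, prod, area, weighting="area")
    cell_vals = dens[0] * area[0] / (prod[0] * 1000.0)
    assert by_mass.value == cell_vals[1]
    assert by_area.value == cell_vals[0]


def test_yield_and_life_scaling_laws(small_world):
    """×k on yields divides per-kg impacts by k; ×k on the layer multiplies by k."""
    w = small_world
    c = w.vegetal[0]
    life = w.layers["life_density"]
    prod = w.layers[f"production:{c}"]
    area = w.layers[f"harvested_area:{c}"]
    cidx = w.country_index
    base = national_production_impact(c, "C00", cidx, 0, life, prod, area)
    k = 2.0  # power of two keeps IEEE division exact
    prod_k = RasterGrid(prod.name, prod.values * k, prod.units)
    scaled_yield = national_production_impact(c, "C00", cidx, 0, life, prod_k, area)
    assert scaled_yield.value == base.value / k
    life_k = RasterGrid(life.name, life.values * k, life.units)
    scaled_life = national_production_impact(c, "C00", cidx, 0, life_k, prod, area)
    assert scaled_life.value == base.value * k
    # non-power-of-two factors hold to rounding
    prod_3 = RasterGrid(prod.name, prod.values * 3.0, prod.units)
    scaled_3 = national_production_impact(c, "C00", cidx, 0, life, prod_3, area)
    assert scaled_3.value == pytest.approx(base.value / 3.0, rel=1e-12)


def test_global_distribution_single_country_degenerates():
    v = ImpactValue(3e-10, "crop", "C00")
    d = global_commodity_distribution([v], [42.0])
    assert d.q10 == d.q50 == d.q90 == 3e-10


def test_group_distribution_follows_dominant_commodity():
    heavy = [ImpactValue(1e-10, "a", f"C{i}") for i in range(5)]
    light = [ImpactValue(9e-9, "b", "C9")]
    d = global_commodity_distribution(heavy + light, [990.0] * 5 + [3.0])
    assert d.q10 == d.q50 == d.q90 == 1e-10


def test_protein_adjustment():
    v = ImpactValue(2e-10, "legume", "C00")
    assert protein_adjusted_impact(v, 1.0) == 2e-10
    assert protein_adjusted_impact(v, 0.2) == pytest.approx(1e-9, rel=1e-12)
    with pytest.raises(ValueError):
        protein_adjusted_impact(v, 0.0)


def test_protein_adjustment_can_invert_rankings():
    """Low impact but little protein can rank worse than high impact, protein-dense."""
    watery = ImpactValue(5e-11, "vegetable", "C00")  # 2% protein
    dense = ImpactValue(4e-10, "legume", "C00")  # 25% protein
    assert watery.value < dense.value
    assert protein_adjusted_impact(watery, 0.02) > protein_adjusted_impact(dense, 0.25)


def test_engineered_impact_ratio_recovered(small_world):
    """Uniform density & yields engineered so crop A is exactly 3× crop B."""
    rows, cols = 6, 6
    dens = RasterGrid("life_density", np.full((rows, cols), 2e-4), "dE/km2")
    area = RasterGrid("harvested_area", np.full((rows, cols), 8.0), "km2")
    y_b = 300.0
    prod_b = RasterGrid("production", area.values * y_b, "t/yr")
    prod_a = RasterGrid("production", area.values * (y_b / 3.0), "t/yr")
    cidx = np.zeros((rows, cols), dtype=np.int64)
    v_a = national_production_impact("a", "C00", cidx, 0, dens, prod_a, area)
    v_b = national_production_impact("b", "C00", cidx, 0, dens, prod_b, area)
    assert v_a.value / v_b.value == pytest.approx(3.0, rel=1e-9)
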