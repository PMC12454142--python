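"""Per-kg extinction opportunity costs of crop production.

The production-side impact of a vegetal commodity in a country is the
production-mass-weighted median, over the cells where it is grown, of

    extinction density (dE km⁻²) × harvested area (km²) / production (kg)

i.e. the extinction cost of the land that produces one kilogram. Global
distributions across countries (or pooled commodity groups) are weighted
10th/50th/90th percentiles with national production tonnage as weights, so a
country growing 100 units pulls the global median toward its value far more
than one growing 3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import RasterGrid, check_aligned


@dataclass
class ImpactValue:
    """Per-kg extinction impact of one commodity in one country.

    ``components`` decomposes the value into crop, grazing and feed parts
    (all dE per kg); they sum to ``value``. Consumption-basis values retain
    the origin portfolio used to build them.
    """

    value: float
    commodity: str
    country: str
    basis: str = "production"  # production | consumption
    components: dict[str, float] = field(default_factory=dict)
    origin_shares: dict[str, float] | None = None
    origin_values: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.components:
            self.components = {"crop": self.value, "grazing": 0.0, "feed": 0.0}


@dataclass
class WeightedDistribution:
    """Weighted 10/50/90 percentiles of per-kg impacts."""

    q10: float
    q50: float
    q90: float

    def __post_init__(self) -> None:
        if not (self.q10 <= self.q50 <= self.q90):
            raise ValueError("quantiles must be ordered q10 <= q50 <= q90")


def weighted_quantile(values, weights, q: float) -> float:
    """Lower-value (type-1) weighted quantile, no interpolation.

    Returns the smallest value v whose cumulative weight reaches ``q`` of the
    total; with integer weights this equals the plain ``inverted_cdf``
    quantile of the weight-expanded sample. Zero-weight entries are ignored.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    w = np.asarray(weights, dtype=np.float64).ravel()
    if v.shape != w.shape:
        raise ValueError("values and weights must have the same length")
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"quantile q={q} outside [0, 1]")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    keep = w > 0
    if not keep.any():
        raise ValueError("need at least one value with positive weight")
    v, w = v[keep], w[keep]
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cw = np.cumsum(w)
    idx = int(np.searchsorted(cw, q * cw[-1], side="left"))
    return float(v[min(idx, len(v) - 1)])


def weighted_distribution(values, weights) -> WeightedDistribution:
    return WeightedDistribution(
        q10=weighted_quantile(values, weights, 0.10),
        q50=weighted_quantile(values, weights, 0.50),
        q90=weighted_quantile(values, weights, 0.90),
    )


def cell_perkg_impacts(
    life_density: RasterGrid, production: RasterGrid, harvested_area: RasterGrid
) -> RasterGrid:
    """Per-cell dE per kg: density × harvested area / production.

    Production is in tonnes/yr; the result is per kilogram. Cells with no
    production, or with nodata extinction density, are nodata in the result.
    """
    check_aligned(life_density, production, harvested_area)
    dens = life_density.values
    prod = production.values
    area = harvested_area.values
    if (prod[production.valid_mask] < 0).any() or (area[harvested_area.valid_mask] < 0).any():
        raise ValueError("production and harvested area must be non-negative")
    bad = (prod > 0) & (area <= 0)
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(f"cell ({r}, {c}) has production but zero harvested area")
    out = np.full(prod.shape, life_density.nodata)
    ok = (prod > 0) & life_density.valid_mask
    out[ok] = dens[ok] * area[ok] / (prod[ok] * 1000.0)
    return RasterGrid("perkg_impact", out, units="dE/kg", nodata=life_density.nodata)


def national_production_impact(
    commodity: str,
    country: str,
    country_index: np.ndarray,
    country_code: int,
    life_density: RasterGrid,
    production: RasterGrid,
    harvested_area: RasterGrid,
    cell_weighting: str = "production",
) -> ImpactValue | None:
    """Weighted median per-kg impact over a country's producing cells.

    Cell weights are production mass by default (``cell_weighting="area"``
    switches to harvested area). Returns None — "defined absent" — when the
    country produces none of the commodity; callers must not read that as a
    zero impact.
    """
    perkg = cell_perkg_impacts(life_density, production, harvested_area)
    mask = (country_index == country_code) & perkg.valid_mask
    if not mask.any():
        return None
    vals = perkg.values[mask]
    w = production.values[mask] if cell_weighting == "production" else harvested_area.values[mask]
    value = weighted_quantile(vals, w, 0.5)
    return ImpactValue(value=value, commodity=commodity, country=country, basis="production")


def global_commodity_distribution(values, production_masses) -> WeightedDistribution:
    """Production-mass-weighted 10/50/90 percentiles over national values.

    For a commodity group, pass the pooled constituent commodity × country
    values with their production masses as weights.
    """
    vals = [v.value if isinstance(v, ImpactValue) else float(v) for v in values]
    if len(vals) == 0:
        raise ValueError("no national impact values supplied")
    return weighted_distribution(vals, production_masses)


def protein_adjusted_impact(v: ImpactValue, protein_fraction: float) -> float:
    """Convert dE per kg of commodity mass into dE per kg of protein."""
    if protein_fraction <= 0:
        raise ValueError(
            f"{v.commodity}: protein fraction must be > 0 to express impact per protein"
        )
    return v.value / protein_fraction
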