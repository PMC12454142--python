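"""Extinction opportunity costs of animal products.

Animal products carry land — and therefore extinction risk — through two
pathways: grazing land (ruminants) and cropland growing feed (all livestock).
The per-kg impact of an animal product in a country is

    grazing density (dE km⁻²) × grazing requirement (km²·yr / kg)
  + Σ_feed  feed requirement (kg feed / kg product) × feed impact (dE / kg)

where the grazing density is the livestock-density-weighted median extinction
density over the country's pasture cells, and feed crops are valued at their
*consumption*-basis impacts in the producing country, so imported feed
(e.g. soy fed in Europe but grown in South America) carries its true origin
impacts.
"""

from __future__ import annotations

import numpy as np

from .grids import RasterGrid
from .spatial import ImpactValue, weighted_quantile


class MissingTableEntryError(KeyError):
    """A required feed/grazing table entry is absent."""


def grazing_life_density(
    life_density: RasterGrid,
    pasture_frac: RasterGrid,
    livestock_density: RasterGrid,
    country_index: np.ndarray,
    country_code: int,
    aggregation: str = "median",
) -> float | None:
    """Aggregate extinction density over a country's grazed pasture cells.

    Cell contributions are weighted by livestock density (Gridded-Livestock-
    of-the-World style). Returns None ("defined absent") when the country has
    no stocked pasture.
    """
    mask = (
        (country_index == country_code)
        & (pasture_frac.values > 0)
        & (livestock_density.values > 0)
        & life_density.valid_mask
    )
    if not mask.any():
        return None
    vals = life_density.values[mask]
    w = livestock_density.values[mask]
    if aggregation == "median":
        return weighted_quantile(vals, w, 0.5)
    if aggregation == "mean":
        return float(np.average(vals, weights=w))
    raise ValueError(f"unknown grazing aggregation {aggregation!r}")


def grazing_component(grazing_density: float, grazing_requirement: float) -> float:
    """dE per kg from grazing land: density × land-time per kg."""
    if grazing_requirement < 0:
        raise ValueError("grazing requirement must be >= 0")
    if grazing_requirement == 0:
        return 0.0  # monogastrics
    return grazing_density * grazing_requirement


def feed_component(
    feed_requirement: dict[str, float],
    feed_impacts: dict[str, ImpactValue],
) -> float:
    """dE per kg from feed: Σ requirement × consumption-basis feed impact."""
    total = 0.0
    for crop, req in feed_requirement.items():
        if req < 0:
            raise ValueError(f"feed requirement for {crop} must be >= 0")
        if req == 0:
            continue
        if crop not in feed_impacts:
            raise MissingTableEntryError(
                f"no consumption impact available for feed crop {crop!r}"
            )
        total += req * feed_impacts[crop].value
    return total


def animal_production_impact(
    commodity: str,
    country: str,
    grazing_density: float | None,
    grazing_requirement: float,
    feed_requirement: dict[str, float],
    feed_impacts: dict[str, ImpactValue],
) -> ImpactValue:
    """Total per-kg impact of an animal product with its decomposition."""
    if grazing_requirement > 0 and grazing_density is None:
        raise MissingTableEntryError(
            f"{commodity} in {country}: grazing requirement is positive but the "
            "country has no grazed pasture to aggregate over"
        )
    grazing = grazing_component(grazing_density or 0.0, grazing_requirement)
    feed = feed_component(feed_requirement, feed_impacts)
    return ImpactValue(
        value=grazing + feed,
        commodity=commodity,
        country=country,
        basis="production",
        components={"crop": 0.0, "grazing": grazing, "feed": feed},
    )
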