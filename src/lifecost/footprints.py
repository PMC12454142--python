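"""Per-capita consumption footprints and their decompositions.

A country's footprint is Σ_c (food supply, kg/person/yr) × (consumption-basis
impact, dE/kg), with sugar excluded by default: supply-chain data cannot
distinguish beet- from cane-derived sugar, so its consumption impact is
unreliable (the exclusion is a flag, not a deletion — production-side sugar
analyses are unaffected). Footprints are broken down by food group and by
origin (domestic vs imported), and an implied-land total supports the
marginality sanity check: the extinction metric is a marginal quantity whose
linear use is only trustworthy for land areas up to about 1,000 km², so any
aggregate implying more land raises a warning flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .spatial import ImpactValue

MARGINALITY_LIMIT_KM2 = 1000.0


@dataclass
class FootprintRecord:
    """Per-capita consumption footprint of one country (dE/person/yr)."""

    country: str
    total: float
    by_group: dict[str, float]
    by_origin: dict[str, float]  # keys: domestic, imported
    implied_land_km2: float | None = None

    def __post_init__(self) -> None:
        for label, parts in (("by_group", self.by_group), ("by_origin", self.by_origin)):
            s = sum(parts.values())
            if abs(s - self.total) > 1e-9 * max(abs(self.total), 1e-30):
                raise ValueError(f"{label} does not sum to total ({s} vs {self.total})")


def per_capita_footprint(
    country: str,
    food_per_capita: pd.Series,
    impacts: dict[str, ImpactValue],
    group_map: pd.Series,
    excluded: set[str] = frozenset(),
) -> FootprintRecord:
    """Assemble a country's per-capita footprint.

    Parameters
    ----------
    food_per_capita:
        kg/person/yr by commodity (FAO-style food supply; waste embedded).
    impacts:
        Consumption-basis impacts by commodity; required for every consumed,
        non-excluded commodity.
    group_map:
        Commodity → food group.
    excluded:
        Commodities excluded from the footprint (sugar by default upstream).
    """
    total = 0.0
    by_group: dict[str, float] = {}
    domestic = 0.0
    imported = 0.0
    for commodity, qty in food_per_capita.items():
        if qty <= 0 or commodity in excluded:
            continue
        if commodity not in impacts:
            raise KeyError(
                f"no consumption impact for consumed commodity {commodity!r} in {country!r}"
            )
        v = impacts[commodity]
        contrib = qty * v.value
        total += contrib
        group = str(group_map.get(commodity, "other"))
        by_group[group] = by_group.get(group, 0.0) + contrib
        if v.origin_shares is not None and v.origin_values is not None:
            for origin, share in v.origin_shares.items():
                part = qty * share * v.origin_values[origin]
                if origin == country:
                    domestic += part
                else:
                    imported += part
        else:
            domestic += contrib  # no provenance decomposition: treat as domestic
    # by_origin must sum to total; recompute total from parts to keep exactness
    return FootprintRecord(
        country=country,
        total=total,
        by_group=by_group,
        by_origin={"domestic": domestic, "imported": total - domestic},
    )


def import_domestic_split(record: FootprintRecord) -> tuple[float, float] | None:
    """(domestic share, imported share) of the footprint; None if total is 0."""
    if record.total <= 0:
        return None
    dom = record.by_origin["domestic"] / record.total
    imp = record.by_origin["imported"] / record.total
    return dom, imp


def implied_land_and_marginality(
    masses: pd.Series,
    land_per_kg: pd.Series,
) -> tuple[float, bool]:
    """Total land behind a consumption basket, and the marginality flag.

    ``masses`` is kg by commodity; ``land_per_kg`` is km²·yr per kg (for
    crops, harvested area / production; for animal products, grazing plus
    feed land). Commodities without a land coefficient are skipped with a
    warning. Returns (km², warn) with warn set when the total exceeds the
    ~1,000 km² marginal-validity envelope of the extinction layer.
    """
    import warnings

    total = 0.0
    for commodity, mass in masses.items():
        if mass <= 0:
            continue
        if commodity not in land_per_kg.index or pd.isna(land_per_kg[commodity]):
            warnings.warn(f"no land coefficient for {commodity!r}; skipped")
            continue
        total += float(mass) * float(land_per_kg[commodity])
    return total, total > MARGINALITY_LIMIT_KM2
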