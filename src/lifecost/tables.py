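"""Country × commodity supply, trade and feed/nutrition accounts.

The structures mirror FAO-style supply–utilisation accounts in
primary-equivalent mass: production, bilateral trade, feed use, per-capita
food supply and population, plus the feed-conversion, grazing-requirement and
nutrition tables needed to attribute land (and extinction risk) to animal
products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FOOD_GROUPS = (
    "fruit_veg",
    "legumes_nuts",
    "grains_roots",
    "dairy_eggs",
    "ruminant_meat",
    "poultry_pig",
    "sugar_other",
)


@dataclass
class CommodityDef:
    """Static commodity attributes: role, food group, nutrition and flags."""

    name: str
    role: str
    group: str
    is_animal: bool = False
    is_ruminant: bool = False
    is_sugar: bool = False
    is_stimulant_or_spice: bool = False
    energy_density: float = 0.0  # kcal per kg
    protein_fraction: float = 0.0  # g protein per g

    def __post_init__(self) -> None:
        if self.group not in FOOD_GROUPS:
            raise ValueError(f"commodity {self.name}: unknown food group {self.group!r}")
        if not 0 <= self.protein_fraction <= 1:
            raise ValueError(f"commodity {self.name}: protein fraction outside [0, 1]")


@dataclass
class SupplyTradeTables:
    """Balanced country-level supply and bilateral trade accounts.

    ``production``, ``feed_use`` and ``food_per_capita`` are
    country × commodity DataFrames (tonnes/yr, tonnes/yr and kg/person/yr).
    ``trade[c]`` is an origin × destination DataFrame of primary-equivalent
    flows (tonnes/yr) with a zero diagonal. ``conversion`` maps processed
    commodities onto primaries (columns: processed, primary, extraction_rate)
    and is empty for synthetic worlds, which trade primaries directly.

    Exact balance is enforced by the generator: for every country and
    commodity, production + imports − exports − feed = food (no stock
    residual), with food >= 0.
    """

    countries: list[str]
    commodities: list[str]
    production: pd.DataFrame
    trade: dict[str, pd.DataFrame]
    feed_use: pd.DataFrame
    food_per_capita: pd.DataFrame
    population: pd.Series
    conversion: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["processed", "primary", "extraction_rate"])
    )

    def imports(self, commodity: str) -> pd.Series:
        return self.trade[commodity].sum(axis=0)

    def exports(self, commodity: str) -> pd.Series:
        return self.trade[commodity].sum(axis=1)

    def domestic_use(self, commodity: str) -> pd.Series:
        """Production + imports − exports (tonnes/yr)."""
        return (
            self.production[commodity] + self.imports(commodity) - self.exports(commodity)
        )

    def food_total(self, commodity: str) -> pd.Series:
        """Food supply in tonnes/yr implied by per-capita supply and population."""
        return self.food_per_capita[commodity] * self.population / 1000.0

    def balance_residual(self) -> pd.DataFrame:
        """P + imports − exports − feed − food, per country × commodity (tonnes/yr).

        Zero (to rounding) on well-formed tables.
        """
        res = {}
        for c in self.commodities:
            res[c] = self.domestic_use(c) - self.feed_use[c] - self.food_total(c)
        return pd.DataFrame(res)[self.commodities]

    def validate(self, rtol: float = 1e-9) -> None:
        for c in self.commodities:
            t = self.trade[c]
            if (np.diag(t.values) != 0).any():
                raise ValueError(f"trade[{c}]: self-flows are forbidden")
            if (t.values < 0).any():
                raise ValueError(f"trade[{c}]: negative flows")
            supply = self.production[c] + self.imports(c)
            excess = self.exports(c) - supply
            if (excess > rtol * (supply + 1)).any():
                bad = excess[excess > rtol * (supply + 1)].index.tolist()
                raise ValueError(f"trade[{c}]: exports exceed supply for {bad}")
        for frame, label in ((self.production, "production"), (self.feed_use, "feed_use"),
                             (self.food_per_capita, "food_per_capita")):
            if (frame.values < 0).any():
                raise ValueError(f"{label}: negative masses")
        scale = float(self.production.values.max()) + 1.0
        resid = self.balance_residual().abs().values.max()
        if resid > rtol * scale:
            raise ValueError(f"supply balance violated: max residual {resid}")


@dataclass
class FeedNutritionTables:
    """Feed conversion, grazing requirements and nutrition facts.

    ``feed_requirement`` is a long DataFrame (country, animal, feed, value)
    in kg of feed crop per kg of animal product. ``grazing_requirement`` is a
    country × animal-commodity DataFrame in km²·yr per kg of product (zero for
    monogastrics). ``commodities`` carries the per-commodity nutrition facts
    and flags.
    """

    commodities: dict[str, CommodityDef]
    feed_requirement: pd.DataFrame
    grazing_requirement: pd.DataFrame

    def feed_row(self, country: str, animal: str) -> dict[str, float]:
        """Feed requirements {feed crop: kg/kg} for one animal product."""
        sel = self.feed_requirement
        sel = sel[(sel["country"] == country) & (sel["animal"] == animal)]
        return dict(zip(sel["feed"], sel["value"]))

    def grazing(self, country: str, animal: str) -> float:
        try:
            return float(self.grazing_requirement.loc[country, animal])
        except KeyError as exc:
            raise KeyError(
                f"grazing_requirement has no entry for country={country!r}, "
                f"animal={animal!r}"
            ) from exc

    @property
    def energy_density(self) -> pd.Series:
        return pd.Series({n: c.energy_density for n, c in self.commodities.items()})

    @property
    def protein_fraction(self) -> pd.Series:
        return pd.Series({n: c.protein_fraction for n, c in self.commodities.items()})

    @property
    def group_map(self) -> pd.Series:
        return pd.Series({n: c.group for n, c in self.commodities.items()})
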