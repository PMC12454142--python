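"""Marginal extinction-risk ("restore") layer from species ranges.

The model scores each grid cell by the change in the expected number of
extinctions, summed over species, that restoring the cell's agricultural land
to natural habitat would produce. For each species the probability of
extinction is tied to the fraction of its human-absent area of habitat (AOH)
that remains, through a power law

    p(A) = 1 - (A / A0) ** z

with ``A`` the current AOH, ``A0`` the pristine (human-absent) AOH and ``z``
a dimensionless exponent (default 0.25). Restoring ``dA`` km² of habitat for
a species changes its extinction probability by ``p(A) - p(A + dA)``; the
cell's score is the unweighted sum of these changes over every species whose
range covers the cell, divided by the restored area, giving an extinction
density in dE km⁻². All species count equally regardless of threat status,
so the layer scales with richness, endemism and habitat loss to date.

Sign convention per species and cell:

* natural cover suitable, agricultural cover not suitable — restoration adds
  habitat, positive contribution;
* both (or neither) suitable — no AOH change, zero contribution;
* agricultural cover suitable but natural cover not — restoration removes
  habitat, negative contribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import NODATA, RasterGrid

LAND_COVER_CLASSES = ("natural", "cropland", "pasture")


class SpeciesInvariantError(ValueError):
    """A species definition violates 0 < A <= A0."""


@dataclass
class SpeciesDef:
    """A species: range, habitat suitability and areas of habitat.

    ``range_mask`` is a boolean grid of the cells the species' range covers.
    ``suitability`` maps each land-cover class (natural, cropland, pasture)
    to whether the species can use it as habitat. ``pristine_aoh`` (A0) and
    ``current_aoh`` (A) are in km².
    """

    id: str
    range_mask: np.ndarray
    pristine_aoh: float
    suitability: dict[str, bool]
    current_aoh: float

    def __post_init__(self) -> None:
        self.range_mask = np.asarray(self.range_mask, dtype=bool)
        missing = [c for c in LAND_COVER_CLASSES if c not in self.suitability]
        if missing:
            raise ValueError(f"species {self.id}: missing suitability for {missing}")
        if not self.current_aoh > 0:
            raise SpeciesInvariantError(f"species {self.id}: current AOH must be > 0")
        if self.current_aoh > self.pristine_aoh * (1 + 1e-12):
            raise SpeciesInvariantError(
                f"species {self.id}: current AOH {self.current_aoh} exceeds "
                f"pristine AOH {self.pristine_aoh}"
            )


def extinction_probability(area: np.ndarray | float, pristine_area: float, z: float):
    """Power-law extinction probability p(A) = 1 - (A/A0)**z."""
    return 1.0 - (np.asarray(area, dtype=np.float64) / pristine_area) ** z


def life_restore_density(
    species: list[SpeciesDef],
    landcover: dict[str, np.ndarray],
    cell_area: float,
    z: float = 0.25,
) -> RasterGrid:
    """Compute the restore-layer extinction density (dE km⁻²).

    Parameters
    ----------
    species:
        Species definitions; each must satisfy 0 < A <= A0.
    landcover:
        Area-fraction layers ``{"natural": ..., "cropland": ..., "pasture": ...}``
        (fractions of each cell, summing to <= 1). ``cropland`` is the total
        over all crops.
    cell_area:
        km² per grid cell.
    z:
        Power-law exponent, > 0.

    Returns
    -------
    RasterGrid
        Per-cell dE per km² of restored (agricultural) land. Cells with no
        agricultural land score 0.
    """
    if z <= 0:
        raise ValueError("power-law exponent z must be > 0")
    crop = np.asarray(landcover["cropland"], dtype=np.float64)
    pasture = np.asarray(landcover["pasture"], dtype=np.float64)
    restored = (crop + pasture) * cell_area

    delta_e = np.zeros_like(restored)
    for sp in species:
        # re-validate: generated worlds guarantee this, hand-built inputs may not
        if sp.current_aoh > sp.pristine_aoh * (1 + 1e-12):
            raise SpeciesInvariantError(
                f"species {sp.id}: current AOH exceeds pristine AOH"
            )
        mask = sp.range_mask
        if mask.shape != restored.shape:
            raise ValueError(f"species {sp.id}: range mask shape {mask.shape} != grid")
        n_ok = sp.suitability["natural"]
        delta = np.zeros(int(mask.sum()), dtype=np.float64)
        for cover, frac in (("cropland", crop), ("pasture", pasture)):
            a_ok = sp.suitability[cover]
            if n_ok and not a_ok:
                delta += frac[mask] * cell_area  # habitat gained on restoration
            elif a_ok and not n_ok:
                delta -= frac[mask] * cell_area  # habitat lost on restoration
        if not np.any(delta):
            continue
        a, a0 = sp.current_aoh, sp.pristine_aoh
        # p(A) - p(A + dA) = ((A+dA)/A0)**z - (A/A0)**z
        delta_e[mask] += ((a + delta) / a0) ** z - (a / a0) ** z

    density = np.zeros_like(restored)
    has_ag = restored > 0
    density[has_ag] = delta_e[has_ag] / restored[has_ag]
    return RasterGrid("life_density", density, units="dE/km2")


def species_richness(species: list[SpeciesDef], shape: tuple[int, int]) -> np.ndarray:
    """Number of species ranges covering each cell."""
    richness = np.zeros(shape, dtype=np.int64)
    for sp in species:
        richness += sp.range_mask.astype(np.int64)
    return richness
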