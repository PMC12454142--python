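"""Equal-area gridded layers.

All spatial layers in this package live on an abstract equal-area grid:
``grid_rows × grid_cols`` cells of constant area (km² per cell). There is no
geographic CRS; readers for real projected rasters would handle area weighting
before data enters the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

NODATA: float = -9999.0


@dataclass
class RasterGrid:
    """A named single-band gridded layer.

    Parameters
    ----------
    name:
        Layer name (e.g. ``"life_density"`` or ``"production:grain_0"``).
    values:
        2-D float64 array, one value per cell. ``nodata`` marks cells outside
        the modelled domain.
    units:
        Free-text units tag (``"dE/km2"``, ``"t/yr"``, ``"head/km2"``,
        ``"country-id"``, ``"fraction"`` ...).
    """

    name: str
    values: np.ndarray
    units: str = ""
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"raster {self.name!r} must be 2-D, got {self.values.ndim}-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells carrying data."""
        return (self.values != self.nodata) & np.isfinite(self.values)

    def filled(self, fill: float = 0.0) -> np.ndarray:
        """Values with nodata cells replaced by ``fill``."""
        out = self.values.copy()
        out[~self.valid_mask] = fill
        return out

    def copy(self, name: str | None = None) -> "RasterGrid":
        return RasterGrid(name or self.name, self.values.copy(), self.units, self.nodata)


def check_aligned(*grids: RasterGrid) -> tuple[int, int]:
    """Raise if the given layers do not share a shape; return it."""
    shapes = {g.shape for g in grids}
    if len(shapes) != 1:
        names = ", ".join(f"{g.name}:{g.shape}" for g in grids)
        raise ValueError(f"layers are not aligned: {names}")
    return next(iter(shapes))
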