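"""Georeferenced grid and scene containers.

All rasters are plain ``numpy`` arrays with ``numpy.nan`` marking nodata
(integer rasters carry an explicit sentinel instead).  Grids are
edge-registered: the origin is the outer corner of the top-left cell, row 0
is the northernmost row and column 0 the westernmost column; reported cell
coordinates refer to cell centers.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

#: Canonical band order for 7-band surface-reflectance scenes.  This is the
#: MODIS band numbering: 1 red, 2 NIR1, 3 blue, 4 green, 5 NIR2, 6 SWIR1,
#: 7 SWIR2.
BAND_NAMES = ("red", "nir1", "blue", "green", "nir2", "swir1", "swir2")
BAND_INDEX = {name: i for i, name in enumerate(BAND_NAMES)}

#: Nominal valid surface-reflectance range after scaling.
REFLECTANCE_VALID_RANGE = (-0.01, 1.6)

#: Scale factor turning stored integer reflectance into unit reflectance.
REFLECTANCE_SCALE = 1e-4


@dataclass(frozen=True)
class GeoGrid:
    """A regular geographic grid with square cells (WGS84 by default)."""

    n_rows: int
    n_cols: int
    cell_size_deg: float
    origin_lon: float
    origin_lat: float
    crs_id: str = "EPSG:4326"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if not self.cell_size_deg > 0:
            raise ValueError("cell_size_deg must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        """West→east longitudes of cell centers."""
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size_deg

    def lat_centers(self) -> np.ndarray:
        """North→south latitudes of cell centers (row 0 is north)."""
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size_deg

    def bounds(self) -> tuple[float, float, float, float]:
        """(west, south, east, north) outer edges."""
        return (
            self.origin_lon,
            self.origin_lat - self.n_rows * self.cell_size_deg,
            self.origin_lon + self.n_cols * self.cell_size_deg,
            self.origin_lat,
        )

    def same_geometry(self, other: "GeoGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size_deg - other.cell_size_deg) <= tol
            and abs(self.origin_lon - other.origin_lon) <= tol
            and abs(self.origin_lat - other.origin_lat) <= tol
        )


def _check_grid(grid: GeoGrid, array: np.ndarray, name: str) -> None:
    if array.shape[-2:] != grid.shape:
        raise ValueError(
            f"{name} shape {array.shape[-2:]} does not match grid {grid.shape}"
        )


@dataclass
class ReflectanceScene:
    """Dated 7-band surface-reflectance raster (unit reflectance, nan nodata)."""

    grid: GeoGrid
    acq_date: _dt.date
    bands: np.ndarray  # float (7, n_rows, n_cols)

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.float64)
        if self.bands.ndim != 3 or self.bands.shape[0] != len(BAND_NAMES):
            raise ValueError("reflectance scene needs 7 band planes")
        _check_grid(self.grid, self.bands, "bands")
        lo, hi = REFLECTANCE_VALID_RANGE
        with np.errstate(invalid="ignore"):
            bad = (self.bands < lo) | (self.bands > hi)
        self.bands[bad] = np.nan

    def band(self, name: str) -> np.ndarray:
        return self.bands[BAND_INDEX[name]]


@dataclass
class ThermalScene:
    """Dated thermal raster of digital numbers; LST Kelvin = 0.02 * dn."""

    grid: GeoGrid
    acq_date: _dt.date
    dn: np.ndarray  # float plane, nan where fill

    def __post_init__(self) -> None:
        self.dn = np.asarray(self.dn, dtype=np.float64)
        _check_grid(self.grid, self.dn, "dn")
        with np.errstate(invalid="ignore"):
            if np.any(self.dn[np.isfinite(self.dn)] < 0):
                raise ValueError("digital numbers must be non-negative")


@dataclass
class QualityMask:
    """Per-pixel usability flags decoded from packed QA words."""

    grid: GeoGrid
    acq_date: _dt.date
    usable: np.ndarray  # bool
    words: np.ndarray | None = None  # raw integer QA words, if known

    def __post_init__(self) -> None:
        self.usable = np.asarray(self.usable, dtype=bool)
        _check_grid(self.grid, self.usable, "usable")


@dataclass
class AnnualComposite:
    """Seasonal (Sep–Mar) composite for one index year.

    ``index_year`` Y labels the September (Y−1) – March (Y) window.  A cell
    is valid only when at least one usable observation contributed to every
    required layer (all 7 reflectance bands share one QA draw; the thermal
    layer has its own).
    """

    index_year: int
    grid: GeoGrid
    bands: np.ndarray  # (7, rows, cols) unit reflectance
    lst_celsius: np.ndarray  # (rows, cols) degrees C
    valid_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands, dtype=np.float64)
        self.lst_celsius = np.asarray(self.lst_celsius, dtype=np.float64)
        _check_grid(self.grid, self.bands, "bands")
        _check_grid(self.grid, self.lst_celsius, "lst_celsius")
        if self.valid_mask is None:
            self.valid_mask = np.all(np.isfinite(self.bands), axis=0) & np.isfinite(
                self.lst_celsius
            )
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)

    def band(self, name: str) -> np.ndarray:
        return self.bands[BAND_INDEX[name]]
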