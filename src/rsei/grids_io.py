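"""GeoTIFF I/O, QA masking, nearest-neighbor resampling and seasonal compositing.

The on-disk dialect is plain tiled-or-strip GeoTIFF: geometry in
``ModelPixelScaleTag``/``ModelTiepointTag``, missing data in ``GDAL_NODATA``,
multiband rasters stored band-major.  Files written here round-trip through
``read_scene`` bit-exactly.
"""

from __future__ import annotations

import datetime as _dt
import re
import warnings
from collections.abc import Iterable, Sequence
from pathlib import Path

import numpy as np
import tifffile

from .grids import (
    BAND_NAMES,
    REFLECTANCE_SCALE,
    AnnualComposite,
    GeoGrid,
    QualityMask,
    ReflectanceScene,
    ThermalScene,
)

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113

# Minimal GeoKeyDirectory declaring geographic WGS84 (EPSG 4326).
_WGS84_GEOKEYS = (1, 1, 0, 3, 1024, 0, 1, 2, 1025, 0, 1, 1, 2048, 0, 1, 4326)

#: MOD09A1-style state-QA acceptance: cloud state (bits 0–1) must be clear
#: and the shadow bit (bit 2) unset.
DEFAULT_QA_BIT_SPEC: tuple[tuple[tuple[int, int], frozenset[int]], ...] = (
    ((0, 1), frozenset({0})),
    ((2, 2), frozenset({0})),
)

#: Synthetic scenes pack everything into a single cloud bit.
SINGLE_BIT_QA_SPEC: tuple[tuple[tuple[int, int], frozenset[int]], ...] = (
    ((0, 0), frozenset({0})),
)

_SEASON_START = (9, 1)  # Sep 1 of year Y-1
_SEASON_END = (3, 31)  # Mar 31 of year Y


# ---------------------------------------------------------------------------
# GeoTIFF read/write


def write_raster(
    path: str | Path,
    array: np.ndarray,
    grid: GeoGrid,
    *,
    nodata: float | int | None = None,
    dtype: np.dtype | str | None = None,
    acq_date: _dt.date | None = None,
) -> Path:
    """Write a 2-D or band-major 3-D array as a GeoTIFF on ``grid``.

    Float nan cells are replaced by ``nodata`` when one is given.
    """
    path = Path(path)
    data = np.asarray(array)
    if dtype is not None:
        data = data.astype(dtype)
    if np.issubdtype(data.dtype, np.floating) and nodata is not None:
        data = data.copy()
        data[np.isnan(data)] = nodata
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (grid.cell_size_deg, grid.cell_size_deg, 0.0), True),
        (
            _TAG_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, grid.origin_lon, grid.origin_lat, 0.0),
            True,
        ),
        (_TAG_GEO_KEYS, "H", len(_WGS84_GEOKEYS), _WGS84_GEOKEYS, True),
    ]
    if nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, repr(nodata), True))
    description = acq_date.isoformat() if acq_date is not None else ""
    tifffile.imwrite(
        path,
        data,
        extratags=extratags,
        metadata=None,
        description=description,
    )
    return path


def _parse_geotiff(path: str | Path) -> tuple[np.ndarray, GeoGrid, float | None, str]:
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        scale_tag = page.tags.get(_TAG_PIXEL_SCALE)
        tie_tag = page.tags.get(_TAG_TIEPOINT)
        if scale_tag is None or tie_tag is None:
            raise ValueError(f"{path}: missing GeoTIFF geometry tags")
        sx, sy = float(scale_tag.value[0]), float(scale_tag.value[1])
        if abs(sx - sy) > 1e-12:
            raise ValueError(f"{path}: cells are not square ({sx} x {sy})")
        tie = tie_tag.value
        # tiepoint maps raster (i, j) = (0, 0) to the top-left outer corner
        origin_lon = float(tie[3]) - float(tie[0]) * sx
        origin_lat = float(tie[4]) + float(tie[1]) * sy
        nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
        nodata = None
        if nodata_tag is not None:
            text = nodata_tag.value
            if isinstance(text, bytes):
                text = text.decode()
            text = text.strip().strip("\x00")
            if re.fullmatch(r"[-+0-9.eE]+", text):
                nodata = float(text)
        description = page.description or ""
        data = tf.asarray()
    if data.ndim == 2:
        n_rows, n_cols = data.shape
    else:
        n_rows, n_cols = data.shape[-2:]
    grid = GeoGrid(n_rows, n_cols, sx, origin_lon, origin_lat)
    return data, grid, nodata, description


def _scene_date(description: str, acq_date: _dt.date | None) -> _dt.date:
    if acq_date is not None:
        return acq_date
    text = description.strip().strip("\x00")
    if text:
        try:
            return _dt.date.fromisoformat(text[:10])
        except ValueError:
            pass
    raise ValueError("scene has no acquisition date (pass acq_date=...)")


def read_scene(
    path: str | Path,
    kind: str,
    *,
    acq_date: _dt.date | None = None,
    reflectance_scale: float | str = "auto",
    qa_bit_spec: Sequence[tuple[tuple[int, int], Iterable[int]]] | None = None,
) -> ReflectanceScene | ThermalScene | QualityMask:
    """Read a GeoTIFF as a reflectance, thermal or quality scene.

    Reflectance stored as scaled integers (MOD09A1 convention, x1e-4) is
    converted to unit reflectance when ``reflectance_scale`` is ``"auto"``
    (integer dtype triggers scaling) or an explicit factor.
    """
    data, grid, nodata, description = _parse_geotiff(path)
    date = _scene_date(description, acq_date)
    if kind == "reflectance":
        if data.ndim != 3 or data.shape[0] != len(BAND_NAMES):
            found = 1 if data.ndim == 2 else data.shape[0]
            raise ValueError(f"{path}: expected 7 bands, found {found}")
        bands = data.astype(np.float64)
        if nodata is not None:
            bands[data == nodata] = np.nan
        if reflectance_scale == "auto":
            scale = REFLECTANCE_SCALE if np.issubdtype(data.dtype, np.integer) else 1.0
        else:
            scale = float(reflectance_scale)
        bands *= scale
        return ReflectanceScene(grid, date, bands)
    if kind == "thermal":
        if data.ndim != 2:
            raise ValueError(f"{path}: thermal scene must be single-band")
        dn = data.astype(np.float64)
        if nodata is not None:
            dn[data == nodata] = np.nan
        return ThermalScene(grid, date, dn)
    if kind == "quality":
        if data.ndim != 2:
            raise ValueError(f"{path}: quality raster must be single-band")
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError(f"{path}: quality words must be integers")
        spec = qa_bit_spec if qa_bit_spec is not None else SINGLE_BIT_QA_SPEC
        usable = decode_qa_words(data, spec)
        if nodata is not None:
            usable &= data != nodata
        return QualityMask(grid, date, usable, words=data)
    raise ValueError(f"unknown scene kind {kind!r}")


# ---------------------------------------------------------------------------
# Quality masking


def decode_qa_words(
    words: np.ndarray,
    bit_spec: Sequence[tuple[tuple[int, int], Iterable[int]]],
) -> np.ndarray:
    """Evaluate packed QA words against a bit specification.

    ``bit_spec`` is a sequence of ``((lo_bit, hi_bit), accepted_values)``
    tests; a pixel is usable only if every extracted bit field is in its
    accepted set.
    """
    words = np.asarray(words)
    usable = np.ones(words.shape, dtype=bool)
    for (lo, hi), accepted in bit_spec:
        if hi < lo or lo < 0:
            raise ValueError(f"invalid bit range ({lo}, {hi})")
        width = hi - lo + 1
        extracted = (words >> lo) & ((1 << width) - 1)
        ok = np.zeros(words.shape, dtype=bool)
        for value in accepted:
            ok |= extracted == value
        usable &= ok
    return usable


def apply_quality_mask(
    scene: ReflectanceScene | ThermalScene,
    qa: np.ndarray | QualityMask,
    bit_spec: Sequence[tuple[tuple[int, int], Iterable[int]]] = DEFAULT_QA_BIT_SPEC,
) -> ReflectanceScene | ThermalScene:
    """Return a copy of ``scene`` with QA-rejected cells set to nodata.

    Retained cells pass through bit-exact.  ``qa`` is either a raster of
    integer quality words (decoded with ``bit_spec``) or an already decoded
    :class:`QualityMask`.
    """
    if isinstance(qa, QualityMask):
        if not qa.grid.same_geometry(scene.grid):
            raise ValueError("quality mask grid does not match scene grid")
        usable = qa.usable
    else:
        qa = np.asarray(qa)
        if qa.shape != scene.grid.shape:
            raise ValueError("quality raster shape does not match scene grid")
        usable = decode_qa_words(qa, bit_spec)
    if isinstance(scene, ReflectanceScene):
        bands = scene.bands.copy()
        bands[:, ~usable] = np.nan
        return ReflectanceScene(scene.grid, scene.acq_date, bands)
    dn = scene.dn.copy()
    dn[~usable] = np.nan
    return ThermalScene(scene.grid, scene.acq_date, dn)


# ---------------------------------------------------------------------------
# Resampling


def _nearest_indices(
    src_centers: np.ndarray, dst_centers: np.ndarray, tol: float = 1e-9
) -> np.ndarray:
    """Index of the nearest source center for each destination center.

    Exact distance ties resolve to the lower index, i.e. the northern row or
    western column.
    """
    dist = np.abs(src_centers[None, :] - dst_centers[:, None])
    dmin = dist.min(axis=1)
    tied = dist <= dmin[:, None] + tol
    return tied.argmax(axis=1)


def resample_nearest(
    src: np.ndarray, src_grid: GeoGrid, dst_grid: GeoGrid
) -> np.ndarray:
    """Nearest-neighbor resample of ``src`` onto ``dst_grid``.

    Each destination cell takes the value of the source cell whose center is
    nearest its own center (no interpolation, nodata propagates unchanged).
    """
    src = np.asarray(src)
    if src.shape[-2:] != src_grid.shape:
        raise ValueError("source array does not match source grid")
    sw, ss, se, sn = src_grid.bounds()
    dw, ds, de, dn_ = dst_grid.bounds()
    if dw >= se or de <= sw or ds >= sn or dn_ <= ss:
        raise ValueError("destination grid does not overlap source grid")
    rows = _nearest_indices(src_grid.lat_centers(), dst_grid.lat_centers())
    cols = _nearest_indices(src_grid.lon_centers(), dst_grid.lon_centers())
    return src[..., rows[:, None], cols[None, :]]


# ---------------------------------------------------------------------------
# Seasonal compositing


def season_window(index_year: int) -> tuple[_dt.date, _dt.date]:
    """Inclusive Sep 1 (Y−1) – Mar 31 (Y) window for index year Y."""
    return (
        _dt.date(index_year - 1, *_SEASON_START),
        _dt.date(index_year, *_SEASON_END),
    )


def _composite_stack(stack: np.ndarray, statistic: str) -> np.ndarray:
    if statistic not in ("median", "mean"):
        raise ValueError(f"unknown composite statistic {statistic!r}")
    with warnings.catch_warnings():
        # cells where every observation is masked legitimately reduce to nan
        warnings.simplefilter("ignore", category=RuntimeWarning)
        reducer = np.nanmedian if statistic == "median" else np.nanmean
        return reducer(stack, axis=0)


def seasonal_composite(
    reflectance_scenes: Sequence[ReflectanceScene],
    thermal_scenes: Sequence[ThermalScene],
    index_year: int,
    statistic: str = "median",
) -> AnnualComposite:
    """Composite masked scenes of one season into an :class:`AnnualComposite`.

    Per cell the composite is the chosen statistic over usable observations;
    cells with no usable observation in any required layer are nodata.  The
    thermal composite is taken on digital numbers and then converted to
    Celsius (the conversion is affine, so it commutes with both mean and
    median).
    """
    if not reflectance_scenes or not thermal_scenes:
        raise ValueError("at least one reflectance and one thermal scene required")
    start, end = season_window(index_year)
    grid = reflectance_scenes[0].grid
    for scene in list(reflectance_scenes) + list(thermal_scenes):
        if not scene.grid.same_geometry(grid):
            raise ValueError("all scenes must share the analysis grid")
        if not start <= scene.acq_date <= end:
            raise ValueError(
                f"scene dated {scene.acq_date} outside season {start}..{end}"
            )
    band_stack = np.stack([s.bands for s in reflectance_scenes])
    bands = _composite_stack(band_stack, statistic)
    dn_stack = np.stack([s.dn for s in thermal_scenes])
    dn = _composite_stack(dn_stack, statistic)
    lst_celsius = 0.02 * dn - 273.15
    valid = np.all(np.isfinite(bands), axis=0) & np.isfinite(lst_celsius)
    bands[:, ~valid] = np.nan
    lst_celsius[~valid] = np.nan
    return AnnualComposite(index_year, grid, bands, lst_celsius, valid)
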