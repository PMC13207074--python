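"""Synthetic MODIS-like scene series with known structure.

Generates reflectance/thermal/QA time series over a small land-cover mosaic
(urban, dense vegetation, agriculture, water, bare soil) with per-class
spectral signatures, additive Gaussian noise, linear temporal drifts, an
optional step change at a known year, and random cloud/shadow flagging — so
every downstream stage (masking, compositing, indicators, RSEI, trend and
change-point maps) can be tested against ground truth without the real
satellite archive.

Two generators are provided at different levels:

* :func:`render_series` renders full dated scene triplets (the pipeline's
  input), with the thermal series on a 2x-coarser grid to exercise
  nearest-neighbor resampling;
* :func:`render_index_cube` draws annual index-unit series directly
  (base + drift·t + step + noise per pixel), the natural scale for scoring
  trend and change-point recovery.

Everything is deterministic given the scenario seed.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np

from .grids import (
    BAND_INDEX,
    BAND_NAMES,
    GeoGrid,
    QualityMask,
    ReflectanceScene,
    ThermalScene,
)
from .grids_io import resample_nearest, season_window

CLASS_NAMES = ("urban", "dense_vegetation", "agriculture", "water", "bare_soil")
CLASS_CODES = {name: i for i, name in enumerate(CLASS_NAMES)}

#: Per-class mean surface reflectance (band order red, NIR1, blue, green,
#: NIR2, SWIR1, SWIR2) and mean LST in °C.  Values are plausible seasonal
#: means for a humid tropical coastal region; water has NIR1 < red so its
#: NDVI is negative.
SIGNATURES: dict[str, tuple[tuple[float, ...], float]] = {
    "urban": ((0.18, 0.22, 0.12, 0.15, 0.22, 0.28, 0.25), 34.0),
    "dense_vegetation": ((0.04, 0.45, 0.03, 0.07, 0.35, 0.15, 0.07), 26.0),
    "agriculture": ((0.08, 0.35, 0.05, 0.09, 0.30, 0.20, 0.12), 29.0),
    "water": ((0.03, 0.02, 0.04, 0.04, 0.02, 0.01, 0.01), 24.0),
    "bare_soil": ((0.22, 0.28, 0.12, 0.17, 0.30, 0.35, 0.30), 36.0),
}

_REFLECTANCE_CLIP = (0.0, 1.6)


@dataclass
class ChangeSpec:
    """A step change applied from ``change_year`` onward inside ``region``."""

    region: np.ndarray  # bool raster on the reflectance grid
    change_year: int
    band_steps: dict[str, float] = field(default_factory=dict)  # band -> step
    lst_step: float = 0.0


@dataclass
class SyntheticScenario:
    """Full description of a synthetic study area and its temporal structure."""

    grid: GeoGrid
    years: list[int]
    class_map: np.ndarray  # int codes into CLASS_NAMES
    signatures: dict[str, tuple[tuple[float, ...], float]]
    noise_sd: float = 0.01  # reflectance units, per band
    lst_noise_sd: float = 0.5  # °C
    trend_spec: dict[str, dict[str, float]] = field(default_factory=dict)
    change_spec: ChangeSpec | None = None
    cloud_fraction: float = 0.1
    seed: int = 0
    thermal_coarsening: int = 2  # thermal grid cell = this many reflectance cells

    def __post_init__(self) -> None:
        if not 0 <= self.cloud_fraction < 1:
            raise ValueError("cloud_fraction must be in [0, 1)")
        if self.change_spec is not None and (
            self.change_spec.change_year not in self.years
        ):
            raise ValueError("change_year must be one of the scenario years")
        self.class_map = np.asarray(self.class_map, dtype=np.int64)
        if self.class_map.shape != self.grid.shape:
            raise ValueError("class_map does not match grid")

    def thermal_grid(self) -> GeoGrid:
        k = self.thermal_coarsening
        return GeoGrid(
            n_rows=max(1, self.grid.n_rows // k),
            n_cols=max(1, self.grid.n_cols // k),
            cell_size_deg=self.grid.cell_size_deg * k,
            origin_lon=self.grid.origin_lon,
            origin_lat=self.grid.origin_lat,
        )


def _mmr_like_class_map(grid: GeoGrid) -> np.ndarray:
    """Deterministic land-cover mosaic loosely echoing a coastal metro region:
    dense vegetation north, agriculture center, urban core east, a coastal
    water strip on the far east edge and bare soil in the southwest."""
    rows, cols = grid.shape
    cmap = np.full(grid.shape, CLASS_CODES["agriculture"], dtype=np.int64)
    cmap[: rows // 3, :] = CLASS_CODES["dense_vegetation"]
    cmap[rows // 4 :, 2 * cols // 3 :] = CLASS_CODES["urban"]
    cmap[:, cols - max(1, cols // 24) :] = CLASS_CODES["water"]
    cmap[3 * rows // 4 :, : cols // 5] = CLASS_CODES["bare_soil"]
    return cmap


def make_scenario(preset: str = "mmr_like", seed: int = 0, **overrides) -> SyntheticScenario:
    """Build a named scenario; ``overrides`` replace any scenario field.

    The ``mmr_like`` preset spans 25 index years (2001–2025) on a 48x48 grid
    of 0.005° cells, with a greening drift on the agricultural belt and a
    degradation step (NIR down, SWIR and LST up) in a sub-region of the
    urban core from 2018 onward.
    """
    if preset != "mmr_like":
        raise ValueError(f"unknown preset {preset!r}")
    grid = overrides.pop("grid", GeoGrid(48, 48, 0.005, -36.0, -9.3))
    years = overrides.pop("years", list(range(2001, 2026)))
    class_map = overrides.pop("class_map", _mmr_like_class_map(grid))
    if "change_spec" in overrides:
        change_spec = overrides.pop("change_spec")
    else:
        region = np.zeros(grid.shape, dtype=bool)
        rows, cols = grid.shape
        region[rows // 4 : rows // 2, 2 * cols // 3 : cols - max(1, cols // 24)] = True
        change_year = 2018
        change_spec = (
            ChangeSpec(
                region=region,
                change_year=change_year,
                band_steps={"nir1": -0.08, "swir1": 0.05},
                lst_step=1.5,
            )
            if change_year in years
            else None
        )
    trend_spec = overrides.pop(
        "trend_spec", {"agriculture": {"nir1": 0.004, "lst": -0.05}}
    )
    scenario = SyntheticScenario(
        grid=grid,
        years=list(years),
        class_map=class_map,
        signatures=dict(SIGNATURES),
        trend_spec=trend_spec,
        change_spec=change_spec,
        seed=seed,
    )
    return replace(scenario, **overrides) if overrides else scenario


@dataclass
class SceneSeries:
    """Dated outputs of :func:`render_series`, ready for the pipeline."""

    reflectance: list[ReflectanceScene]
    thermal: list[ThermalScene]
    reflectance_qa: list[QualityMask]
    thermal_qa: list[QualityMask]


def _season_dates(index_year: int, scenes_per_season: int) -> list[_dt.date]:
    start, end = season_window(index_year)
    span = (end - start).days
    if scenes_per_season == 1:
        return [start + _dt.timedelta(days=span // 2)]
    step = span // (scenes_per_season - 1) if scenes_per_season > 1 else 0
    return [start + _dt.timedelta(days=i * step) for i in range(scenes_per_season)]


def _class_fields(
    scn: SyntheticScenario, year: int
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free reflectance (7, rows, cols) and LST °C field for one year."""
    t = year - scn.years[0]
    bands = np.empty((len(BAND_NAMES),) + scn.grid.shape)
    lst = np.empty(scn.grid.shape)
    for name, code in CLASS_CODES.items():
        mask = scn.class_map == code
        if not mask.any():
            continue
        sig_bands, sig_lst = scn.signatures[name]
        drift = scn.trend_spec.get(name, {})
        for b, bname in enumerate(BAND_NAMES):
            bands[b][mask] = sig_bands[b] + drift.get(bname, 0.0) * t
        lst[mask] = sig_lst + drift.get("lst", 0.0) * t
    cs = scn.change_spec
    if cs is not None and year >= cs.change_year:
        for bname, step in cs.band_steps.items():
            bands[BAND_INDEX[bname]][cs.region] += step
        lst[cs.region] += cs.lst_step
    return bands, lst


def render_series(scn: SyntheticScenario, scenes_per_season: int = 3) -> SceneSeries:
    """Render the dated scene triplets for every scenario year.

    Per date, each reflectance cell draws signature + drift + step + Gaussian
    noise (truncated to the physical reflectance range); LST fields are
    encoded to thermal digital numbers ND = round((LST°C + 273.15)/0.02) on
    the coarser thermal grid.  Cloud/shadow QA flags are drawn once per date
    on the reflectance grid (bit 0 set = unusable) and shared with the
    thermal series by nearest resampling, mimicking co-located cloudiness.
    """
    if scenes_per_season < 1:
        raise ValueError("scenes_per_season must be >= 1")
    rng = np.random.default_rng(scn.seed)
    tgrid = scn.thermal_grid()
    out = SceneSeries([], [], [], [])
    for year in scn.years:
        bands0, lst0 = _class_fields(scn, year)
        lst0_t = resample_nearest(lst0, scn.grid, tgrid)
        for date in _season_dates(year, scenes_per_season):
            bands = bands0 + rng.normal(0.0, scn.noise_sd, bands0.shape)
            np.clip(bands, *_REFLECTANCE_CLIP, out=bands)
            lst = lst0_t + rng.normal(0.0, scn.lst_noise_sd, tgrid.shape)
            dn = np.round((lst + 273.15) / 0.02)
            cloudy = rng.random(scn.grid.shape) < scn.cloud_fraction
            words = cloudy.astype(np.uint8)
            words_t = resample_nearest(words, scn.grid, tgrid)
            out.reflectance.append(ReflectanceScene(scn.grid, date, bands))
            out.thermal.append(ThermalScene(tgrid, date, dn))
            out.reflectance_qa.append(
                QualityMask(scn.grid, date, ~cloudy, words=words)
            )
            out.thermal_qa.append(
                QualityMask(tgrid, date, words_t == 0, words=words_t)
            )
    return out


def _ndvi_rate(sig_bands: tuple[float, ...], drift: dict[str, float]) -> float:
    """d/dt NDVI at the class signature under the band drifts."""
    n = sig_bands[BAND_INDEX["nir1"]]
    r = sig_bands[BAND_INDEX["red"]]
    dn_ = drift.get("nir1", 0.0)
    dr = drift.get("red", 0.0)
    denom = (n + r) ** 2
    if denom == 0:
        return 0.0
    return (2 * r * dn_ - 2 * n * dr) / denom


def truth_layers(scn: SyntheticScenario) -> dict[str, np.ndarray]:
    """Ground-truth rasters for recovery scoring.

    ``trend_sign`` is the sign of the ecological drift per class: the sign
    of the NDVI rate implied by the band drifts at the class signature, or,
    when that rate is zero, the opposite sign of the LST drift (warming is
    degradation).  ``change_year`` holds the step year inside the affected
    region (−1 elsewhere or when no change is configured) and
    ``change_region`` the affected-region mask.
    """
    trend_sign = np.zeros(scn.grid.shape, dtype=np.int8)
    for name, code in CLASS_CODES.items():
        drift = scn.trend_spec.get(name, {})
        rate = _ndvi_rate(scn.signatures[name][0], drift)
        if rate == 0.0:
            rate = -drift.get("lst", 0.0)
        trend_sign[scn.class_map == code] = int(np.sign(rate))
    change_year = np.full(scn.grid.shape, -1, dtype=np.int32)
    change_region = np.zeros(scn.grid.shape, dtype=bool)
    if scn.change_spec is not None:
        change_region = scn.change_spec.region.copy()
        change_year[change_region] = scn.change_spec.change_year
    return {
        "trend_sign": trend_sign,
        "change_year": change_year,
        "change_region": change_region,
    }


def render_index_cube(
    grid: GeoGrid,
    years: np.ndarray | list[int],
    *,
    base: float = 0.5,
    drift: np.ndarray | float = 0.0,
    step: np.ndarray | float = 0.0,
    change_year: int | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Draw an annual index cube directly in index units.

    Per pixel and year Y: value = base + drift·(Y − years[0]) +
    step·1[Y ≥ change_year] + N(0, noise_sd).  ``drift`` and ``step`` may be
    scalars or per-pixel rasters.  Returns the (n_years, rows, cols) cube
    and truth layers (``trend_sign``, ``change_year``, ``change_region``).
    """
    years = np.asarray(list(years))
    rng = np.random.default_rng(seed)
    drift = np.broadcast_to(np.asarray(drift, dtype=np.float64), grid.shape)
    step = np.broadcast_to(np.asarray(step, dtype=np.float64), grid.shape)
    t = (years - years[0]).astype(np.float64)
    cube = base + drift[None] * t[:, None, None]
    if change_year is not None:
        after = (years >= change_year).astype(np.float64)
        cube = cube + step[None] * after[:, None, None]
    cube = cube + rng.normal(0.0, noise_sd, (years.size,) + grid.shape)
    truth = {
        "trend_sign": np.sign(drift).astype(np.int8),
        "change_region": (step != 0) & (change_year is not None),
        "change_year": np.where(
            (step != 0) if change_year is not None else False, change_year or -1, -1
        ).astype(np.int32),
    }
    return cube, truth
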