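"""End-to-end orchestration: scenes → composites → indicators → RSEI →
trend and change-point maps → report tables.

The pipeline consumes either a synthetic scenario or a directory of dated
GeoTIFF scenes, produces per-year indicator/RSEI rasters plus summary CSV
tables, and writes a JSON manifest of every product.  All randomness flows
from the single configured seed, so two runs with the same config are
byte-identical.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import changepoint as _cp
from . import grids_io, indicators, rsei_core, synthetic, trends
from .grids import GeoGrid, QualityMask, ReflectanceScene, ThermalScene

logger = logging.getLogger(__name__)

_QA_SPECS = {
    "mod09a1": grids_io.DEFAULT_QA_BIT_SPEC,
    "single_bit": grids_io.SINGLE_BIT_QA_SPEC,
}

FLOAT_NODATA = -9999.0


@dataclass
class RunConfig:
    """Validated options for one pipeline run."""

    out_dir: str
    mode: str = "synthetic"  # synthetic | scenes
    preset: str = "mmr_like"
    scene_dir: str | None = None
    first_year: int = 2001
    last_year: int = 2025
    scenes_per_season: int = 3
    composite_statistic: str = "median"
    qa_bit_spec: str = "single_bit"
    rsein_normalization: str = "scene"  # scene | per_pixel
    slope_statistic: str = "median"
    min_years: int = 10
    z_thresholds: tuple[float, float, float] = trends.DEFAULT_Z_THRESHOLDS
    pettitt_alpha: float = 0.10
    seed: int = 0
    log_level: str = "INFO"
    scenario_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.last_year < self.first_year:
            raise ValueError("year range is empty")
        if self.mode not in ("synthetic", "scenes"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "scenes" and not self.scene_dir:
            raise ValueError("scene_dir required in scenes mode")
        if self.qa_bit_spec not in _QA_SPECS:
            raise ValueError(f"unknown qa_bit_spec {self.qa_bit_spec!r}")
        if self.rsein_normalization not in ("scene", "per_pixel"):
            raise ValueError("rsein_normalization must be 'scene' or 'per_pixel'")
        self.z_thresholds = tuple(float(v) for v in self.z_thresholds)

    @property
    def years(self) -> list[int]:
        return list(range(self.first_year, self.last_year + 1))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# scene acquisition


def _load_scene_dir(
    scene_dir: Path, qa_spec
) -> synthetic.SceneSeries:
    """Read a directory written by ``write_scene_series`` back into memory."""
    series = synthetic.SceneSeries([], [], [], [])
    for path in sorted(scene_dir.glob("refl_*.tif")):
        date = _dt.date.fromisoformat(path.stem.split("_", 1)[1])
        series.reflectance.append(grids_io.read_scene(path, "reflectance"))
        series.thermal.append(
            grids_io.read_scene(scene_dir / f"therm_{date}.tif", "thermal")
        )
        series.reflectance_qa.append(
            grids_io.read_scene(
                scene_dir / f"qa_{date}.tif", "quality", qa_bit_spec=qa_spec
            )
        )
        series.thermal_qa.append(
            grids_io.read_scene(
                scene_dir / f"thermqa_{date}.tif", "quality", qa_bit_spec=qa_spec
            )
        )
    if not series.reflectance:
        raise FileNotFoundError(f"no refl_*.tif scenes found in {scene_dir}")
    return series


def write_scene_series(series: synthetic.SceneSeries, out_dir: str | Path) -> Path:
    """Write a rendered scene series as the GeoTIFF layout the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for scene in series.reflectance:
        grids_io.write_raster(
            out / f"refl_{scene.acq_date}.tif",
            scene.bands,
            scene.grid,
            nodata=FLOAT_NODATA,
            dtype=np.float32,
            acq_date=scene.acq_date,
        )
    for tscene in series.thermal:
        grids_io.write_raster(
            out / f"therm_{tscene.acq_date}.tif",
            np.where(np.isfinite(tscene.dn), tscene.dn, 0).astype(np.uint16),
            tscene.grid,
            nodata=0,
            acq_date=tscene.acq_date,
        )
    for qa, prefix in [(q, "qa") for q in series.reflectance_qa] + [
        (q, "thermqa") for q in series.thermal_qa
    ]:
        words = qa.words if qa.words is not None else (~qa.usable).astype(np.uint8)
        grids_io.write_raster(
            out / f"{prefix}_{qa.acq_date}.tif",
            words.astype(np.uint8),
            qa.grid,
            acq_date=qa.acq_date,
        )
    return out


# ---------------------------------------------------------------------------
# per-year processing


def _year_composite(
    config: RunConfig,
    year: int,
    series: synthetic.SceneSeries,
    grid: GeoGrid,
    qa_spec,
):
    start, end = grids_io.season_window(year)

    def in_window(scene):
        return start <= scene.acq_date <= end

    refl = [s for s in series.reflectance if in_window(s)]
    therm = [s for s in series.thermal if in_window(s)]
    if not refl or not therm:
        raise FileNotFoundError(f"no scenes available for index year {year}")
    qa_by_date = {q.acq_date: q for q in series.reflectance_qa}
    tqa_by_date = {q.acq_date: q for q in series.thermal_qa}

    masked_refl = []
    for scene in refl:
        qa = qa_by_date.get(scene.acq_date)
        masked_refl.append(
            grids_io.apply_quality_mask(scene, qa, qa_spec) if qa else scene
        )
    masked_therm = []
    for tscene in therm:
        qa = tqa_by_date.get(tscene.acq_date)
        if qa is not None:
            tscene = grids_io.apply_quality_mask(tscene, qa, qa_spec)
        if not tscene.grid.same_geometry(grid):
            dn = grids_io.resample_nearest(tscene.dn, tscene.grid, grid)
            tscene = ThermalScene(grid, tscene.acq_date, dn)
        masked_therm.append(tscene)
    return grids_io.seasonal_composite(
        masked_refl, masked_therm, year, statistic=config.composite_statistic
    )


# ---------------------------------------------------------------------------
# full run


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured analysis and return the run manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    qa_spec = _QA_SPECS[config.qa_bit_spec]

    if config.mode == "synthetic":
        scenario = synthetic.make_scenario(
            config.preset,
            seed=config.seed,
            years=config.years,
            **config.scenario_overrides,
        )
        series = synthetic.render_series(scenario, config.scenes_per_season)
    else:
        series = _load_scene_dir(Path(config.scene_dir), qa_spec)
    grid = series.reflectance[0].grid

    # audit trail of the numerical conventions this run actually uses
    logger.info(
        "conventions: normalization=min-max difference form; slope=%s of "
        "pairwise slopes; MK variance=tie-corrected n(n-1)(2n+5)/18; "
        "z thresholds=%s; Pettitt p=2*exp(-6K^2/(T^3+T^2)) clamped to 1; "
        "rsein normalization=%s",
        config.slope_statistic,
        config.z_thresholds,
        config.rsein_normalization,
    )

    manifest: dict = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(config).items()
        },
        "grid": {
            "n_rows": grid.n_rows,
            "n_cols": grid.n_cols,
            "cell_size_deg": grid.cell_size_deg,
            "origin_lon": grid.origin_lon,
            "origin_lat": grid.origin_lat,
        },
        "years": config.years,
        "rasters": {},
        "tables": {},
    }

    stats_rows, pca_rows, class_rows = [], [], []
    rsei_layers: dict[int, rsei_core.RSEILayer] = {}
    for year in config.years:
        composite = _year_composite(config, year, series, grid, qa_spec)
        stack = indicators.compute_indicators(composite)
        rsei_core.normalize_stack(stack)
        layer = rsei_core.compute_rsei(stack)
        rsei_layers[year] = layer
        year_rasters = {}
        for name in indicators.IndicatorStack.ORDER:
            path = out_dir / f"{year}_{name}.tif"
            grids_io.write_raster(
                path, stack.raw(name), grid, nodata=FLOAT_NODATA, dtype=np.float32
            )
            year_rasters[name] = str(path)
        for label, data in [("rsein", layer.rsein), ("rsei0", layer.rsei0)]:
            path = out_dir / f"{year}_{label}.tif"
            grids_io.write_raster(
                path, data, grid, nodata=FLOAT_NODATA, dtype=np.float32
            )
            year_rasters[label] = str(path)
        path = out_dir / f"{year}_class.tif"
        grids_io.write_raster(path, layer.class_raster, grid, nodata=0)
        year_rasters["class"] = str(path)
        manifest["rasters"][str(year)] = year_rasters

        st = rsei_core.annual_stats(layer.rsein, year)
        stats_rows.append(vars(st))
        pca_rows.append(
            {
                "year": year,
                **{
                    f"loading_{n}": layer.pca.loadings[i]
                    for i, n in enumerate(indicators.IndicatorStack.ORDER)
                },
                **{
                    f"explained_pc{i + 1}": layer.pca.explained_fraction[i]
                    for i in range(4)
                },
            }
        )
        counts = np.bincount(layer.class_raster.ravel(), minlength=6)
        n_valid = counts[1:].sum()
        class_rows.append(
            {
                "year": year,
                **{
                    name: 100.0 * counts[i + 1] / n_valid if n_valid else 0.0
                    for i, name in enumerate(rsei_core.CLASS_NAMES)
                },
            }
        )

    _write_csv(pd.DataFrame(stats_rows), out_dir / "annual_stats.csv", manifest)
    _write_csv(pd.DataFrame(pca_rows), out_dir / "pca_summary.csv", manifest)
    _write_csv(pd.DataFrame(class_rows), out_dir / "class_areas.csv", manifest)

    years = np.array(config.years)
    cube = np.stack([rsei_layers[y].rsein for y in config.years])
    if config.rsein_normalization == "per_pixel":
        cube = _per_pixel_normalize(
            np.stack([rsei_layers[y].rsei0 for y in config.years])
        )

    if len(config.years) < 2:
        logger.warning(
            "year range has %d year(s); trend and change-point stages skipped",
            len(config.years),
        )
    else:
        trend = trends.trend_map(
            cube,
            years,
            grid,
            min_years=min(config.min_years, len(config.years)),
            z_thresholds=config.z_thresholds,
            slope_statistic=config.slope_statistic,
        )
        for label, data, nodata in [
            ("trend_beta", trend.beta, FLOAT_NODATA),
            ("trend_s", trend.s, FLOAT_NODATA),
            ("trend_z", trend.z, FLOAT_NODATA),
        ]:
            path = out_dir / f"{label}.tif"
            grids_io.write_raster(path, data, grid, nodata=nodata, dtype=np.float32)
            manifest["rasters"][label] = str(path)
        path = out_dir / "trend_sig_class.tif"
        grids_io.write_raster(
            path, trend.sig_class, grid, nodata=int(trends.TrendLayer.NODATA_CLASS)
        )
        manifest["rasters"]["trend_sig_class"] = str(path)
        trend_rows = []
        tested = trend.sig_class != trends.TrendLayer.NODATA_CLASS
        for code, label in sorted(trends.SIG_CLASS_LABELS.items()):
            count = int(np.sum(trend.sig_class[tested] == code))
            trend_rows.append(
                {
                    "class": label,
                    "cells": count,
                    "percent": 100.0 * count / tested.sum() if tested.any() else 0.0,
                }
            )
        _write_csv(pd.DataFrame(trend_rows), out_dir / "trend_classes.csv", manifest)

        cp = _cp.changepoint_map(
            cube,
            years,
            grid,
            min_years=min(config.min_years, len(config.years)),
            alpha=config.pettitt_alpha,
        )
        for label, data, nodata in [
            ("pettitt_k", cp.k_stat, FLOAT_NODATA),
            ("pettitt_p", cp.p_approx, FLOAT_NODATA),
        ]:
            path = out_dir / f"{label}.tif"
            grids_io.write_raster(path, data, grid, nodata=nodata, dtype=np.float32)
            manifest["rasters"][label] = str(path)
        path = out_dir / "pettitt_tau.tif"
        grids_io.write_raster(
            path, cp.tau_year_masked(), grid, nodata=int(_cp.YEAR_NODATA)
        )
        manifest["rasters"]["pettitt_tau"] = str(path)
        tau = cp.tau_year_masked()
        hist_rows = [
            {"change_year": int(y), "cells": int(np.sum(tau == y))}
            for y in years
        ]
        _write_csv(
            pd.DataFrame(hist_rows), out_dir / "change_year_histogram.csv", manifest
        )

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    manifest["manifest_path"] = str(manifest_path)
    return manifest


def _per_pixel_normalize(cube: np.ndarray) -> np.ndarray:
    """Alternative temporal normalization: min-max per pixel across years."""
    with np.errstate(all="ignore"):
        lo = np.nanmin(cube, axis=0)
        hi = np.nanmax(cube, axis=0)
        out = (cube - lo[None]) / (hi - lo)[None]
    out[:, hi == lo] = np.nan
    return out


def _write_csv(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, index=False, float_format="%.6f")
    manifest["tables"][path.stem] = str(path)


# ---------------------------------------------------------------------------
# reporting


def summarize_report(manifest: dict | str | Path) -> str:
    """Plain-text digest of a finished run: annual index extremes, quality
    class areas, trend classes and the modal change year."""
    if not isinstance(manifest, dict):
        with open(manifest) as fh:
            manifest = json.load(fh)
    tables = manifest["tables"]
    lines = ["RSEI run summary", "================"]

    stats = pd.read_csv(tables["annual_stats"])
    imin = stats.loc[stats["mean"].idxmin()]
    imax = stats.loc[stats["mean"].idxmax()]
    lines.append(
        f"Annual mean RSEI: lowest {imin['mean']:.4f} in {int(imin['year'])}, "
        f"highest {imax['mean']:.4f} in {int(imax['year'])}"
    )

    classes = pd.read_csv(tables["class_areas"])
    last = classes.iloc[-1]
    lines.append(f"Quality class areas in {int(last['year'])} (% of valid cells):")
    for name in rsei_core.CLASS_NAMES:
        lines.append(f"  {name:<9} {last[name]:6.2f}%")

    if "trend_classes" in tables:
        trend = pd.read_csv(tables["trend_classes"])
        lines.append("Trend classes (% of tested cells):")
        for _, row in trend.iterrows():
            lines.append(f"  {row['class']:<6} {row['percent']:6.2f}%")

    if "change_year_histogram" in tables:
        hist = pd.read_csv(tables["change_year_histogram"])
        if hist["cells"].sum() > 0:
            modal = hist.loc[hist["cells"].idxmax()]
            lines.append(
                f"Modal significant change year: {int(modal['change_year'])} "
                f"({int(modal['cells'])} cells)"
            )
        else:
            lines.append("No significant change points detected.")
    return "\n".join(lines) + "\n"
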