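"""RSEI construction: min-max normalization, PC1 extraction, orientation,
five-class quality mapping and annual descriptive statistics.

The index is the first principal component of the four min-max-normalized
indicators (Dryness, Greenness, Heat, Wetness), computed per year on the
covariance matrix of the normalized variables with pixels as observations —
the original RSEI recipe.  PC1 is oriented so that larger values mean better
ecological condition (Greenness/Wetness loading positively), then rescaled
to [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grids import GeoGrid
from .indicators import IndicatorStack

logger = logging.getLogger(__name__)

#: quality classes, byte codes 1–5 (0 = nodata in rasters on disk)
CLASS_NAMES = ("Poor", "Fair", "Moderate", "Good", "Excellent")
CLASS_EDGES = (0.2, 0.4, 0.6, 0.8)  # half-open, upper class owns boundary


@dataclass
class PCAResult:
    """Loadings, explained-variance fractions and PC1 scores of the 4x4 PCA."""

    loadings: np.ndarray  # (4,) unit vector, indicator order D, G, H, W
    explained_fraction: np.ndarray  # (4,) sums to 1
    pc1: np.ndarray  # raster of scores, nan outside valid mask


@dataclass
class RSEILayer:
    """Per-year RSEI products: oriented PC1, normalized index, classes, PCA."""

    index_year: int
    grid: GeoGrid
    rsei0: np.ndarray
    rsein: np.ndarray
    class_raster: np.ndarray  # uint8, 1..5, 0 = nodata
    pca: PCAResult
    valid_mask: np.ndarray


@dataclass
class AnnualStats:
    """Table-3-style descriptive statistics of one year's index raster."""

    year: int
    min: float
    q1: float
    mean: float
    median: float
    q3: float
    max: float
    sd: float
    cv: float  # percent, 100*sd/mean


class DegenerateInputError(ValueError):
    """Raised when normalization or PCA input carries no usable variation."""


def normalize_indicator(
    raster: np.ndarray, valid_mask: np.ndarray | None = None
) -> np.ndarray:
    """Min-max rescale a raster to [0, 1] over its valid cells.

    The minimum and maximum are taken over valid cells of this raster only,
    so the output attains both 0 and 1.  A constant raster has no scale and
    raises :class:`DegenerateInputError`.
    """
    raster = np.asarray(raster, dtype=np.float64)
    if valid_mask is None:
        valid_mask = np.isfinite(raster)
    valid_mask = np.asarray(valid_mask, dtype=bool) & np.isfinite(raster)
    values = raster[valid_mask]
    if values.size < 2:
        raise DegenerateInputError("need at least 2 valid cells to normalize")
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise DegenerateInputError("constant raster cannot be min-max normalized")
    out = np.full(raster.shape, np.nan)
    out[valid_mask] = (raster[valid_mask] - lo) / (hi - lo)
    return out


def normalize_stack(stack: IndicatorStack) -> IndicatorStack:
    """Fill the normalized counterparts of all four indicators in place."""
    for name in IndicatorStack.ORDER:
        setattr(
            stack, f"{name}_n", normalize_indicator(stack.raw(name), stack.valid_mask)
        )
    return stack


def _pca_first_component(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Covariance-matrix PCA of observation matrix ``x`` (n_obs, 4).

    Returns (loadings of PC1, explained fractions of all 4 components,
    centered scores on PC1).  The eigen-solver sign is made deterministic by
    forcing the largest-magnitude loading positive.
    """
    mean = x.mean(axis=0)
    centered = x - mean
    cov = (centered.T @ centered) / (x.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    total = eigvals.sum()
    if total <= 0:
        raise DegenerateInputError("indicators have zero total variance")
    loadings = eigvecs[:, 0]
    if loadings[np.argmax(np.abs(loadings))] < 0:
        loadings = -loadings
    scores = centered @ loadings
    return loadings, eigvals / total, scores


def compute_rsei(stack: IndicatorStack, min_valid_cells: int = 5) -> RSEILayer:
    """Build the per-year RSEI layer from a normalized indicator stack.

    PC1 is extracted from the covariance of the normalized indicators over
    valid cells.  Orientation: when the Greenness and Wetness loadings are
    both negative (ecology-positive indicators pointing down the axis) the
    component is reflected, RSEI0 = 1 − PC1; when they disagree in sign the
    Greenness loading decides and a warning is logged.  RSEI0 is then
    min-max rescaled to RSEIn in [0, 1] over the year's valid cells and
    classified into the five quality classes.
    """
    if stack.greenness_n is None:
        normalize_stack(stack)
    valid = stack.valid_mask
    n_valid = int(valid.sum())
    if n_valid < min_valid_cells:
        raise DegenerateInputError(
            f"only {n_valid} valid cells; need >= {min_valid_cells}"
        )
    x = np.column_stack([stack.normalized(name)[valid] for name in IndicatorStack.ORDER])
    loadings, explained, scores = _pca_first_component(x)

    g_load = loadings[IndicatorStack.ORDER.index("greenness")]
    w_load = loadings[IndicatorStack.ORDER.index("wetness")]
    if g_load < 0 and w_load < 0:
        flip = True
    elif g_load >= 0 and w_load >= 0:
        flip = False
    else:
        flip = g_load < 0
        logger.warning(
            "Greenness (%.3f) and Wetness (%.3f) PC1 loadings disagree in sign; "
            "orientation follows Greenness",
            g_load,
            w_load,
        )

    rsei0 = np.full(stack.grid.shape, np.nan)
    rsei0[valid] = 1.0 - scores if flip else scores
    rsein = normalize_indicator(rsei0, valid)
    pca = PCAResult(loadings=loadings, explained_fraction=explained, pc1=rsei0)
    return RSEILayer(
        index_year=stack.index_year,
        grid=stack.grid,
        rsei0=rsei0,
        rsein=rsein,
        class_raster=classify_rsei(rsein),
        pca=pca,
        valid_mask=valid,
    )


def classify_rsei(rsein: np.ndarray) -> np.ndarray:
    """Map a [0, 1] index raster to byte-coded quality classes 1–5.

    Poor [0, 0.2), Fair [0.2, 0.4), Moderate [0.4, 0.6), Good [0.6, 0.8),
    Excellent [0.8, 1.0] — boundaries owned by the upper class, the top
    interval closed.  Nodata cells code 0.  Out-of-range values are an error.
    """
    rsein = np.asarray(rsein, dtype=np.float64)
    valid = np.isfinite(rsein)
    vals = rsein[valid]
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ValueError("classify_rsei input must lie in [0, 1]")
    codes = np.zeros(rsein.shape, dtype=np.uint8)
    codes[valid] = np.digitize(vals, CLASS_EDGES, right=False) + 1
    return codes


def annual_stats(rsein: np.ndarray, year: int) -> AnnualStats:
    """Min, quartiles, mean, median, max, SD (n−1) and CV (%) of valid cells."""
    values = np.asarray(rsein, dtype=np.float64)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise DegenerateInputError("need at least 2 valid cells for annual stats")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])  # linear interpolation
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else float("nan")
    return AnnualStats(
        year=year,
        min=float(values.min()),
        q1=float(q1),
        mean=mean,
        median=float(med),
        q3=float(q3),
        max=float(values.max()),
        sd=sd,
        cv=float(cv),
    )
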