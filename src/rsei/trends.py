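"""Per-pixel Theil-Sen slope and Mann–Kendall trend significance.

The slope is the median of all pairwise slopes (the Theil-Sen estimator);
the Mann–Kendall S statistic counts concordant minus discordant pairs, its
variance carries the standard tie correction, and the Z statistic is
continuity-corrected.  Significance classes follow a two-tailed comparison
of |Z| against the normal critical values 1.645 / 1.96 / 2.574 (90 / 95 /
99% confidence), with the sign of Z giving the direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GeoGrid

#: |Z| thresholds for the 90%, 95% and 99% confidence classes.  The 99%
#: value defaults to 2.574, a rounding common in applied trend mapping
#: (standard normal tables give 2.576); override via ``z_thresholds``.
DEFAULT_Z_THRESHOLDS = (1.645, 1.96, 2.574)

#: signed significance codes: 0 none, ±1 90%, ±2 95%, ±3 99%
SIG_CLASS_LABELS = {
    -3: "dec99",
    -2: "dec95",
    -1: "dec90",
    0: "none",
    1: "inc90",
    2: "inc95",
    3: "inc99",
}

#: minimum valid years per pixel before the tests are attempted
DEFAULT_MIN_YEARS = 10


@dataclass
class TrendLayer:
    """Per-pixel trend products over a multi-year index cube."""

    grid: GeoGrid
    years: np.ndarray
    beta: np.ndarray  # index units / year, nan nodata
    s: np.ndarray  # float raster of integers, nan nodata
    var_s: np.ndarray
    z: np.ndarray
    sig_class: np.ndarray  # int8, codes as SIG_CLASS_LABELS, -128 nodata

    NODATA_CLASS = np.int8(-128)


def _clean_series(
    years: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    years = np.asarray(years, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if years.shape != values.shape:
        raise ValueError("years and values must have equal length")
    if np.any(np.diff(years) <= 0):
        raise ValueError("years must be strictly increasing")
    keep = np.isfinite(values)
    return years[keep], values[keep]


def sen_slope(
    years: np.ndarray, values: np.ndarray, statistic: str = "median"
) -> float:
    """Theil-Sen slope: median of (x_j − x_i)/(t_j − t_i) over all pairs i < j.

    Missing values are skipped.  ``statistic="mean"`` averages the pairwise
    slopes instead (the literal printed variant), for comparison only.
    """
    t, x = _clean_series(years, values)
    n = t.size
    if n < 2:
        raise ValueError("need at least 2 non-missing values for a slope")
    iu, ju = np.triu_indices(n, k=1)
    slopes = (x[ju] - x[iu]) / (t[ju] - t[iu])
    if statistic == "median":
        return float(np.median(slopes))
    if statistic == "mean":
        return float(np.mean(slopes))
    raise ValueError(f"unknown slope statistic {statistic!r}")


def mk_variance(values: np.ndarray) -> float:
    """Tie-corrected Mann–Kendall variance of S for a series of n values."""
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    _, counts = np.unique(values, return_counts=True)
    ties = counts[counts > 1]
    correction = np.sum(ties * (ties - 1) * (2 * ties + 5))
    return (n * (n - 1) * (2 * n + 5) - correction) / 18.0


def mann_kendall(
    years: np.ndarray,
    values: np.ndarray,
    min_n: int = 4,
    z_thresholds: tuple[float, float, float] = DEFAULT_Z_THRESHOLDS,
) -> tuple[float, float, float, int]:
    """Mann–Kendall test on one series: returns (S, Var(S), Z, class code).

    S sums sign(x_j − x_i) over pairs i < j; Z applies the continuity
    correction (S−1 or S+1) and is 0 when S is 0.  The class code is signed:
    0 none, ±1/±2/±3 for the 90/95/99% confidence levels, positive for
    increasing trends.
    """
    t, x = _clean_series(years, values)
    n = x.size
    if n < min_n:
        raise ValueError(f"need at least {min_n} non-missing values")
    iu, ju = np.triu_indices(n, k=1)
    s = float(np.sum(np.sign(x[ju] - x[iu])))
    var_s = mk_variance(x)
    if s > 0:
        z = (s - 1.0) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1.0) / np.sqrt(var_s)
    else:
        z = 0.0
    code = int(np.searchsorted(z_thresholds, abs(z), side="right"))
    return s, var_s, float(z), code * (1 if z > 0 else -1 if z < 0 else 0)


def trend_map(
    cube: np.ndarray,
    years: np.ndarray,
    grid: GeoGrid,
    min_years: int = DEFAULT_MIN_YEARS,
    z_thresholds: tuple[float, float, float] = DEFAULT_Z_THRESHOLDS,
    slope_statistic: str = "median",
) -> TrendLayer:
    """Apply Sen slope and Mann–Kendall independently at every pixel.

    ``cube`` has shape (n_years, rows, cols); missing years at a pixel are
    skipped, not imputed, and pixels with fewer than ``min_years`` valid
    observations are nodata throughout.
    """
    cube = np.asarray(cube, dtype=np.float64)
    years = np.asarray(years)
    if cube.ndim != 3 or cube.shape[0] != years.size:
        raise ValueError("cube must be (n_years, rows, cols) matching years")
    if cube.shape[0] == 0:
        raise ValueError("empty cube")
    shape = cube.shape[1:]
    beta = np.full(shape, np.nan)
    s = np.full(shape, np.nan)
    var_s = np.full(shape, np.nan)
    z = np.full(shape, np.nan)
    sig = np.full(shape, TrendLayer.NODATA_CLASS, dtype=np.int8)
    counts = np.isfinite(cube).sum(axis=0)
    for r, c in zip(*np.nonzero(counts >= max(min_years, 2))):
        series = cube[:, r, c]
        beta[r, c] = sen_slope(years, series, statistic=slope_statistic)
        s_, v_, z_, code = mann_kendall(
            years, series, min_n=min_years, z_thresholds=z_thresholds
        )
        s[r, c] = s_
        var_s[r, c] = v_
        z[r, c] = z_
        sig[r, c] = code
    return TrendLayer(
        grid=grid, years=years, beta=beta, s=s, var_s=var_s, z=z, sig_class=sig
    )
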