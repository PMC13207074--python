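"""Per-pixel Pettitt single change-point detection.

The Pettitt test is a rank-based variant of the Mann–Whitney test: for each
split point t it accumulates U_t,T = sum over i <= t < j of sign(x_j − x_i);
the most probable break is the t maximizing |U_t,T|, with the approximate
two-sided significance p = 2·exp(−6K²/(T³ + T²)) clamped to 1.  The break is
reported as the label of the last year of the first segment; ties in the
argmax resolve to the earliest year.

Missing years at a pixel are compressed out before testing, so the rank
statistic treats the surviving observations as equally spaced (unequal
spacing is ignored, as for any rank-based test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import GeoGrid

DEFAULT_MIN_YEARS = 10
DEFAULT_ALPHA = 0.10

YEAR_NODATA = np.int32(-1)


@dataclass
class ChangePointLayer:
    """Per-pixel Pettitt products over a multi-year index cube."""

    grid: GeoGrid
    years: np.ndarray
    k_stat: np.ndarray  # max |U|, nan nodata
    tau_year: np.ndarray  # int32 year labels, -1 nodata
    p_approx: np.ndarray  # (0, 1], nan nodata
    significant: np.ndarray  # bool, p < alpha
    alpha: float = DEFAULT_ALPHA

    def tau_year_masked(self) -> np.ndarray:
        """Change-year raster with non-significant pixels set to nodata."""
        out = self.tau_year.copy()
        out[~self.significant] = YEAR_NODATA
        return out


def pettitt_u(values: np.ndarray) -> np.ndarray:
    """The U_t,T sequence for t = 1..T−1 via the recursive relation.

    U_t,T = U_{t−1,T} + V_t,T with V_t,T = sum_j sign(x_j − x_t); this equals
    the direct cross-segment double sum sum_{i<=t, j>t} sign(x_j − x_i).
    """
    x = np.asarray(values, dtype=np.float64)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    signs = np.sign(x[None, :] - x[:, None])  # signs[t, j] = sign(x_j - x_t)
    v = signs.sum(axis=1)
    return np.cumsum(v)[:-1]


def pettitt(
    years: np.ndarray, values: np.ndarray, min_n: int = 4
) -> tuple[np.ndarray, float, int, float]:
    """Pettitt test on one series: (U sequence, K, tau year label, approx p).

    ``tau`` is the year label of the last observation of the first segment.
    """
    years = np.asarray(years)
    values = np.asarray(values, dtype=np.float64)
    if years.shape != values.shape:
        raise ValueError("years and values must have equal length")
    keep = np.isfinite(values)
    t_years, x = years[keep], values[keep]
    n = x.size
    if n < min_n:
        raise ValueError(f"need at least {min_n} non-missing values")
    u = pettitt_u(x)
    k = float(np.max(np.abs(u)))
    tau_index = int(np.argmax(np.abs(u)))  # earliest on ties
    p = min(1.0, 2.0 * np.exp(-6.0 * k * k / (n**3 + n**2)))
    return u, k, int(t_years[tau_index]), p


def changepoint_map(
    cube: np.ndarray,
    years: np.ndarray,
    grid: GeoGrid,
    min_years: int = DEFAULT_MIN_YEARS,
    alpha: float = DEFAULT_ALPHA,
) -> ChangePointLayer:
    """Apply the Pettitt test independently at every pixel of an index cube."""
    cube = np.asarray(cube, dtype=np.float64)
    years = np.asarray(years)
    if cube.ndim != 3 or cube.shape[0] != years.size:
        raise ValueError("cube must be (n_years, rows, cols) matching years")
    if cube.shape[0] == 0:
        raise ValueError("empty cube")
    shape = cube.shape[1:]
    k_stat = np.full(shape, np.nan)
    tau_year = np.full(shape, YEAR_NODATA, dtype=np.int32)
    p_approx = np.full(shape, np.nan)
    counts = np.isfinite(cube).sum(axis=0)
    for r, c in zip(*np.nonzero(counts >= max(min_years, 2))):
        _, k, tau, p = pettitt(years, cube[:, r, c], min_n=min_years)
        k_stat[r, c] = k
        tau_year[r, c] = tau
        p_approx[r, c] = p
    with np.errstate(invalid="ignore"):
        significant = p_approx < alpha
    return ChangePointLayer(
        grid=grid,
        years=years,
        k_stat=k_stat,
        tau_year=tau_year,
        p_approx=p_approx,
        significant=significant,
        alpha=alpha,
    )
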