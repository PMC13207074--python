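"""The four ecological indicator rasters: Dryness, Greenness, Heat, Wetness.

Dryness is the NDBSI, the mean of the index-based built-up index (IBI) and
the bare-soil index (SI); Greenness is the NDVI; Heat is land surface
temperature decoded from thermal digital numbers; Wetness is the MODIS
tasseled-cap wetness component.  Zero denominators in the normalized-ratio
indices produce nodata rather than infinities, since composites over water
or fill can legitimately contain zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import AnnualComposite, GeoGrid

#: Tasseled-cap wetness coefficients for the 7 reflectance bands, in the
#: canonical band order (red, NIR1, blue, green, NIR2, SWIR1, SWIR2).
WETNESS_COEFFS = np.array(
    [0.1147, 0.2489, 0.2408, 0.3132, 0.3122, -0.6416, -0.5087]
)

#: LST decoding: Kelvin = LST_DN_SCALE * dn, Celsius = Kelvin + KELVIN_OFFSET
LST_DN_SCALE = 0.02
KELVIN_OFFSET = -273.15


@dataclass
class IndicatorStack:
    """Co-registered per-year indicator rasters, raw and (optionally) normalized."""

    index_year: int
    grid: GeoGrid
    dryness: np.ndarray
    greenness: np.ndarray
    heat: np.ndarray  # degrees C
    wetness: np.ndarray
    valid_mask: np.ndarray
    dryness_n: np.ndarray | None = None
    greenness_n: np.ndarray | None = None
    heat_n: np.ndarray | None = None
    wetness_n: np.ndarray | None = None

    #: indicator order used for PCA loadings throughout the package
    ORDER = ("dryness", "greenness", "heat", "wetness")

    def raw(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def normalized(self, name: str) -> np.ndarray:
        layer = getattr(self, f"{name}_n")
        if layer is None:
            raise ValueError(f"indicator {name!r} has not been normalized yet")
        return layer


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = np.isfinite(num) & np.isfinite(den) & (den != 0)
    out[ok] = num[ok] / den[ok]
    return out


def ndvi(composite: AnnualComposite) -> np.ndarray:
    """Greenness: (NIR1 − red) / (NIR1 + red), in [−1, 1]; negative over water."""
    nir1, red = composite.band("nir1"), composite.band("red")
    return _safe_ratio(nir1 - red, nir1 + red)


def ndbsi(composite: AnnualComposite) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dryness (NDBSI) and its parts.

    Returns ``(ibi, si, dryness)`` where::

        IBI = (A − B) / (A + B)
        A   = 2·SWIR1 / (SWIR1 + NIR1)
        B   = NIR1 / (NIR1 + red) + green / (green + SWIR1)
        SI  = ((SWIR1 + red) − (NIR1 + blue)) / ((SWIR1 + red) + (NIR1 + blue))
        Dryness = (IBI + SI) / 2

    Any zero sub-denominator makes the cell nodata.
    """
    red = composite.band("red")
    green = composite.band("green")
    blue = composite.band("blue")
    nir1 = composite.band("nir1")
    swir1 = composite.band("swir1")

    a = _safe_ratio(2.0 * swir1, swir1 + nir1)
    b = _safe_ratio(nir1, nir1 + red) + _safe_ratio(green, green + swir1)
    ibi = _safe_ratio(a - b, a + b)
    si = _safe_ratio((swir1 + red) - (nir1 + blue), (swir1 + red) + (nir1 + blue))
    dryness = 0.5 * (ibi + si)
    return ibi, si, dryness


def wetness(composite: AnnualComposite) -> np.ndarray:
    """Tasseled-cap wetness: fixed linear combination of the 7 bands."""
    return np.tensordot(WETNESS_COEFFS, composite.bands, axes=1)


def lst_celsius(dn: np.ndarray) -> np.ndarray:
    """Heat in °C from thermal digital numbers: 0.02·dn − 273.15."""
    dn = np.asarray(dn, dtype=np.float64)
    return LST_DN_SCALE * dn + KELVIN_OFFSET


def compute_indicators(composite: AnnualComposite) -> IndicatorStack:
    """Compute all four indicator rasters from an annual composite.

    The stack's valid mask is the composite's mask intersected with cells
    where every indicator is defined (no zero-denominator nodata).
    """
    _, _, dryness = ndbsi(composite)
    greenness = ndvi(composite)
    heat = composite.lst_celsius.copy()
    wet = wetness(composite)
    valid = (
        composite.valid_mask
        & np.isfinite(dryness)
        & np.isfinite(greenness)
        & np.isfinite(heat)
        & np.isfinite(wet)
    )
    for layer in (dryness, greenness, heat, wet):
        layer[~valid] = np.nan
    return IndicatorStack(
        index_year=composite.index_year,
        grid=composite.grid,
        dryness=dryness,
        greenness=greenness,
        heat=heat,
        wetness=wet,
        valid_mask=valid,
    )
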