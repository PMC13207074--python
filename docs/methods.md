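# Methods

## The index

The Remote Sensing Ecological Index (RSEI) summarizes eco-environmental
quality as the first principal component of four per-pixel indicators
computed from multiband surface-reflectance and thermal rasters:

- **Dryness (NDBSI)** — the mean of the index-based built-up index (IBI)
  and the bare-soil index (SI),

      IBI = (A − B) / (A + B),
      A   = 2·ρ_SWIR1 / (ρ_SWIR1 + ρ_NIR1),
      B   = ρ_NIR1 / (ρ_NIR1 + ρ_red) + ρ_green / (ρ_green + ρ_SWIR1),
      SI  = ((ρ_SWIR1 + ρ_red) − (ρ_NIR1 + ρ_blue))
          / ((ρ_SWIR1 + ρ_red) + (ρ_NIR1 + ρ_blue)),
      NDBSI = (IBI + SI) / 2.

  Both NIR symbols in the IBI are mapped to the NIR1 band (MODIS band 2),
  the standard IBI reading; NDBSI runs from −1 (vegetated) to +1
  (impervious/bare).
- **Greenness (NDVI)** — (ρ_NIR1 − ρ_red)/(ρ_NIR1 + ρ_red); negative over
  water.
- **Heat (LST)** — land surface temperature decoded from thermal digital
  numbers, LST[K] = 0.02·ND, reported in °C (−273.15).
- **Wetness** — the tasseled-cap wetness component for 7-band MODIS-style
  reflectance: 0.1147·ρ_red + 0.2489·ρ_NIR1 + 0.2408·ρ_blue +
  0.3132·ρ_green + 0.3122·ρ_NIR2 − 0.6416·ρ_SWIR1 − 0.5087·ρ_SWIR2.

Each indicator is min-max rescaled per year over valid pixels,
NI = (I − I_min)/(I_max − I_min), so the four variables are unit-free in
[0, 1] before PCA.  The difference form of the denominator is the one that
actually yields a [0, 1] range, which is the property the construction
depends on, so it is used throughout.  A constant raster has no scale and is
rejected as degenerate.

PCA runs per year on the covariance matrix of the four normalized
indicators with pixels as observations (the original RSEI recipe — not the
correlation matrix, and not pooled across years, since explained variance
is reported annually).  The eigen-solver's arbitrary sign is fixed by
forcing the largest-magnitude loading positive.  Orientation: if the
Greenness and Wetness loadings are both negative, the ecology-positive
indicators point down the axis and the component is reflected
(RSEI₀ = 1 − PC1); if the two disagree in sign, Greenness — the dominant
ecological indicator — decides, and a warning is logged.  RSEI₀ is then
min-max rescaled to RSEIn ∈ [0, 1] over the year's valid pixels and
classified: Poor [0, 0.2), Fair [0.2, 0.4), Moderate [0.4, 0.6),
Good [0.6, 0.8), Excellent [0.8, 1.0] — boundaries half-open with upper
ownership, top interval closed.

Scene-wise (spatial) normalization of RSEI₀ is the default because the
mapped quality classes are spatial; a per-pixel temporal alternative
(min/max over the years of each pixel) is available as
`rsein_normalization: per_pixel` without endorsement.

## Compositing and masking

Annual composites use the September 1 (Y−1) – March 31 (Y) window, labelled
by index year Y (austral spring–summer); e.g. year 2001 covers Sep 2000 –
Mar 2001.  Pixels failing the QA bit tests (default MOD09A1-style state
flags: cloud-state bits 0–1 must be 0 and shadow bit 2 must be 0; synthetic
archives use a single cloud bit) become nodata before compositing.  The
composite statistic is the per-cell **median** over usable observations
(robust to residual cloud); mean is selectable.  A cell is valid only when
every required layer received at least one usable observation.  Thermal
digital numbers are composited first and converted after — the conversion
is affine, so it commutes with the mean, and the median commutes with any
monotone map, making either order exact.  Thermal rasters on a coarser grid
are brought to the analysis grid by nearest-neighbor resampling (value
preserving; exact center ties resolve deterministically to the
northern-then-western source cell).

## Trend and change-point mapping

Per pixel over the annual RSEIn series (missing years skipped, never
imputed; fewer than `min_years` = 10 valid years → nodata):

- **Theil-Sen slope** β = median of all pairwise slopes
  (xⱼ − xᵢ)/(tⱼ − tᵢ), i < j.  The mean of pairwise slopes is available as
  an option for comparison, but the median is the Theil-Sen definition and
  the default.
- **Mann–Kendall** S = Σ_{i<j} sign(xⱼ − xᵢ) with the tie-corrected
  variance Var(S) = [n(n−1)(2n+5) − Σₜ t(t−1)(2t+5)]/18 and the
  continuity-corrected Z ((S∓1)/√Var(S); Z = 0 when S = 0).  Two-tailed
  classification compares |Z| against 1.645 / 1.96 / 2.574 (90/95/99%),
  direction from sign(Z).  2.574 is a rounding seen in applied trend
  mapping; the standard 2.576 can be passed via `z_thresholds`.
- **Pettitt** U_t,T = Σ_{i≤t} Σ_{j>t} sign(xⱼ − xᵢ), computed by the
  recursion U_t = U_{t−1} + Σⱼ sign(xⱼ − xₜ) and verified in tests against
  the direct double sum.  K = max|U_t|, break position τ = earliest argmax,
  approximate two-sided p = min(1, 2·exp(−6K²/(T³ + T²))), significant at
  α = 0.10.  τ is reported as the year label of the last observation of the
  first segment; with a step first applied in year Y*, the expected label
  is therefore Y* − 1.  Gaps compress the series to its valid observations
  with T = n; the rank statistic ignores the resulting unequal spacing.

## Synthetic scenes

The generator emulates an 8-day, 500 m reflectance product (7 bands, scaled
integers ×1e-4 on disk) and a 1 km thermal product (ND = (LST[K])/0.02)
over a five-class land-cover mosaic (urban, dense vegetation, agriculture,
water, bare soil).  The `mmr_like` preset places vegetation north,
agriculture center, an urban core east, a coastal water strip and a
bare-soil patch on a 48×48 grid of 0.005° cells over 25 index years
(2001–2025), with three scenes per seasonal window by default.  Per-class
spectral signatures are plausible tropical-coastal seasonal means; water
has NIR1 < red so its NDVI is negative.  Scene values are
signature + per-class linear drift·(Y − Y₀) + optional step·1[Y ≥ Y*]
+ additive Gaussian noise (sd 0.01 reflectance, 0.5 °C LST), truncated to
the physical reflectance range.  Cloud/shadow QA flags are Bernoulli draws
(default rate 0.1) shared between the reflectance and thermal series of a
date to mimic co-located cloudiness.  The preset injects a greening drift
(+0.004 yr⁻¹ on NIR1, −0.05 °C yr⁻¹) on the agricultural belt and a
degradation step (NIR1 −0.08, SWIR1 +0.05, LST +1.5 °C) in part of the
urban core from 2018 on.

Ground-truth layers give the per-pixel true trend sign (the sign of the
NDVI rate implied by the band drifts at the class signature, falling back
to the negated LST drift sign when that rate is zero), the true change year
and the affected-region mask.

A second generator, `render_index_cube`, draws annual series directly in
index units (base + drift·t + step + noise per pixel).  Trend and
change-point recovery is scored on such cubes — a stated drift of
0.01 units yr⁻¹ under 0.05 noise is then exactly what the test statistic
sees — while the scene-level path is checked directionally (urban pixels
score below dense vegetation; the greening belt is flagged increasing),
because band-level drifts have no closed-form image in index units.

What the generator does **not** model: radiative transfer or BRDF effects,
spatially correlated noise or cloud fields, sensor drift, mixed pixels,
seasonality within the compositing window.  Passing recovery tests
therefore demonstrate the statistical machinery under clean additive
structure, not performance on real archives.

## Numerical choices and edge cases

- Zero denominators in the ratio indices yield nodata, not ±∞.
- PCA requires ≥ 5 valid cells and nonzero total variance; normalization
  requires ≥ 2 distinct values.
- Mann–Kendall/Pettitt require ≥ 4 observations (configurable; the
  per-pixel maps default to 10).
- Problem sizes: tests and the acceptance script use grids of ~1–2 thousand
  pixels and 25-year series, where every stage runs in seconds and
  per-pixel loops are still exact enumeration.
- All randomness flows from one integer seed through
  `numpy.random.default_rng`; identical configs give byte-identical CSV and
  manifest outputs.

## Known limitations

- Single change point per series; no prewhitening or seasonal Mann–Kendall
  variant (annual series are treated as exchangeable under H₀).
- No reprojection between coordinate reference systems; all grids must
  share one geographic CRS.
- The Pettitt p-value is the classical exponential approximation; it is
  approximate in small samples and conservative near the series endpoints.
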