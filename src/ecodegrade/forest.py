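"""Forest degradation from canopy-cover time series and land-use conversion.

Degraded forest pixels are found from a multi-year percent-canopy-cover
raster stack (a Vegetation-Continuous-Fields-style product): the ordinary
least-squares linear trend of canopy against year is fitted per pixel, and a
pixel is flagged degraded where the fitted total change over the series span
— slope times (last year - first year) — is a drop of more than 10
percentage points. Optionally only pixels whose mean canopy lies in a
mappable band (default 30-80%, the canopy range over which such products
resolve forest reliably) are considered forest at all.

Land-use conversion (deforestation to pasture, built-up, unproductive land)
is detected by comparing two aligned categorical rasters: cells that are
forest in the early epoch and non-forest in the late epoch are labeled with
the late-epoch category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AlignmentError, SimulationSpecError
from .grid import Grid

#: Fitted total change (percentage points over the span) below which a pixel
#: is flagged degraded.
DROP_THRESHOLD_PP = -10.0

#: Default canopy band (percent cover) treated as mappable forest.
CANOPY_RANGE = (30.0, 80.0)


@dataclass
class TrendResult:
    """Per-pixel OLS trend of canopy cover against year."""

    slope: np.ndarray          # percent cover per year; NaN where nodata
    total_change: np.ndarray   # slope * (last year - first year)
    degraded: np.ndarray       # bool; False where nodata
    valid: np.ndarray          # bool; >= 3 valid epochs (and in canopy band)


def pixel_trend(years, canopy, nodata_mask=None, canopy_range=CANOPY_RANGE,
                drop_threshold=DROP_THRESHOLD_PP) -> TrendResult:
    """Per-pixel OLS slope of canopy (percent) against year.

    Parameters
    ----------
    years : sequence of int, strictly increasing, length >= 3.
    canopy : array (n_years, nrows, ncols) of percent cover.
    nodata_mask : optional bool array of the same shape; True marks missing
        observations. Pixels with fewer than 3 valid epochs are returned as
        nodata (NaN slope, not flagged), never raised.
    canopy_range : (lo, hi) mean-canopy band to treat as forest, or None to
        disable the mask.
    """
    years = np.asarray(years, dtype=float)
    if years.size < 3:
        raise SimulationSpecError(f"need >= 3 epochs, got {years.size}")
    if np.any(np.diff(years) <= 0):
        raise SimulationSpecError("years must be strictly increasing")
    canopy = np.asarray(canopy, dtype=float)
    if canopy.shape[0] != years.size:
        raise AlignmentError(
            f"canopy stack has {canopy.shape[0]} bands for {years.size} years"
        )
    missing = ~np.isfinite(canopy)
    if nodata_mask is not None:
        missing |= np.asarray(nodata_mask, dtype=bool)
    obs = np.where(missing, np.nan, canopy)

    nvalid = (~missing).sum(axis=0)
    valid = nvalid >= 3

    # masked closed-form OLS: slope = cov(t, y) / var(t) over valid epochs
    w = (~missing).astype(float)
    t = years[:, None, None]
    sw = np.maximum(w.sum(axis=0), 1.0)
    y0 = np.where(missing, 0.0, obs)
    tbar = (w * t).sum(axis=0) / sw
    ybar = (w * y0).sum(axis=0) / sw
    stt = (w * (t - tbar) ** 2).sum(axis=0)
    sty = (w * (t - tbar) * (y0 - ybar)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(valid & (stt > 0), sty / np.where(stt > 0, stt, 1.0), np.nan)

    span = years[-1] - years[0]
    total_change = slope * span
    if canopy_range is not None:
        lo, hi = canopy_range
        mean_canopy = ybar
        valid = valid & (mean_canopy >= lo) & (mean_canopy <= hi)
    degraded = valid & (total_change < drop_threshold)
    slope = np.where(valid, slope, np.nan)
    return TrendResult(slope=slope, total_change=np.where(valid, total_change, np.nan),
                       degraded=degraded, valid=valid)


def detect_conversion(landuse_t0: Grid, landuse_t1: Grid, forest_codes) -> Grid:
    """Forest-loss transition raster between two categorical epochs.

    Cells that are forest (code in ``forest_codes``) at t0 and non-forest at
    t1 take the t1 category code; all other cells take the nodata value.
    """
    landuse_t0.require_aligned(landuse_t1)
    t0 = np.asarray(landuse_t0.values)
    t1 = np.asarray(landuse_t1.values)
    codes = np.asarray(sorted(forest_codes))
    was_forest = np.isin(t0, codes)
    lost = was_forest & ~np.isin(t1, codes)
    out = np.where(lost, t1, landuse_t0.nodata)
    return landuse_t0.with_values(out)


def transition_areas(transition: Grid) -> dict:
    """Area (km²) per destination category in a transition raster."""
    vals = transition.values
    cats = np.unique(vals[vals != transition.nodata])
    return {float(c): float((vals == c).sum() * transition.cell_area_km2) for c in cats}
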