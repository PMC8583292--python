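"""Degraded-feature density grids, Getis-Ord Gi* hotspots and classification.

The hotspot stage works on per-ecosystem density grids: the amount of
degraded ecosystem (feature count, clipped line length, or clipped polygon
area) in each cell, divided by the cell area in km². Densities are scored
into five classes (1 very low ... 5 very high; 0 where the ecosystem is
absent), the per-ecosystem score layers are summed into a national
degradation-density layer, and the Getis-Ord Gi* local statistic locates
statistically significant concentrations.

Gi* for cell i over the value field x with spatial weights w_ij is the
z-score

    Gi* = [ sum_j w_ij x_j  -  Xbar sum_j w_ij ]
          / ( S * sqrt( [ n sum_j w_ij^2 - (sum_j w_ij)^2 ] / (n - 1) ) )

with Xbar = sum_j x_j / n and S = sqrt( sum_j x_j^2 / n - Xbar^2 ).
Weights here are binary fixed-distance-band weights on cell centers,
self-inclusive (w_ii = 1), the conventional "star" form. Under the
randomization null Gi* has mean 0 and variance 1, so |z| cut-offs
1.645 / 1.960 / 2.576 give 90 / 95 / 99% confidence hot- and cold-spot bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve
from shapely.geometry import box

from .errors import ClassingError, SimulationSpecError
from .features import DEGRADED
from .grid import Grid

log = logging.getLogger(__name__)

Z90, Z95, Z99 = 1.645, 1.960, 2.576

#: Integer codes for the confidence bins (sign = hot/cold, magnitude = level).
BIN_LABELS = {
    -3: "cold99", -2: "cold95", -1: "cold90",
    0: "not-significant",
    1: "hot90", 2: "hot95", 3: "hot99",
}


@dataclass
class GiStarResult:
    """Per-cell Gi* z-scores and integer-coded confidence bins."""

    z: Grid
    bins: Grid  # integer codes per BIN_LABELS


def rasterize_density(features, grid: Grid, mode: str,
                      include_classes=frozenset({DEGRADED})) -> Grid:
    """Per-cell density (amount per km²) of features in ``include_classes``.

    mode: ``count`` (points), ``length`` (lines, km in cell), ``area``
    (polygons, km² in cell); the per-cell amount is divided by the cell
    area in km².
    """
    if grid.values.size == 0:
        raise SimulationSpecError("empty grid")
    if mode not in ("count", "length", "area"):
        raise SimulationSpecError(f"unknown density mode {mode!r}")
    out = np.zeros((grid.nrows, grid.ncols), dtype=float)
    selected = [f for f in features if f.degradation_class in include_classes]
    for f in selected:
        geom = f.geometry
        if mode == "count":
            row, col = grid.cell_index(geom.x, geom.y)
            if 0 <= row < grid.nrows and 0 <= col < grid.ncols:
                out[row, col] += 1.0
            continue
        # clip the geometry against every cell its bbox touches
        xmin, ymin, xmax, ymax = geom.bounds
        r0, c0 = grid.cell_index(xmin, ymax)
        r1, c1 = grid.cell_index(xmax, ymin)
        for row in range(max(r0, 0), min(r1, grid.nrows - 1) + 1):
            for col in range(max(c0, 0), min(c1, grid.ncols - 1) + 1):
                cell = box(*grid.cell_bounds(row, col))
                inter = geom.intersection(cell)
                if inter.is_empty:
                    continue
                amount = inter.length / 1000.0 if mode == "length" else inter.area / 1e6
                out[row, col] += amount
    return grid.with_values(out / grid.cell_area_km2)


def classify_density(grid: Grid, k: int = 5, method: str = "quantile") -> Grid:
    """Score positive-density cells 1..k (low to high); zero cells score 0.

    ``quantile`` classes positive cells by k-quantile edges with ties broken
    toward the lower class; ``equal-interval`` splits the positive value
    range into k equal bins, collapsing to class 1 on a degenerate (constant)
    range.
    """
    if k < 2:
        raise ClassingError(f"need k >= 2 classes, got {k}")
    if method not in ("quantile", "equal-interval"):
        raise ClassingError(f"unknown classing method {method!r}")
    vals = grid.values
    pos = vals[vals > 0]
    scores = np.zeros_like(vals, dtype=int)
    if pos.size == 0:
        log.warning("classify_density: all-zero grid, all scores 0")
        return grid.with_values(scores)
    if method == "quantile":
        edges = np.quantile(pos, np.arange(1, k) / k)
    else:
        lo, hi = pos.min(), pos.max()
        edges = lo + np.arange(1, k) * (hi - lo) / k  # degenerate range: all edges == lo
    mask = vals > 0
    # strict > on each edge sends tied values to the lower class
    scores[mask] = 1 + np.sum(vals[mask, None] > edges[None, :], axis=1)
    return grid.with_values(scores)


def sum_layers(grids) -> Grid:
    """Cell-wise sum of scored layers (all grids must align)."""
    grids = list(grids)
    if not grids:
        raise SimulationSpecError("sum_layers needs at least one grid")
    first = grids[0]
    total = np.zeros_like(first.values, dtype=float)
    for g in grids:
        first.require_aligned(g)
        total = total + g.values
    return first.with_values(total)


def _disk_kernel(radius: float, cell_size: float) -> np.ndarray:
    """Binary fixed-distance-band kernel on cell centers, self-inclusive."""
    r_cells = int(np.floor(radius / cell_size))
    offs = np.arange(-r_cells, r_cells + 1)
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    return ((dx * cell_size) ** 2 + (dy * cell_size) ** 2 <= radius**2).astype(float)


def gi_star(grid: Grid, neighborhood: float) -> GiStarResult:
    """Getis-Ord Gi* z-score per cell with binary distance-band weights.

    ``neighborhood`` is the band radius in meters applied to cell centers;
    it must be at least the cell size. A constant field has S = 0 and all
    z defined as 0.
    """
    x = np.asarray(grid.values, dtype=float)
    n = x.size
    if n < 2:
        raise SimulationSpecError("Gi* needs at least 2 cells")
    if neighborhood < grid.cell_size:
        raise SimulationSpecError(
            f"neighborhood radius {neighborhood} m is smaller than the cell size"
        )
    kernel = _disk_kernel(neighborhood, grid.cell_size)
    wx = convolve(x, kernel, mode="constant", cval=0.0)
    wsum = convolve(np.ones_like(x), kernel, mode="constant", cval=0.0)
    # binary weights: sum of squared weights equals the weight sum
    xbar = x.mean()
    s = np.sqrt(max((x**2).mean() - xbar**2, 0.0))
    var_term = (n * wsum - wsum**2) / (n - 1)
    denom = s * np.sqrt(np.maximum(var_term, 0.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(denom > 0, (wx - xbar * wsum) / np.where(denom > 0, denom, 1.0), 0.0)
    zg = grid.with_values(z)
    return GiStarResult(z=zg, bins=confidence_bins(zg))


def confidence_bins(z: Grid) -> Grid:
    """Integer-coded hot/cold confidence bins from Gi* z-scores.

    |z| >= 2.576 -> 99%, >= 1.960 -> 95%, >= 1.645 -> 90%, else not
    significant; the sign separates hot (+) from cold (-). Non-finite
    z-scores map to not-significant with a warning.
    """
    zv = np.asarray(z.values, dtype=float)
    finite = np.isfinite(zv)
    if not finite.all():
        log.warning("confidence_bins: %d non-finite z-scores treated as not significant",
                    int((~finite).sum()))
    za = np.where(finite, zv, 0.0)
    mag = (np.abs(za) >= Z90).astype(int) + (np.abs(za) >= Z95) + (np.abs(za) >= Z99)
    return z.with_values(np.sign(za).astype(int) * mag)


def natural_breaks(values, k: int) -> list[float]:
    """Jenks/Fisher optimal 1-D classification into k classes.

    Returns the k-1 break values — the maximum of each class but the last —
    of the partition of the sorted values minimizing the total within-class
    sum of squared deviations. Deterministic; requires at least k distinct
    values.
    """
    vals = np.sort(np.asarray(list(values), dtype=float))
    n = vals.size
    if k < 1:
        raise ClassingError(f"need k >= 1, got {k}")
    if np.unique(vals).size < k:
        raise ClassingError(
            f"need at least {k} distinct values for {k} classes, "
            f"got {np.unique(vals).size}"
        )
    # prefix sums for O(1) within-class SSD of any contiguous run
    c1 = np.concatenate([[0.0], np.cumsum(vals)])
    c2 = np.concatenate([[0.0], np.cumsum(vals**2)])

    def ssd_to(j: int, i_arr: np.ndarray) -> np.ndarray:
        """Within-class SSD of vals[i:j] for a vector of run starts i."""
        m = j - i_arr
        s = c1[j] - c1[i_arr]
        return (c2[j] - c2[i_arr]) - s * s / m

    # cost[j][c]: min total SSD of vals[:j] split into c classes
    cost = np.full((n + 1, k + 1), np.inf)
    cut = np.zeros((n + 1, k + 1), dtype=int)
    cost[0, 0] = 0.0
    all_j = np.arange(n + 1)
    zero = np.array([0])
    cost[1:, 1] = np.array([ssd_to(j, zero)[0] for j in range(1, n + 1)])
    for c in range(2, k + 1):
        for j in range(c, n + 1):
            i_arr = all_j[c - 1 : j]
            cand = cost[i_arr, c - 1] + ssd_to(j, i_arr)
            arg = int(np.argmin(cand))
            cost[j, c], cut[j, c] = cand[arg], i_arr[arg]
    # backtrack class boundaries
    breaks = []
    j = n
    for c in range(k, 1, -1):
        i = cut[j, c]
        breaks.append(float(vals[i - 1]))
        j = i
    return breaks[::-1]


def assign_breaks_classes(values, breaks) -> np.ndarray:
    """0-based class index per value given break values (class maxima)."""
    return np.searchsorted(np.asarray(breaks, dtype=float),
                           np.asarray(values, dtype=float), side="left")
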