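"""Seeded synthetic landscapes with known degradation ground truth.

The generator stands in for the national datasets the assessment normally
consumes. It is class-conditional: each feature first draws its hidden true
condition (degraded with a controllable prevalence), then draws every
criterion attribute inside the band(s) that place the feature in that class,
so prevalence is a direct parameter and every threshold class is exercised.
Degraded features are placed in Gaussian clusters around uniformly located
centers so that genuine density hotspots exist; with ``cluster_count = 0``
degraded features are spread uniformly (no spatial structure, the null
landscape for hotspot calibration).

All randomness flows from one integer seed; each stage (ecosystem kind,
canopy series, validation points) uses its own child stream with a fixed
offset, so stages are individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon
from shapely.strtree import STRtree

from .errors import EmptyValidationError, SimulationSpecError
from .features import DEGRADED, NATURAL, EcosystemFeature, worst_class
from .io import load_bundled_scheme

#: Fixed per-stage offsets for child RNG streams.
_STREAM_OFFSETS = {
    "grassland": 1, "forest": 2, "cave": 3, "river": 4, "lake": 5, "coastal": 6,
    "canopy": 10, "validation": 11, "regions": 12,
}

#: Typical feature footprint (m) per kind: polygon side or line length scale.
_FOOTPRINT = {"grassland": 600.0, "lake": 400.0, "coastal": 500.0, "forest": 800.0,
              "river": 4000.0, "cave": 0.0}


@dataclass
class SimulationSpec:
    """Study-condition parameters of a synthetic landscape."""

    extent: tuple = (0.0, 0.0, 50_000.0, 50_000.0)  # xmin, ymin, xmax, ymax (m)
    n_features: dict = field(default_factory=lambda: {"grassland": 500})
    prevalence: dict = field(default_factory=lambda: {"grassland": 0.3})
    cluster_count: int = 3
    cluster_sd: float = 2500.0  # m
    noise_sd: float = 2.0       # canopy noise, percent-cover points
    seed: int = 0

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if not (xmax > xmin and ymax > ymin):
            raise SimulationSpecError(f"degenerate extent {self.extent}")
        for kind, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise SimulationSpecError(f"prevalence[{kind!r}] = {p} outside [0, 1]")
        for kind, n in self.n_features.items():
            if n < 0:
                raise SimulationSpecError(f"n_features[{kind!r}] = {n} < 0")
        if self.cluster_count < 0:
            raise SimulationSpecError("cluster_count must be >= 0")
        if self.cluster_sd <= 0:
            raise SimulationSpecError("cluster_sd must be > 0")

    def rng(self, stage: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM_OFFSETS[stage]])


def _cluster_centers(spec: SimulationSpec, rng) -> np.ndarray:
    xmin, ymin, xmax, ymax = spec.extent
    return rng.uniform([xmin, ymin], [xmax, ymax], size=(max(spec.cluster_count, 1), 2))


def _place(spec: SimulationSpec, rng, centers, clustered: bool) -> tuple[float, float]:
    xmin, ymin, xmax, ymax = spec.extent
    if clustered and spec.cluster_count > 0:
        cx, cy = centers[rng.integers(len(centers))]
        x = np.clip(rng.normal(cx, spec.cluster_sd), xmin, xmax)
        y = np.clip(rng.normal(cy, spec.cluster_sd), ymin, ymax)
        return float(x), float(y)
    return float(rng.uniform(xmin, xmax)), float(rng.uniform(ymin, ymax))


def _geometry(kind: str, x: float, y: float, rng):
    scale = _FOOTPRINT[kind]
    if kind == "cave":
        return Point(x, y)
    if kind == "river":
        # short polyline: random heading with jitter per segment
        length = scale * rng.lognormal(0.0, 0.4)
        heading = rng.uniform(0, 2 * math.pi)
        pts = [(x, y)]
        for _ in range(3):
            heading += rng.normal(0, 0.4)
            step = length / 3
            x, y = x + step * math.cos(heading), y + step * math.sin(heading)
            pts.append((x, y))
        return LineString(pts)
    side = scale * rng.lognormal(0.0, 0.3)
    half = side / 2
    return Polygon([(x - half, y - half), (x + half, y - half),
                    (x + half, y + half), (x - half, y + half)])


def _draw_attributes(criteria, degraded: bool, rng) -> dict:
    attrs = {}
    for crit in criteria:
        lo, hi = crit.simulate[DEGRADED if degraded else NATURAL]
        attrs[crit.attribute] = float(rng.uniform(lo, hi))
    return attrs


def simulate_features(kind: str, spec: SimulationSpec, scheme=None) -> list[EcosystemFeature]:
    """Generate one ecosystem's features with hidden true classes.

    Attributes are drawn inside the natural or degraded band of every
    criterion of the kind's scheme, so downstream scoring recovers the true
    class by construction; the informative signal the pipeline must recover
    is the spatial arrangement and the prevalence.
    """
    if kind == "grassland":
        return simulate_grassland(spec)
    if scheme is None:
        scheme = load_bundled_scheme("coastal_terrestrial" if kind == "coastal" else kind)
    rng = spec.rng(kind)
    n = spec.n_features.get(kind, 0)
    prev = spec.prevalence.get(kind, 0.0)
    centers = _cluster_centers(spec, rng)
    feats = []
    for i in range(n):
        degraded = bool(rng.random() < prev)
        x, y = _place(spec, rng, centers, clustered=degraded)
        feats.append(EcosystemFeature(
            feature_id=f"{kind}-{i}",
            kind=kind,
            geometry=_geometry(kind, x, y, rng),
            attributes=_draw_attributes(scheme.criteria, degraded, rng),
            true_class=DEGRADED if degraded else NATURAL,
        ))
    return feats


# semi-degraded bands of the three low-weight grassland criteria; any
# combination keeps DI <= 5 + 20 + 5 = 30, i.e. still the natural class
_GRASSLAND_SEMI = {
    "dist_locality_km": (2.0, 4.0),
    "dist_sheepfold_km": (0.5, 2.0),
    "slope_deg": (15.0, 30.0),
}


def simulate_grassland(spec: SimulationSpec) -> list[EcosystemFeature]:
    """Grassland parcels whose DI class equals the hidden truth.

    Non-degraded parcels draw the three low-weight criteria from the natural
    or semi-degraded band at random (their weights sum to 30, so DI stays
    in the natural range) and the heavy criteria from the natural band;
    degraded parcels draw the bare-soil criterion (weight 100) in its
    degraded band, which alone forces DI >= 200, and the rest from their
    degraded bands with probability 1/2 each.
    """
    scheme = load_bundled_scheme("grassland")
    rng = spec.rng("grassland")
    n = spec.n_features.get("grassland", 0)
    prev = spec.prevalence.get("grassland", 0.0)
    centers = _cluster_centers(spec, rng)
    feats = []
    for i in range(n):
        degraded = bool(rng.random() < prev)
        x, y = _place(spec, rng, centers, clustered=degraded)
        attrs = {}
        for crit in scheme.criteria:
            if degraded:
                band = DEGRADED if (crit.attribute == "bare_soil_pct" or rng.random() < 0.5) \
                    else NATURAL
                lo, hi = crit.simulate[band]
            elif crit.attribute in _GRASSLAND_SEMI and rng.random() < 0.3:
                lo, hi = _GRASSLAND_SEMI[crit.attribute]
            else:
                lo, hi = crit.simulate[NATURAL]
            attrs[crit.attribute] = float(rng.uniform(lo, hi))
        feats.append(EcosystemFeature(
            feature_id=f"grassland-{i}", kind="grassland",
            geometry=_geometry("grassland", x, y, rng),
            attributes=attrs,
            true_class=DEGRADED if degraded else NATURAL,
        ))
    return feats


@dataclass
class CanopySeriesSim:
    """Synthetic canopy-cover stack with its true-degraded mask."""

    years: np.ndarray
    canopy: np.ndarray        # (n_years, nrows, ncols) percent cover
    true_degraded: np.ndarray  # bool (nrows, ncols)


def simulate_canopy_series(spec: SimulationSpec, years, shape=(40, 40),
                           drop_range=(12.0, 25.0), noise_sd=None) -> CanopySeriesSim:
    """Per-pixel canopy time series: flat (noisy) where intact, linearly
    declining by more than 10 percentage points where truly degraded.

    The true-degraded mask is spatially clustered: the fraction
    ``prevalence['forest']`` of pixels nearest to the cluster centers is
    degraded, giving exactly the requested prevalence.
    """
    years = np.asarray(years, dtype=float)
    if years.size < 3:
        raise SimulationSpecError(f"need >= 3 time points, got {years.size}")
    rng = spec.rng("canopy")
    if noise_sd is None:
        noise_sd = spec.noise_sd
    nrows, ncols = shape
    prev = spec.prevalence.get("forest", 0.0)

    rr, cc = np.meshgrid(np.arange(nrows), np.arange(ncols), indexing="ij")
    if spec.cluster_count > 0 and prev > 0:
        centers = rng.uniform([0, 0], [nrows, ncols], size=(spec.cluster_count, 2))
        d = np.min([np.hypot(rr - r0, cc - c0) for r0, c0 in centers], axis=0)
        true_deg = d <= np.quantile(d, prev)
    else:
        true_deg = rng.random(shape) < prev

    base = rng.uniform(35.0, 75.0, size=shape)
    drop = rng.uniform(*drop_range, size=shape)
    span = years[-1] - years[0]
    frac = (years[:, None, None] - years[0]) / span
    canopy = np.where(true_deg, base + 5.0, base)[None] - np.where(true_deg, drop, 0.0)[None] * frac
    if noise_sd > 0:
        canopy = canopy + rng.normal(0.0, noise_sd, size=canopy.shape)
    canopy = np.clip(canopy, 0.0, 100.0)
    return CanopySeriesSim(years=years, canopy=canopy, true_degraded=true_deg)


def simulate_validation_truth(features, spec: SimulationSpec, n_points: int = 100,
                              radius: float = 300.0) -> pd.DataFrame:
    """Ground-truth points near scored features with binary degraded labels.

    Each point is seeded on a random feature and jittered within half the
    buffer radius; its truth label is 1 when any feature whose hidden true
    class is degraded lies within the buffer radius. Raises
    :class:`EmptyValidationError` for an empty feature set or zero points.
    """
    feats = list(features)
    if not feats or n_points <= 0:
        raise EmptyValidationError("validation needs features and n_points > 0")
    rng = spec.rng("validation")
    tree = STRtree([f.geometry for f in feats])
    rows = []
    for _ in range(n_points):
        f = feats[rng.integers(len(feats))]
        geom = f.geometry
        if geom.geom_type == "Point":
            bx, by = geom.x, geom.y
        elif geom.geom_type in ("LineString", "MultiLineString"):
            p = geom.interpolate(rng.random(), normalized=True)
            bx, by = p.x, p.y
        else:
            p = geom.representative_point()
            bx, by = p.x, p.y
        ang, r = rng.uniform(0, 2 * math.pi), radius * 0.5 * math.sqrt(rng.random())
        pt = Point(bx + r * math.cos(ang), by + r * math.sin(ang))
        hit_classes = [feats[j].true_class for j in tree.query(pt.buffer(radius))
                       if feats[j].geometry.dwithin(pt, radius)]
        truth = int(bool(hit_classes) and worst_class(hit_classes) == DEGRADED)
        rows.append((pt.x, pt.y, truth))
    return pd.DataFrame(rows, columns=["x", "y", "truth"])


def simulate_regions(spec: SimulationSpec, nx: int = 2, ny: int = 2) -> list:
    """Rectangular region polygons tiling the extent (zonal-table input)."""
    xmin, ymin, xmax, ymax = spec.extent
    xs = np.linspace(xmin, xmax, nx + 1)
    ys = np.linspace(ymin, ymax, ny + 1)
    regions = []
    for i in range(nx):
        for j in range(ny):
            regions.append((
                f"region-{i}{j}",
                Polygon([(xs[i], ys[j]), (xs[i + 1], ys[j]),
                         (xs[i + 1], ys[j + 1]), (xs[i], ys[j + 1])]),
            ))
    return regions
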