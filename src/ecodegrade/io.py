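"""Feature, raster, scheme and pipeline-configuration I/O.

Formats: vector features as GeoJSON FeatureCollections (coordinates in a
planar projected CRS in meters — geographic lon/lat input is rejected, not
reprojected), rasters as ESRI ASCII grids, tables as CSV, schemes and
pipeline configuration as YAML. A JSON run manifest can be written beside
outputs for reproducibility.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml
from shapely.geometry import mapping, shape

from .errors import GeometryError, MissingAttributeError, SchemeError, SimulationSpecError
from .features import GEOMETRY_BY_KIND, EcosystemFeature
from .grid import read_ascii_grid, write_ascii_grid  # noqa: F401  (re-export)
from .scoring import ScoringScheme

log = logging.getLogger(__name__)

#: Bundled scheme file per name.
BUNDLED_SCHEMES = {
    "grassland": "grassland.yaml",
    "cave": "cave.yaml",
    "river": "river.yaml",
    "lake": "lake.yaml",
    "coastal_terrestrial": "coastal_terrestrial.yaml",
    "coastal_marine": "coastal_marine.yaml",
}

_META_KEYS = ("feature_id", "kind", "true_class", "score", "degradation_class")


def load_scheme(path) -> ScoringScheme:
    """Load and validate a scoring scheme from a YAML document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemeError(f"{path}: scheme document must be a mapping")
    return ScoringScheme.from_dict(doc)


def load_bundled_scheme(name: str) -> ScoringScheme:
    """Load one of the shipped schemes (grassland, cave, river, lake,
    coastal_terrestrial, coastal_marine)."""
    if name not in BUNDLED_SCHEMES:
        raise SchemeError(f"no bundled scheme {name!r}; have {sorted(BUNDLED_SCHEMES)}")
    ref = resources.files("ecodegrade.schemes") / BUNDLED_SCHEMES[name]
    return ScoringScheme.from_dict(yaml.safe_load(ref.read_text()))


def dump_scheme(scheme: ScoringScheme, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scheme.to_dict(), fh, sort_keys=False)


def _required_attributes(kind: str) -> tuple[str, ...]:
    name = "coastal_terrestrial" if kind == "coastal" else kind
    if name in BUNDLED_SCHEMES:
        return load_bundled_scheme(name).attribute_names
    return ()


def _looks_geographic(geom) -> bool:
    xmin, ymin, xmax, ymax = geom.bounds
    return -180 <= xmin <= xmax <= 180 and -90 <= ymin <= ymax <= 90


def read_features(path, kind: str, require_attributes: bool = True) -> list[EcosystemFeature]:
    """Read a GeoJSON FeatureCollection as features of one ecosystem kind.

    Geometry types must match the kind (polygons for grassland / forest /
    lake / coastal, lines for rivers, points for caves) and coordinates must
    be planar meters; bounds that fit inside lon/lat ranges are rejected as
    geographic. With ``require_attributes`` every attribute named by the
    kind's bundled scheme must be present on every feature.
    """
    if kind not in GEOMETRY_BY_KIND:
        raise GeometryError(f"unknown ecosystem kind {kind!r}")
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise GeometryError(f"{path}: expected a GeoJSON FeatureCollection")
    required = _required_attributes(kind) if require_attributes else ()
    feats = []
    for i, f in enumerate(doc.get("features", [])):
        geom = shape(f["geometry"])
        if geom.geom_type not in GEOMETRY_BY_KIND[kind]:
            raise GeometryError(
                f"{path}: feature {i} has {geom.geom_type}, "
                f"kind '{kind}' requires {GEOMETRY_BY_KIND[kind]}"
            )
        if _looks_geographic(geom):
            raise GeometryError(
                f"{path}: feature {i} coordinates look geographic (lon/lat); "
                "a planar projected CRS in meters is required"
            )
        props = dict(f.get("properties") or {})
        meta = {k: props.pop(k, None) for k in _META_KEYS}
        missing = [a for a in required if a not in props]
        if missing:
            raise MissingAttributeError(missing, kind=kind)
        feats.append(EcosystemFeature(
            feature_id=str(meta["feature_id"] if meta["feature_id"] is not None else i),
            kind=kind,
            geometry=geom,
            attributes=props,
            true_class=meta["true_class"],
            score=meta["score"],
            degradation_class=meta["degradation_class"],
        ))
    log.info("read %d %s features from %s", len(feats), kind, path)
    return feats


def write_features(features, path) -> None:
    """Write features as a GeoJSON FeatureCollection (attributes + metadata)."""
    out = {"type": "FeatureCollection", "features": []}
    for f in features:
        props = dict(f.attributes)
        props["feature_id"] = f.feature_id
        props["kind"] = f.kind
        if f.true_class is not None:
            props["true_class"] = f.true_class
        if f.score is not None:
            props["score"] = f.score
        if f.degradation_class is not None:
            props["degradation_class"] = f.degradation_class
        out["features"].append(
            {"type": "Feature", "geometry": mapping(f.geometry), "properties": props}
        )
    with open(path, "w") as fh:
        json.dump(out, fh)
    log.info("wrote %d features to %s", len(out["features"]), path)


@dataclass
class PipelineConfig:
    """Run-level parameters shared by the pipeline stages."""

    grid_cell_size: float = 1000.0       # m
    neighborhood_radius: float = 3000.0  # m, Gi* fixed distance band
    density_class_count: int = 5
    random_seed: int = 0
    crs: str = "local-planar-meters"
    schemes: dict = field(default_factory=dict)  # kind -> scheme path or bundled name

    def __post_init__(self) -> None:
        if self.grid_cell_size <= 0:
            raise SimulationSpecError("grid_cell_size must be > 0")
        if self.neighborhood_radius < self.grid_cell_size:
            raise SimulationSpecError("neighborhood_radius must be >= grid_cell_size")
        if self.density_class_count < 2:
            raise SimulationSpecError("density_class_count must be >= 2")

    def resolve_scheme(self, kind: str) -> ScoringScheme:
        ref = self.schemes.get(kind, kind)
        if isinstance(ref, str) and ref in BUNDLED_SCHEMES:
            return load_bundled_scheme(ref)
        p = Path(ref)
        if not p.exists():
            raise SchemeError(f"scheme reference {ref!r} for kind {kind!r} does not resolve")
        return load_scheme(p)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = {k: doc[k] for k in (
        "grid_cell_size", "neighborhood_radius", "density_class_count",
        "random_seed", "crs", "schemes") if k in doc}
    return PipelineConfig(**known)


def write_manifest(path, payload: dict) -> None:
    """Write a machine-readable JSON run manifest beside outputs."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
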