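"""Spatial ecosystem features and the degradation-class vocabulary.

Every ecosystem unit handled by the pipeline — a grassland parcel, a river
reach, a cave entrance, a lake or coastal polygon — is an
:class:`EcosystemFeature`: a shapely geometry in a planar metric CRS plus a
flat attribute mapping holding the per-criterion measurements a scoring
scheme consumes. Simulated features additionally carry a hidden ``true_class``
used only for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from shapely.geometry.base import BaseGeometry

from .errors import GeometryError

NATURAL = "natural"
SEMI_DEGRADED = "semi-degraded"
DEGRADED = "degraded"

#: Ordering used for "worst class wins" reductions.
CLASS_ORDER = {NATURAL: 0, SEMI_DEGRADED: 1, DEGRADED: 2}
CLASSES = (NATURAL, SEMI_DEGRADED, DEGRADED)

#: Accepted geometry types per ecosystem kind.
GEOMETRY_BY_KIND = {
    "grassland": ("Polygon", "MultiPolygon"),
    "forest": ("Polygon", "MultiPolygon"),
    "lake": ("Polygon", "MultiPolygon"),
    "coastal": ("Polygon", "MultiPolygon"),
    "river": ("LineString", "MultiLineString"),
    "cave": ("Point",),
}

KINDS = tuple(GEOMETRY_BY_KIND)


@dataclass
class EcosystemFeature:
    """One spatial unit of an ecosystem with its criterion attributes."""

    feature_id: str
    kind: str
    geometry: BaseGeometry
    attributes: dict = field(default_factory=dict)
    true_class: str | None = None
    score: float | None = None
    degradation_class: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in GEOMETRY_BY_KIND:
            raise GeometryError(f"unknown ecosystem kind: {self.kind!r}")
        allowed = GEOMETRY_BY_KIND[self.kind]
        if self.geometry.geom_type not in allowed:
            raise GeometryError(
                f"kind '{self.kind}' requires geometry in {allowed}, "
                f"got {self.geometry.geom_type}"
            )


def worst_class(classes) -> str:
    """Return the most degraded class among ``classes`` (max by severity)."""
    return max(classes, key=CLASS_ORDER.__getitem__)
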