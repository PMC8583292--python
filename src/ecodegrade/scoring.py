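"""Generic declarative weighted-score engine for ecosystem classification.

A :class:`ScoringScheme` is an ordered list of :class:`CriterionSpec` entries
plus two cut-points that turn the weighted aggregate into a three-way
degradation class. Two criterion modes exist:

``banded``
    The raw attribute is mapped to a 0/1/2 condition score by two threshold
    values. The middle band is a *closed* interval: printed band triplets of
    the form ``>b = natural, a–b = semi-degraded, <a = degraded`` are read
    with both endpoints belonging to the semi-degraded band, and the outer
    bands strict.

``raw``
    The attribute already is a score (e.g. the cave impact and vulnerability
    form totals) and enters the aggregate unchanged.

The aggregate is ``sum(weight_i * score_i)``; classification is
``aggregate <= cut1 -> natural``, ``aggregate >= cut2 -> degraded``,
semi-degraded in between. The same engine, configured with the grassland
thresholds and weights (5, 20, 5, 10, 50, 100), reproduces the grassland
Degradation Index; dedicated cave (CCI), river, lake (WRASTIC-HI-style) and
coastal schemes ship as data files.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .errors import DomainError, MissingAttributeError, SchemeError
from .features import DEGRADED, NATURAL, SEMI_DEGRADED

log = logging.getLogger(__name__)

HIGHER_IS_WORSE = "higher_is_worse"
LOWER_IS_WORSE = "lower_is_worse"
_DIRECTIONS = (HIGHER_IS_WORSE, LOWER_IS_WORSE)


@dataclass(frozen=True)
class CriterionSpec:
    """One criterion: thresholds, direction, weight and valid domain."""

    name: str
    attribute: str
    weight: float
    direction: str = HIGHER_IS_WORSE
    bands: tuple[float, float] | None = None  # (lower cut, upper cut)
    mode: str = "banded"  # "banded" | "raw"
    transform: str | None = None  # None | "abs"
    domain: tuple[float, float] = (-math.inf, math.inf)
    #: attribute sampling ranges for the synthetic generator, per true class
    simulate: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not math.isfinite(self.weight) or self.weight < 0:
            raise SchemeError(f"criterion {self.name}: weight must be finite and >= 0")
        if self.mode not in ("banded", "raw"):
            raise SchemeError(f"criterion {self.name}: unknown mode {self.mode!r}")
        if self.transform not in (None, "abs"):
            raise SchemeError(f"criterion {self.name}: unknown transform {self.transform!r}")
        if self.mode == "banded":
            if self.direction not in _DIRECTIONS:
                raise SchemeError(
                    f"criterion {self.name}: unknown direction {self.direction!r}"
                )
            if self.bands is None or len(self.bands) != 2:
                raise SchemeError(f"criterion {self.name}: banded mode needs two thresholds")
            lo, hi = self.bands
            if not lo < hi:
                raise SchemeError(
                    f"criterion {self.name}: thresholds must be strictly increasing, "
                    f"got ({lo}, {hi})"
                )
        if not self.domain[0] < self.domain[1]:
            raise SchemeError(f"criterion {self.name}: empty domain {self.domain}")

    def score(self, value: float) -> float:
        """Condition score for one attribute value (0/1/2 if banded)."""
        if not (self.domain[0] <= value <= self.domain[1]):
            raise DomainError(
                f"criterion {self.name}: value {value} outside domain {self.domain}"
            )
        v = abs(value) if self.transform == "abs" else value
        if self.mode == "raw":
            return v
        lo, hi = self.bands
        if self.direction == HIGHER_IS_WORSE:
            if v < lo:
                return 0
            return 1 if v <= hi else 2
        # lower_is_worse: large values are the natural band
        if v > hi:
            return 0
        return 1 if v >= lo else 2


@dataclass(frozen=True)
class ScoringScheme:
    """Ordered criteria plus aggregate cut-points for one ecosystem kind."""

    kind: str
    criteria: tuple[CriterionSpec, ...]
    class_cutpoints: tuple[float, float]

    def validate(self) -> "ScoringScheme":
        if not self.criteria:
            raise SchemeError("scheme needs at least one criterion")
        c1, c2 = self.class_cutpoints
        if not c1 < c2:
            raise SchemeError(
                f"class cut-points must be strictly increasing, got ({c1}, {c2})"
            )
        for crit in self.criteria:
            crit.validate()
        return self

    @property
    def attribute_names(self) -> tuple[str, ...]:
        return tuple(c.attribute for c in self.criteria)

    @classmethod
    def from_dict(cls, doc: dict) -> "ScoringScheme":
        try:
            crits = tuple(
                CriterionSpec(
                    name=c["name"],
                    attribute=c["attribute"],
                    weight=float(c["weight"]),
                    direction=c.get("direction", HIGHER_IS_WORSE),
                    bands=tuple(float(b) for b in c["bands"]) if "bands" in c else None,
                    mode=c.get("mode", "banded"),
                    transform=c.get("transform"),
                    domain=tuple(float(d) for d in c.get("domain", (-math.inf, math.inf))),
                    simulate={k: tuple(v) for k, v in c.get("simulate", {}).items()},
                )
                for c in doc["criteria"]
            )
            scheme = cls(
                kind=doc["kind"],
                criteria=crits,
                class_cutpoints=tuple(float(x) for x in doc["class_cutpoints"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemeError(f"malformed scheme document: {exc}") from exc
        return scheme.validate()

    def to_dict(self) -> dict:
        out = {"kind": self.kind, "class_cutpoints": list(self.class_cutpoints)}
        crits = []
        for c in self.criteria:
            d = {"name": c.name, "attribute": c.attribute, "weight": c.weight}
            if c.mode != "banded":
                d["mode"] = c.mode
            if c.bands is not None:
                d["bands"] = list(c.bands)
                d["direction"] = c.direction
            if c.transform:
                d["transform"] = c.transform
            if all(map(math.isfinite, c.domain)):
                d["domain"] = list(c.domain)
            if c.simulate:
                d["simulate"] = {k: list(v) for k, v in c.simulate.items()}
            crits.append(d)
        out["criteria"] = crits
        return out


@dataclass(frozen=True)
class ScoreResult:
    """Per-criterion scores, weighted aggregate and resulting class."""

    criterion_scores: tuple[float, ...]
    aggregate: float
    degradation_class: str


def classify_aggregate(aggregate: float, cutpoints: tuple[float, float]) -> str:
    """Three-way class from an aggregate score and two cut-points."""
    c1, c2 = cutpoints
    if aggregate <= c1:
        return NATURAL
    if aggregate >= c2:
        return DEGRADED
    return SEMI_DEGRADED


def apply_scheme(feature, scheme: ScoringScheme) -> ScoreResult:
    """Score one feature under a scheme; the feature is not modified.

    Raises :class:`MissingAttributeError` naming every absent attribute, and
    :class:`DomainError` when an attribute lies outside its declared domain.
    """
    missing = [c.attribute for c in scheme.criteria if c.attribute not in feature.attributes]
    if missing:
        raise MissingAttributeError(missing, kind=scheme.kind)
    scores = tuple(c.score(float(feature.attributes[c.attribute])) for c in scheme.criteria)
    aggregate = sum(w * s for w, s in zip((c.weight for c in scheme.criteria), scores))
    return ScoreResult(scores, aggregate, classify_aggregate(aggregate, scheme.class_cutpoints))


# Printed coastal aggregate bands: terrestrial <=4 natural, 5-12 semi-degraded,
# >=13 degraded; marine <=5 natural, 6-15 semi-degraded, >15 degraded.
COASTAL_CUTPOINTS = {"terrestrial": (4.0, 13.0), "marine": (5.0, 16.0)}


def classify_coastal(score: float, zone: str) -> str:
    """Degradation class of a coastal aggregate score for a given zone."""
    if zone not in COASTAL_CUTPOINTS:
        raise DomainError(f"unknown coastal zone {zone!r}; expected terrestrial or marine")
    if score < 0:
        raise DomainError(f"coastal score must be >= 0, got {score}")
    return classify_aggregate(score, COASTAL_CUTPOINTS[zone])


def batch_score(features, scheme: ScoringScheme):
    """Score a homogeneous feature collection in place.

    Returns ``(features, tally)`` where ``tally`` maps class name to count.
    """
    features = list(features)
    kinds = {f.kind for f in features}
    if len(kinds) > 1:
        raise DomainError(f"batch_score expects one ecosystem kind, got {sorted(kinds)}")
    if not features:
        log.warning("batch_score: empty input for scheme kind %s", scheme.kind)
        return features, {}
    tally = {NATURAL: 0, SEMI_DEGRADED: 0, DEGRADED: 0}
    for f in features:
        res = apply_scheme(f, scheme)
        f.score = res.aggregate
        f.degradation_class = res.degradation_class
        tally[res.degradation_class] += 1
    return features, {k: v for k, v in tally.items() if v or True}
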