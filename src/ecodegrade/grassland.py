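"""Grassland Degradation Index (DI).

Six criteria describe anthropo-zoogenic impact (distance to localities,
distance to sheepfolds, livestock-density deviation), stationary conditions
(slope) and structure (invasive-species cover, bare soil / erosion). Each is
banded into a condition score — 0 natural, 1 semi-degraded, 2 degraded — and
combined as

    DI = 5*s1 + 20*s2 + 5*s3 + 10*s4 + 50*s5 + 100*s6

so DI is a multiple of 5 in [0, 380]. Parcels classify as natural for
DI <= 30, semi-degraded for 31-64 and degraded for DI >= 65. The livestock
criterion is a signed percent deviation from the sustainable stocking rate;
its magnitude is banded (<10 natural, 10-30 semi-degraded, >30 degraded).

Criterion bands (closed middle interval, outer bands strict):

====  ======================  ============  ==============  ===========
id    attribute               natural (0)   semi (1)        degraded (2)
====  ======================  ============  ==============  ===========
C1    dist_locality_km        > 4           2 - 4           < 2
C2    dist_sheepfold_km       > 2           0.5 - 2         < 0.5
C3    slope_deg               < 15          15 - 30         > 30
C4    |livestock_dev_pct|     < 10          10 - 30         > 30
C5    invasive_pct            < 5           5 - 20          > 20
C6    bare_soil_pct           < 5           5 - 20          > 20
====  ======================  ============  ==============  ===========
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError
from .scoring import CriterionSpec, classify_aggregate

DI_WEIGHTS = (5, 20, 5, 10, 50, 100)
DI_CUTPOINTS = (30.0, 65.0)
DI_MAX = 2 * sum(DI_WEIGHTS)  # 380

#: The six criteria, in DI order, as engine specs (shared with the bundled scheme).
CRITERIA = (
    CriterionSpec("proximity_to_localities", "dist_locality_km", 5,
                  direction="lower_is_worse", bands=(2.0, 4.0), domain=(0.0, float("inf"))),
    CriterionSpec("proximity_to_sheepfolds", "dist_sheepfold_km", 20,
                  direction="lower_is_worse", bands=(0.5, 2.0), domain=(0.0, float("inf"))),
    CriterionSpec("slope", "slope_deg", 5,
                  direction="higher_is_worse", bands=(15.0, 30.0), domain=(0.0, 90.0)),
    CriterionSpec("livestock_density_deviation", "livestock_dev_pct", 10,
                  direction="higher_is_worse", bands=(10.0, 30.0), transform="abs"),
    CriterionSpec("invasive_species", "invasive_pct", 50,
                  direction="higher_is_worse", bands=(5.0, 20.0), domain=(0.0, 100.0)),
    CriterionSpec("bare_soil", "bare_soil_pct", 100,
                  direction="higher_is_worse", bands=(5.0, 20.0), domain=(0.0, 100.0)),
)

CRITERION_IDS = ("C1", "C2", "C3", "C4", "C5", "C6")
_BY_ID = dict(zip(CRITERION_IDS, CRITERIA))

#: Attribute columns a grassland feature must carry.
ATTRIBUTES = tuple(c.attribute for c in CRITERIA)


@dataclass(frozen=True)
class DIResult:
    criterion_scores: tuple[int, int, int, int, int, int]
    di: int
    di_class: str


def score_criterion(value: float, criterion: str) -> int:
    """Band one criterion value into a 0/1/2 condition score.

    ``criterion`` is one of C1..C6. Boundary values fall in the closed
    semi-degraded middle band.
    """
    if criterion not in _BY_ID:
        raise DomainError(f"unknown criterion id {criterion!r}; expected C1..C6")
    return int(_BY_ID[criterion].score(value))


def compute_di(scores) -> int:
    """Weighted sum of the six condition scores (weights 5,20,5,10,50,100)."""
    scores = tuple(scores)
    if len(scores) != 6:
        raise DomainError(f"expected 6 criterion scores, got {len(scores)}")
    for s in scores:
        if s not in (0, 1, 2):
            raise DomainError(f"criterion scores must be in {{0,1,2}}, got {s}")
    return sum(w * s for w, s in zip(DI_WEIGHTS, scores))


def classify_di(di: float) -> str:
    """Degradation class of a DI value: <=30 natural, >=65 degraded.

    The gaps 31-34 and 61-64 are unreachable for valid score combinations
    (DI is a multiple of 5); they classify as semi-degraded so the function
    is total over non-negative integers.
    """
    if di < 0:
        raise DomainError(f"DI must be >= 0, got {di}")
    return classify_aggregate(di, DI_CUTPOINTS)


def score_parcel(attributes: dict) -> DIResult:
    """Score one parcel's attribute mapping through all six criteria."""
    scores = tuple(int(c.score(float(attributes[c.attribute]))) for c in CRITERIA)
    di = compute_di(scores)
    return DIResult(scores, di, classify_di(di))
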