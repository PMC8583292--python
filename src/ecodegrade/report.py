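"""Per-ecosystem class summaries and zonal classification tables.

Two tabular products close the pipeline: a per-ecosystem summary of class
totals in each ecosystem's native unit (km² for areal ecosystems, km of
length for rivers, feature counts for caves) with percentage shares, and a
zonal table giving, for each region polygon, the area and share falling in
each class of the combined degradation-density grid.
"""

from __future__ import annotations

import logging
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from shapely.geometry import box

from .errors import DomainError
from .features import CLASSES, DEGRADED, NATURAL, SEMI_DEGRADED
from .grid import Grid

log = logging.getLogger(__name__)

#: Native summary unit per ecosystem kind.
UNIT_BY_KIND = {
    "forest": "area", "grassland": "area", "lake": "area", "coastal": "area",
    "river": "length", "cave": "count",
}


def class_percentages(part: float, total: float) -> float:
    """Percentage share 100*part/total, rounded half-up to 2 decimals."""
    part, total = float(part), float(total)
    if total <= 0:
        raise DomainError(f"total must be > 0, got {total}")
    if not 0 <= part <= total:
        raise DomainError(f"part {part} outside [0, {total}]")
    pct = Decimal(100) * Decimal(repr(part)) / Decimal(repr(total))
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _native_amount(feature, unit: str) -> float:
    if unit == "area":
        return feature.geometry.area / 1e6  # km²
    if unit == "length":
        return feature.geometry.length / 1000.0  # km
    if unit == "count":
        return 1.0
    raise DomainError(f"unknown unit {unit!r}")


def summarize_classes(features, unit: str | None = None) -> dict:
    """One summary row: per-class native-unit totals, shares and grand total.

    ``unit`` defaults to the ecosystem kind's native unit (area for
    polygons, length for rivers, count for caves).
    """
    features = list(features)
    if not features:
        log.warning("summarize_classes: empty input, zero row")
        row = {c: 0.0 for c in CLASSES}
        return {**row, **{f"{c}_pct": 0.0 for c in CLASSES}, "total": 0.0, "unit": unit}
    kinds = {f.kind for f in features}
    if len(kinds) > 1:
        raise DomainError(f"summarize_classes expects one ecosystem kind, got {sorted(kinds)}")
    kind = kinds.pop()
    if unit is None:
        unit = UNIT_BY_KIND[kind]
    totals = {c: 0.0 for c in CLASSES}
    for f in features:
        if f.degradation_class not in totals:
            raise DomainError(f"feature {f.feature_id} is not classified")
        totals[f.degradation_class] += _native_amount(f, unit)
    grand = sum(totals.values())
    row = dict(totals)
    for c in CLASSES:
        row[f"{c}_pct"] = class_percentages(totals[c], grand) if grand > 0 else 0.0
    row["total"] = grand
    row["unit"] = unit
    row["kind"] = kind
    return row


def summary_table(features_by_kind: dict) -> pd.DataFrame:
    """Per-ecosystem summary rows (natural / semi-degraded / degraded)."""
    rows = []
    for kind, feats in features_by_kind.items():
        row = summarize_classes(feats)
        row.setdefault("kind", kind)
        rows.append(row)
    cols = ["kind", "unit", NATURAL, f"{NATURAL}_pct", SEMI_DEGRADED,
            f"{SEMI_DEGRADED}_pct", DEGRADED, f"{DEGRADED}_pct", "total"]
    return pd.DataFrame(rows)[cols]


def zonal_summary(class_grid: Grid, regions, class_labels=None) -> pd.DataFrame:
    """Area (km²) and share per combined-degradation class for each region.

    ``class_grid`` holds small-integer class codes (e.g. 0/1/2 for the
    low/medium/high natural-breaks classes of the summed density layer);
    ``regions`` is an iterable of (name, polygon) pairs. Cell/region overlap
    uses exact polygon intersection, so a region straddling cells is split
    proportionally. Regions outside the grid yield a zero row and a warning.
    """
    vals = np.asarray(class_grid.values)
    codes = sorted(int(c) for c in np.unique(vals[np.isfinite(vals)]))
    labels = class_labels or {c: str(c) for c in codes}
    rows = []
    grid_box = box(*class_grid.extent)
    for name, poly in regions:
        areas = {labels[c]: 0.0 for c in codes}
        if not poly.intersects(grid_box):
            log.warning("zonal_summary: region %s lies outside the grid", name)
        else:
            xmin, ymin, xmax, ymax = poly.bounds
            r0, c0 = class_grid.cell_index(xmin, ymax)
            r1, c1 = class_grid.cell_index(xmax, ymin)
            for r in range(max(r0, 0), min(r1, class_grid.nrows - 1) + 1):
                for c in range(max(c0, 0), min(c1, class_grid.ncols - 1) + 1):
                    cell = box(*class_grid.cell_bounds(r, c))
                    inter_area = poly.intersection(cell).area
                    if inter_area > 0:
                        areas[labels[int(vals[r, c])]] += inter_area / 1e6
        total = sum(areas.values())
        row = {"region": name, "total_km2": total}
        for lab, a in areas.items():
            row[f"{lab}_km2"] = a
            row[f"{lab}_pct"] = class_percentages(a, total) if total > 0 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
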