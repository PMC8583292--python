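# Methods

This note records the scientific and numerical choices behind the package:
what each stage computes, which parameters matter, what the synthetic
landscapes do and do not emulate, and where the design was genuinely open.

## Scoring model

All six ecosystems share one engine: an ordered list of criteria, each
mapping a raw attribute to a condition score, a weighted sum, and two
cut-points that turn the aggregate into natural / semi-degraded / degraded.

**Band convention.** Printed band triplets of the form
">4 km natural, 2–4 km semi-degraded, <2 km degraded" leave the endpoints
ambiguous. We read the middle band as a *closed* interval (both endpoints
semi-degraded) and the outer bands strict, because the middle bands are
printed as dashed ranges while the outer bands carry strict inequalities.
The convention is applied uniformly across every scheme.

**Grassland DI.** Weights (5, 20, 5, 10, 50, 100) over criteria C1–C6, class
cuts at 30 and 65. DI is a multiple of 5 in [0, 380]; the integer gaps 31–34
and 61–64 are unreachable for valid scores (verified by exhaustive
enumeration of all 3⁶ = 729 combinations) but classify as semi-degraded so
the function is total. Two source inconsistencies are resolved as follows:
the livestock criterion's printed bands ("±10–50% semi, >±30% degraded")
overlap — we band the magnitude as <10 → 0, 10–30 → 1, >30 → 2, honoring
the degraded trigger; and the printed degraded range "65–180" understates
the attainable maximum 380 — only the lower bound 65 is used.

**Cave CCI.** The impact and vulnerability form totals are upstream field
products; the engine consumes them as raw scores, sums them, and applies the
published cuts 34/85. The forms' internal items are out of scope.

**River scheme.** 13 criteria in four groups (riparian human pressure,
adjacent-land substrate, in-channel condition, morphological complexity).
The source method publishes which six indicators carry the highest weight
but not the numbers; we assign those six weight 2 and the rest weight 1
(aggregate range 0–38, cuts 12/25) as a documented, overridable stand-in.
The thirteenth criterion (dams/barriers) reflects the dams-on-rivers layer
in the method's data inventory; the published list names twelve explicitly.

**Lake composite.** The wastewater / recreation / agriculture / size /
transport / industry / land-cover / vulnerability components are published
in separate component indices we do not reimplement; each arrives as a 0–10
pressure score, banded 0/1/2 at 3/6 with weight 1, cuts 5/11 — again an
explicit, overridable stand-in for unpublished constants.

**Coastal sums.** Eight indicators banded 0/1/2, weight 1. Terrestrial cuts
4/13: the printed bands leave the value 13 unassigned ("5–12" vs ">13"),
which we close on the degraded side. The printed marine bands overlap
("5–15 semi, >13 degraded"); we use ≤5 / 6–15 / >15, keeping the bands
exhaustive and disjoint.

## Forest canopy trend

Per-pixel unweighted OLS of percent canopy against calendar year (≥3 valid
epochs; fewer makes the pixel nodata, never an exception). A pixel is
degraded when slope × (last − first year) < −10 percentage points — an
*absolute* drop, since the input is already a percent; a relative rule would
be a configuration change. An optional mean-canopy mask (default 30–80%)
restricts the analysis to the band in which canopy-cover products resolve
forest reliably. The estimator is deliberately the simplest trend fit
compatible with the method description; a robust alternative (Theil–Sen)
could be swapped behind the same interface. Land-use conversion is a
cell-wise comparison of two aligned categorical rasters, labeling
forest→non-forest cells with the destination category.

## Density and Gi* hotspots

Densities are per-cell amounts (point count, clipped line length in km,
clipped polygon area in km²) divided by the cell area in km². Defaults:
1 km cells, five quantile classes for the per-ecosystem score (ties broken
toward the lower class; a degenerate equal-interval range collapses to
class 1), cells with no ecosystem presence score 0 so absent ecosystems
contribute nothing to the sum — consistent with combined scores observed
well below the theoretical maximum when few ecosystems overlap.

Gi\* uses binary fixed-distance-band weights on cell centers, self-inclusive
(the conventional "star" form), with the population standard deviation
S = √(Σx²/n − X̄²) and variance term [nΣw² − (Σw)²]/(n−1). A constant field
(S = 0) defines z = 0 everywhere. The implementation is convolution-based
and is verified against an independent direct-summation double loop to
1e-10 on random grids; under value permutation the empirical fraction of
|z| > 1.96 sits at ~4.9% (nominal 5%). The neighborhood radius (default
2 km = 2 cells) is a config parameter; the source workflow used a desktop
GIS default it does not document, as is its grid cell size.

Natural breaks are computed by exact dynamic programming over the sorted
values (Fisher's method, O(kn²) with a vectorized inner loop), returning
class maxima as break values; results match exhaustive enumeration of all
partitions for n ≤ 12.

## Validation protocol

About 100 ground-truth points per ecosystem, each assessed within a 300 m
buffer: the prediction is the *worst* class (and highest aggregate score)
among features intersecting the buffer; empty-buffer points are flagged and
excluded. The binary reduction treats semi-degraded as not-degraded
(configurable). The ROC ranks by the continuous aggregate score — more
informative than the 3-class label, which was the open alternative — and
the AUC equals the tie-corrected Mann–Whitney statistic (verified to 1e-12).
AUC ≥ 0.800 is reported as a "strong" verdict, as a label only, never
enforced.

## Synthetic landscapes

The generator is class-conditional: a feature first draws its hidden truth
(Bernoulli with the requested prevalence), then draws each attribute
uniformly inside a band consistent with that truth, so every threshold class
is constructible and prevalence is a direct parameter. Degraded features are
placed in Gaussian clusters (default 3 clusters, sd 2.5 km over a 50 km
square) around uniform centers; `cluster_count=0` gives the spatially
uniform null landscape. Grassland non-degraded parcels mix natural and
semi-degraded bands of the three low-weight criteria (their weights sum to
exactly 30, the natural cut) so sub-degraded variation exists without ever
crossing the class boundary; degraded parcels always take a degraded
bare-soil band, which alone forces DI ≥ 200. Canopy stacks hold intact
pixels flat (base uniform 35–75%) and degraded pixels on a linear decline
of 12–25 points (default) with Gaussian noise (sd 2 points); the degraded
mask takes the prevalence-quantile of distance-to-nearest-cluster-center, so
the realized pixel prevalence is exact. All randomness flows from a single
seed through fixed per-stage child streams, so identical seeds give
byte-identical output files.

What this does *not* emulate: real geography, real attribute correlation
structure (attributes are independent given the class), semi-degraded truth
states, misclassified features, or sensor radiometry. Consequently the
synthetic validation AUCs are ~1.0 by construction — passing tests show the
pipeline recovers planted structure faithfully, not that any real map would
validate at that level; the published field AUCs (~0.8–0.92) depend on
national data and field campaigns outside this package's scope.

## Numerical choices and degenerate inputs

- Percent shares are rounded half-up to two decimals (matching the printed
  tables' style); unrounded values are preserved in machine outputs.
- Geographic (lon/lat-looking) coordinates are rejected, not reprojected:
  all distances, areas and densities assume planar meters.
- ASCII-grid rasters carry NODATA = −9999; non-finite Gi\* inputs propagate
  to "not significant" bins with a warning rather than failing.
- Quantile ties break low; all-zero density grids warn and score 0.
- Aggregate classification is ≤cut₁ natural / ≥cut₂ degraded, applied
  identically everywhere so boundary behavior is uniform.

## Problem sizes

Default study conditions: 800 features per ecosystem on a 50 × 50 km extent
(1 km cells, 2 km Gi\* band), 1000 features for prevalence recovery, 40 × 40
canopy pixels × 14 years, 100 validation points per ecosystem, 200
permutations for null calibrations. These sizes give stable statistics while
keeping any full run in seconds.

## Known limitations

- The river and lake scheme constants are stand-ins (see above); national
  results are not reproducible without the original weights and data.
- Line/polygon rasterization clips per cell with exact geometry and scales
  as features × bbox cells; very large landscapes would want an indexed
  implementation.
- Gi\* significance is unadjusted for multiple testing, matching the source
  workflow; the null-calibration tests quantify the consequence.
- The published summary contains three internally inconsistent percentage
  cells (river degraded, coastal degraded, cave degraded by 0.01); the
  reporting module recomputes shares from totals and does not attempt to
  reproduce them.
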