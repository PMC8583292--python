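# ecodegrade

National-scale ecosystem degradation assessment as a reusable, testable
pipeline. The package implements the full analysis chain used to map
degraded ecosystems across a country — six ecosystem types (forest,
grassland, cave, river, lake, coastal), each with its own degradation
scoring scheme — and exercises it end to end on synthetic landscapes with
known ground truth, since the national input datasets (LPIS, CORINE,
canopy-cover satellite products, cave survey forms, ...) are not
redistributable.

It is written for landscape ecologists and GIS analysts who want the
*method* — composite degradation indices, degraded-feature density surfaces,
Getis–Ord Gi\* hotspot detection, natural-breaks classing and ROC
validation — as inspectable, seedable code rather than a chain of desktop-GIS
tool runs.

## The method

**Per-ecosystem scoring.** Each ecosystem unit (parcel, reach, cave, lake,
coastal segment) is scored by a declarative weighted scheme. Grassland uses
the six-criterion Degradation Index

    DI = 5·C1 + 20·C2 + 5·C3 + 10·C4 + 50·C5 + 100·C6

where each criterion score Ci ∈ {0, 1, 2} (natural / semi-degraded /
degraded) comes from banding distance-to-locality, distance-to-sheepfold,
slope, livestock-density deviation, invasive-species cover and bare-soil
cover; DI ≤ 30 is natural, DI ≥ 65 degraded. Caves sum an impact and a
vulnerability form score (CCI, cut at 34/85); rivers use a 13-criterion
multicriteria scheme; lakes a WRASTIC-HI-style composite; coastal areas an
8-indicator sum (terrestrial cuts 4/13, marine 5/16). All schemes are YAML
data files under `src/ecodegrade/schemes/` and fully overridable. Forest
degradation is flagged per pixel from a multi-year canopy-cover stack: the
OLS trend of percent canopy against year, flagged where the fitted loss over
the span exceeds 10 percentage points.

**Density + hotspots.** Degraded features are rasterized to per-km² density
on a common grid (counts for caves, clipped length for rivers, clipped area
for the rest), scored into five quantile classes (1 very low … 5 very high,
0 where absent), and summed across ecosystems. The Getis–Ord Gi\* statistic

    Gi* = [Σⱼ wᵢⱼxⱼ − X̄ Σⱼ wᵢⱼ] / (S·√([n Σⱼ wᵢⱼ² − (Σⱼ wᵢⱼ)²]/(n−1)))

with binary self-inclusive distance-band weights turns each layer into a
z-score surface with 90/95/99% hot/cold confidence bins. The summed layer is
classed low/medium/high by Jenks natural breaks and summarized per region
polygon.

**Validation.** Ground-truth points (≈100 per ecosystem) are assessed in a
300 m buffer; the worst feature class in the buffer is the model prediction.
Accuracy is reported as a binary confusion matrix and the ROC AUC of the
continuous aggregate score, with AUC ≥ 0.8 labeled a strong model.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
50 × 50 km landscape (800 features per ecosystem, degradation prevalence
0.3 clustered around 3 centers, 14-year canopy stack):

```bash
python analysis/01_simulate_landscape.py --seed 42
python analysis/02_score_ecosystems.py
python analysis/03_density_hotspots.py
python analysis/04_validate_roc.py
python analysis/05_worked_example.py
```

Stage 02 prints the per-ecosystem class summary (native units, shares):

```
     kind   unit     natural  natural_pct  degraded  degraded_pct       total
grassland   area  241.391452        70.75 99.793181         29.25  341.184633
     cave  count  586.000000        73.25 214.00000         26.75  800.000000
    river length 2467.926710        72.28 946.47162         27.72 3414.398331
forest: 19.8% of pixels flagged degraded (sensitivity vs truth 99.2%)
```

Stage 03 finds the planted hotspots (e.g. `grassland: 218 hot99 cells,
max z = 15.7`) and classes the combined surface at natural breaks
`[2.0, 6.0]`; stage 04 validates every map at `AUC = 1.000 (strong)` —
expected here, because attributes are drawn class-conditionally so the only
recoverable error is spatial. Tables land under `results/`, large
regenerable layers under `scratch/`.

The same stages are exposed as a CLI for ad-hoc runs:
`ecodegrade simulate|score|density|hotspot|validate|report --help`.

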