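# Grassland Degradation Index: six banded criteria, weights 5/20/5/10/50/100,
# aggregate classed at 30 (natural) and 65 (degraded).
kind: grassland
class_cutpoints: [30, 65]
criteria:
  - name: proximity_to_localities
    attribute: dist_locality_km
    direction: lower_is_worse
    bands: [2.0, 4.0]
    weight: 5
    domain: [0, .inf]
    simulate: {natural: [4.2, 12.0], degraded: [0.0, 1.9]}
  - name: proximity_to_sheepfolds
    attribute: dist_sheepfold_km
    direction: lower_is_worse
    bands: [0.5, 2.0]
    weight: 20
    domain: [0, .inf]
    simulate: {natural: [2.1, 8.0], degraded: [0.0, 0.45]}
  - name: slope
    attribute: slope_deg
    direction: higher_is_worse
    bands: [15.0, 30.0]
    weight: 5
    domain: [0, 90]
    simulate: {natural: [0.0, 14.5], degraded: [31.0, 45.0]}
  - name: livestock_density_deviation
    attribute: livestock_dev_pct
    direction: higher_is_worse
    transform: abs
    bands: [10.0, 30.0]
    weight: 10
    domain: [-200, 200]
    simulate: {natural: [-9.5, 9.5], degraded: [31.0, 120.0]}
  - name: invasive_species
    attribute: invasive_pct
    direction: higher_is_worse
    bands: [5.0, 20.0]
    weight: 50
    domain: [0, 100]
    simulate: {natural: [0.0, 4.8], degraded: [21.0, 70.0]}
  - name: bare_soil
    attribute: bare_soil_pct
    direction: higher_is_worse
    bands: [5.0, 20.0]
    weight: 100
    domain: [0, 100]
    simulate: {natural: [0.0, 4.8], degraded: [21.0, 70.0]}
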