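# River multicriteria scheme: 13 banded criteria in four groups —
# A. human pressure on riparian areas, B. adjacent-land substrate,
# C. in-channel condition, D. morphological complexity. The six indicators
# reported as carrying the highest importance (riparian anthropization,
# riparian vegetation cover, major pollution sources, transport-network
# length, bank interventions, ecological status) take weight 2, the other
# seven weight 1. The numeric weights and the aggregate cut-points are a
# documented stand-in (the source method publishes the ordering of
# importance, not the numbers) and are fully config-overridable.
# Aggregate range 0-38; <= 12 natural, >= 25 degraded.
kind: river
class_cutpoints: [12, 25]
criteria:
  # A. human pressure on riparian areas
  - name: riparian_anthropization
    attribute: anthropization_pct
    direction: higher_is_worse
    bands: [10.0, 30.0]
    weight: 2
    domain: [0, 100]
    simulate: {natural: [0.0, 9.5], degraded: [31.0, 90.0]}
  - name: riparian_vegetation_cover
    attribute: riparian_veg_pct
    direction: lower_is_worse
    bands: [40.0, 70.0]
    weight: 2
    domain: [0, 100]
    simulate: {natural: [71.0, 100.0], degraded: [0.0, 39.0]}
  - name: settlements
    attribute: settlement_density
    direction: higher_is_worse
    bands: [2.0, 8.0]
    weight: 1
    domain: [0, .inf]
    simulate: {natural: [0.0, 1.9], degraded: [8.5, 30.0]}
  - name: sewage_treatment_plants
    attribute: treatment_plant_count
    direction: higher_is_worse
    bands: [1.0, 3.0]
    weight: 1
    domain: [0, .inf]
    simulate: {natural: [0.0, 0.9], degraded: [3.5, 10.0]}
  - name: major_pollution_sources
    attribute: pollution_source_count
    direction: higher_is_worse
    bands: [1.0, 3.0]
    weight: 2
    domain: [0, .inf]
    simulate: {natural: [0.0, 0.9], degraded: [3.5, 10.0]}
  - name: transport_network
    attribute: transport_km_per_km
    direction: higher_is_worse
    bands: [0.5, 2.0]
    weight: 2
    domain: [0, .inf]
    simulate: {natural: [0.0, 0.45], degraded: [2.1, 8.0]}
  - name: protected_area_share
    attribute: protected_pct
    direction: lower_is_worse
    bands: [20.0, 50.0]
    weight: 1
    domain: [0, 100]
    simulate: {natural: [51.0, 100.0], degraded: [0.0, 19.0]}
  # B. substrate of the adjacent land
  - name: adjacent_slope
    attribute: adjacent_slope_deg
    direction: higher_is_worse
    bands: [10.0, 25.0]
    weight: 1
    domain: [0, 90]
    simulate: {natural: [0.0, 9.5], degraded: [26.0, 45.0]}
  - name: soil_permeability
    attribute: permeability_index
    direction: lower_is_worse
    bands: [30.0, 60.0]
    weight: 1
    domain: [0, 100]
    simulate: {natural: [61.0, 100.0], degraded: [0.0, 29.0]}
  # C. in-channel condition
  - name: bank_interventions
    attribute: bank_intervention_pct
    direction: higher_is_worse
    bands: [10.0, 30.0]
    weight: 2
    domain: [0, 100]
    simulate: {natural: [0.0, 9.5], degraded: [31.0, 95.0]}
  - name: ecological_status
    attribute: ecological_status_score
    direction: higher_is_worse
    bands: [2.0, 3.5]
    weight: 2
    domain: [1, 5]
    simulate: {natural: [1.0, 1.9], degraded: [3.6, 5.0]}
  # D. morphological complexity
  - name: sinuosity
    attribute: sinuosity_ratio
    direction: lower_is_worse
    bands: [1.1, 1.3]
    weight: 1
    domain: [1, .inf]
    simulate: {natural: [1.35, 2.5], degraded: [1.0, 1.08]}
  - name: dams_and_barriers
    attribute: barrier_count
    direction: higher_is_worse
    bands: [1.0, 2.0]
    weight: 1
    domain: [0, .inf]
    simulate: {natural: [0.0, 0.9], degraded: [2.5, 8.0]}
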