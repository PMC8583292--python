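# Terrestrial coastal scheme: eight indicators (biological,
# hydro-morphological, physical-chemical/infrastructure groups), each banded
# 0/1/2 with weight 1 and summed; aggregate <= 4 natural, 5-12
# semi-degraded, >= 13 degraded (13, unassigned by the printed bands, closes
# the gap on the degraded side).
kind: coastal
class_cutpoints: [4, 13]
criteria:
  - name: invasive_species
    attribute: invasive_pct
    direction: higher_is_worse
    bands: [5.0, 20.0]
    weight: 1
    domain: [0, 100]
    simulate: {natural: [0.0, 4.8], degraded: [21.0, 80.0]}
  - name: wastewater_plants
    attribute: wastewater_plant_count
    direction: higher_is_worse
    bands: [1.0, 3.0]
    weight: 1
    domain: [0, .inf]
    simulate: {natural: [0.0, 0.9], degraded: [3.5, 10.0]}
  - name: demographic_poles
    attribute: demographic_pole_count
    direction: higher_is_worse
    bands: [1.0, 2.0]
    weight: 1
    domain: [0, .inf]
    simulate: {natural: [0.0, 0.9], degraded: [2.5, 8.0]}
  - name: shoreline_artificialization
    attribute: artificial_shoreline_pct
    direction: higher_is_worse
    bands: [10.0, 40.0]
    weight: 1
    domain: [0, 100]
    simulate: {natural: [0.0, 9.5], degraded: [41.0, 95.0]}
  - name: shoreline_erosion
    attribute: erosion_rate_m_yr
    direction: higher_is_worse
    bands: [0.5, 2.0]
    weight: 1
    domain: [0, .inf]
    simulate: {natural: [0.0, 0.45], degraded: [2.1, 6.0]}
  - name: road_infrastructure
    attribute: road_km_per_km2
    direction: higher_is_worse
    bands: [0.5, 2.0]
    weight: 1
    domain: [0, .inf]
    simulate: {natural: [0.0, 0.45], degraded: [2.1, 8.0]}
  - name: navigation_channels
    attribute: navigation_channel_count
    direction: higher_is_worse
    bands: [1.0, 2.0]
    weight: 1
    domain: [0, .inf]
    simulate: {natural: [0.0, 0.9], degraded: [2.5, 6.0]}
  - name: maritime_traffic
    attribute: traffic_intensity_score
    direction: higher_is_worse
    bands: [3.0, 6.0]
    weight: 1
    domain: [0, 10]
    simulate: {natural: [0.0, 2.8], degraded: [6.2, 10.0]}
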