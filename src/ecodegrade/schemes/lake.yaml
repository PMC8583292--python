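# Lake composite (WRASTIC-HI style): wastewater, recreational, agricultural,
# size, transportation, industrial and land-cover pollutant-load components
# plus a lake-vulnerability term. Each component arrives as a 0-10 pressure
# score (the component indices themselves are computed upstream of this
# package) and is banded 0/1/2; equal weights. The band edges and the
# aggregate cut-points (aggregate range 0-16; <= 5 natural, >= 11 degraded)
# are a documented stand-in and are config-overridable.
kind: lake
class_cutpoints: [5, 11]
criteria:
  - name: wastewater
    attribute: wastewater_score
    direction: higher_is_worse
    bands: [3.0, 6.0]
    weight: 1
    domain: [0, 10]
    simulate: {natural: [0.0, 2.8], degraded: [6.2, 10.0]}
  - name: recreation
    attribute: recreation_score
    direction: higher_is_worse
    bands: [3.0, 6.0]
    weight: 1
    domain: [0, 10]
    simulate: {natural: [0.0, 2.8], degraded: [6.2, 10.0]}
  - name: agriculture
    attribute: agriculture_score
    direction: higher_is_worse
    bands: [3.0, 6.0]
    weight: 1
    domain: [0, 10]
    simulate: {natural: [0.0, 2.8], degraded: [6.2, 10.0]}
  - name: size_pressure
    attribute: size_score
    direction: higher_is_worse
    bands: [3.0, 6.0]
    weight: 1
    domain: [0, 10]
    simulate: {natural: [0.0, 2.8], degraded: [6.2, 10.0]}
  - name: transportation
    attribute: transport_score
    direction: higher_is_worse
    bands: [3.0, 6.0]
    weight: 1
    domain: [0, 10]
    simulate: {natural: [0.0, 2.8], degraded: [6.2, 10.0]}
  - name: industry
    attribute: industry_score
    direction: higher_is_worse
    bands: [3.0, 6.0]
    weight: 1
    domain: [0, 10]
    simulate: {natural: [0.0, 2.8], degraded: [6.2, 10.0]}
  - name: land_cover
    attribute: cover_score
    direction: higher_is_worse
    bands: [3.0, 6.0]
    weight: 1
    domain: [0, 10]
    simulate: {natural: [0.0, 2.8], degraded: [6.2, 10.0]}
  - name: vulnerability
    attribute: vulnerability_score
    direction: higher_is_worse
    bands: [3.0, 6.0]
    weight: 1
    domain: [0, 10]
    simulate: {natural: [0.0, 2.8], degraded: [6.2, 10.0]}
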