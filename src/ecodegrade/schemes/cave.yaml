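# Cave Conservation Index (CCI): the environmental-impact rapid-assessment
# total and the vulnerability-form total are consumed as raw scores and
# summed; aggregate <= 34 natural, 35-84 semi-degraded, >= 85 degraded.
kind: cave
class_cutpoints: [34, 85]
criteria:
  - name: environmental_impact
    attribute: impact_score
    mode: raw
    weight: 1
    domain: [0, 100]
    simulate: {natural: [2.0, 15.0], degraded: [50.0, 90.0]}
  - name: vulnerability
    attribute: vulnerability_score
    mode: raw
    weight: 1
    domain: [0, 100]
    simulate: {natural: [2.0, 15.0], degraded: [40.0, 80.0]}
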