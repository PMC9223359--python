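# Default scoring criteria for the 16 riverine health indicators.
#
# anchors map score -> raw threshold.  units: "percent" means thresholds
# (and the matching observations) are percentages, converted to fractions
# on load; observations themselves are always fractions internally.
indicators:
  - id: C1
    name: Flow deviation
    criterion: Hydrology
    subsystem: natural
    rule: ladder
    orientation: cost
    anchors: {1.0: 0.05, 0.8: 0.1, 0.6: 0.3, 0.4: 0.8, 0.2: 2.0, 0.0: 5.0}

  - id: C2
    name: Ecological flow satisfaction
    criterion: Hydrology
    subsystem: natural
    rule: composite_min
    orientation: benefit
    units: percent
    components:
      # spawning-period (EF1) and normal-period (EF2) environmental flow
      # guarantee; below the lowest threshold the score steps to 0
      EF1: {1.0: 50, 0.8: 40, 0.4: 30, 0.2: 10, 0.0: 10}
      EF2: {1.0: 30, 0.8: 20, 0.4: 10, 0.2: 5, 0.0: 5}
    notes: >
      Components combined by the minimum (conservative satisfaction of both
      flow periods).

  - id: C3
    name: Riparian status
    criterion: Physical form
    subsystem: natural
    rule: passthrough
    notes: >
      Composite of riverbank stability, fractional vegetation cover and
      riparian disturbance, pre-scored per the national river and lake
      health assessment guide; consumed here as a ready [0, 1] score.

  - id: C4
    name: River connectivity
    criterion: Physical form
    subsystem: natural
    rule: ladder
    orientation: cost
    anchors: {1.0: 0.0, 0.6: 0.25, 0.4: 0.5}
    notes: >
      The published criteria row for this indicator is internally
      inconsistent (thresholds 0.2 and 0 below score 0.4 reverse the cost
      ordering); the shipped ladder keeps the monotone prefix and scores
      clamp at 0.4 for values of 0.5 and above.

  - id: C5
    name: Wetland retention
    criterion: Physical form
    subsystem: natural
    rule: ladder
    orientation: benefit
    units: percent
    anchors: {1.0: 95, 0.6: 90, 0.3: 80, 0.2: 75, 0.0: 60}

  - id: C6
    name: DO concentration
    criterion: Water quality
    subsystem: natural
    rule: ladder
    orientation: benefit
    anchors: {1.0: 7.5, 0.8: 6.0, 0.6: 5.0, 0.3: 3.0, 0.0: 0.0}

  - id: C7
    name: Nutrient concentration
    criterion: Water quality
    subsystem: natural
    rule: composite_min
    orientation: cost
    components:
      CODMn: {1.0: 2, 0.8: 4, 0.6: 6, 0.3: 10, 0.0: 15}
      COD: {1.0: 15, 0.8: 17.5, 0.6: 20, 0.3: 30, 0.0: 40}
      BOD: {1.0: 3, 0.8: 3.5, 0.6: 4, 0.3: 6, 0.0: 10}
      NH3N: {1.0: 0.15, 0.8: 0.5, 0.6: 1, 0.3: 1.5, 0.0: 2}
    notes: Minimum score across the four organic-pollutant concentrations.

  - id: C8
    name: Heavy metal pollutants
    criterion: Water quality
    subsystem: natural
    rule: composite_min
    orientation: cost
    components:
      Hg: {1.0: 0.00005, 0.6: 0.0001, 0.0: 0.001}
      Cd: {1.0: 0.001, 0.6: 0.005, 0.0: 0.01}
      Cr: {1.0: 0.01, 0.6: 0.05, 0.0: 0.1}
      Pb: {1.0: 0.01, 0.6: 0.05, 0.0: 0.1}
      As: {1.0: 0.05, 0.6: 0.075, 0.0: 0.1}
    notes: Minimum score across the five metal concentrations.

  - id: C9
    name: Biodiversity
    criterion: Aquatic life
    subsystem: natural
    rule: composite_mean
    orientation: benefit
    shared_ladder: {1.0: 4, 0.8: 3.2, 0.6: 2.4, 0.4: 1.6, 0.3: 1.2, 0.2: 0.8, 0.0: 0}
    notes: >
      Shannon-Wiener diversity; multiple sampling points along a reach are
      averaged (a single point passes through unchanged).

  - id: C10
    name: Fish
    criterion: Aquatic life
    subsystem: natural
    rule: composite_mean
    orientation: benefit
    shared_ladder: {1.0: 1.0, 0.8: 0.85, 0.6: 0.75, 0.4: 0.6, 0.3: 0.5, 0.0: 0}
    notes: Fish index; sampling points averaged as for C9.

  - id: C11
    name: Flood control
    criterion: Flood control function
    subsystem: social
    rule: ladder
    orientation: benefit
    units: percent
    anchors: {1.0: 95, 0.8: 90, 0.6: 85, 0.4: 80, 0.2: 70, 0.0: 50}

  - id: C12
    name: Water function zone
    criterion: Loading pollutant function
    subsystem: social
    rule: ladder
    orientation: benefit
    units: percent
    anchors: {1.0: 100, 0.8: 80, 0.6: 60, 0.4: 40, 0.3: 30, 0.2: 20, 0.0: 0}

  - id: C13
    name: Water resource utilization
    criterion: Water supply function
    subsystem: social
    rule: parabolic
    parabola: {coef_a: -1111.11, coef_b: 666.67, scale: 100, cutoff: 0.6}
    notes: >
      Parabolic score peaking at a 30% utilization rate and falling to 0 at
      the 60% cap.  The published coefficient magnitudes are 1111.11 and
      666.67; the quadratic coefficient is taken negative (the only reading
      with an interior maximum) and the parabola output is on a 0-100 scale.

  - id: C14
    name: Water supply
    criterion: Water supply function
    subsystem: social
    rule: ladder
    orientation: benefit
    units: percent
    anchors: {1.0: 100, 0.8: 80, 0.6: 60, 0.4: 40, 0.3: 30, 0.2: 20, 0.0: 0}

  - id: C15
    name: Hydropower development
    criterion: Water supply function
    subsystem: social
    rule: ladder
    orientation: cost
    units: percent
    anchors: {1.0: 10, 0.8: 20, 0.6: 30, 0.4: 40, 0.2: 50, 0.0: 60}

  - id: C16
    name: Public satisfaction
    criterion: Landscape function
    subsystem: social
    rule: passthrough
    notes: Questionnaire mean, consumed as a ready [0, 1] score.
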