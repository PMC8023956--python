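# Default pass/fail criteria per competency level.
# A procedure passes iff every criterion for its level holds; thresholds
# are inclusive pass-bounds (failure is strictly beyond the threshold).
# Levels 0 and 1 (K-wire placement) share the wire criteria; level 2
# (full DHS procedure) extends them with implant-step criteria.
levels:
  0: &wire
    - id: tad
      metric: tip_apex_distance
      comparator: le
      threshold: 20.0
    - id: placement_zone
      metric: placement_zone
      comparator: in
      allowed: [center-center, center-inferior]
    - id: cortical_breach
      metric: cortical_breach
      comparator: is
      value: false
    - id: kwire_attempts
      metric: kwire_attempts
      comparator: le
      threshold: 3
  1: *wire
  2:
    - id: tad
      metric: tip_apex_distance
      comparator: le
      threshold: 20.0
    - id: placement_zone
      metric: placement_zone
      comparator: in
      allowed: [center-center, center-inferior]
    - id: cortical_breach
      metric: cortical_breach
      comparator: is
      value: false
    - id: kwire_attempts
      metric: kwire_attempts
      comparator: le
      threshold: 3
    - id: reamer_breach
      metric: reamer_breach
      comparator: is
      value: false
    - id: plate_angle
      metric: plate_angle_appropriate
      comparator: is
      value: true
    - id: shaft_screw
      metric: shaft_screw_bicortical
      comparator: is
      value: true
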