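# Polytrauma Grading Score (PTGS) - shipped default definition.
#
# A registry-derived points system over shock, coagulation and injury
# severity; by design it has no in-extremis stratum.  Its borderline
# markers (systolic BP < 75 mmHg, NISS > 50, pRBC of 15 or more, here
# counted over 24 h) sit close to other scores' in-extremis bands.  Any
# single borderline-band criterion (1 point) grades the patient
# borderline; 3+ points grade unstable.  Reconstruction of the source
# score; all values overridable.
name: PTGS
strata: [stable, borderline, unstable]
aggregation: point_sum
point_table: {stable: 0, borderline: 1, unstable: 3}
criteria:
  - parameter: systolic_bp
    pathway: hemorrhage
    direction: low_is_worse
    required: true
    cuts:
      borderline: {value: 75.0, inclusive: false}
      unstable: {value: 55.0, inclusive: false}
    points: {borderline: 1, unstable: 2}
  - parameter: prbc_24h
    pathway: hemorrhage
    direction: high_is_worse
    required: true
    cuts:
      borderline: {value: 15, inclusive: true}
      unstable: {value: 30, inclusive: true}
    points: {borderline: 1, unstable: 2}
  - parameter: inr
    pathway: coagulation
    direction: high_is_worse
    required: true
    cuts:
      borderline: {value: 1.4, inclusive: false}
      unstable: {value: 2.2, inclusive: true}
    points: {borderline: 1, unstable: 2}
  - parameter: niss
    pathway: injury_severity
    direction: high_is_worse
    required: true
    cuts:
      borderline: {value: 50, inclusive: false}
      unstable: {value: 65, inclusive: false}
    points: {borderline: 1, unstable: 2}
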