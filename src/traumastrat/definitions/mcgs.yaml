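# Modified Clinical Grading System (mCGS) - shipped default definition.
#
# The modification pares the CGS down (factor V, fibrinogen and the
# prothrombin value are dropped), widens the overlapping bands so that any
# patient maps to exactly one grade, and swaps the transfusion window from
# pRBC units within 2 h of admission to units within 24 h of injury.
# Every shared-parameter band is equal to or laxer than its CGS
# counterpart, so on any patient whose transfusion trajectory satisfies
# prbc_24h <= 3*prbc_2h + 5 the mCGS grade is never more severe than the
# CGS grade (the modification only downgrades).  Reconstruction of the
# source publication's bands; all values overridable.
name: mCGS
strata: [stable, borderline, unstable, in_extremis]
aggregation: worst_criterion
criteria:
  - parameter: lactate
    pathway: acid_base
    direction: high_is_worse
    required: true
    cuts:
      borderline: {value: 2.5, inclusive: true}
      unstable: {value: 4.0, inclusive: true}
      in_extremis: {value: 8.0, inclusive: true}
  - parameter: ph
    pathway: acid_base
    direction: low_is_worse
    required: true
    cuts:
      borderline: {value: 7.30, inclusive: false}
      unstable: {value: 7.20, inclusive: false}
      in_extremis: {value: 7.10, inclusive: false}
  - parameter: base_excess
    pathway: acid_base
    direction: low_is_worse
    required: true
    cuts:
      borderline: {value: -3.0, inclusive: false}
      unstable: {value: -8.0, inclusive: false}
      in_extremis: {value: -12.0, inclusive: false}
  - parameter: systolic_bp
    pathway: hemorrhage
    direction: low_is_worse
    required: true
    cuts:
      borderline: {value: 90.0, inclusive: false}
      unstable: {value: 75.0, inclusive: false}
      in_extremis: {value: 50.0, inclusive: false}
  - parameter: prbc_24h
    pathway: hemorrhage
    direction: high_is_worse
    required: true
    cuts:
      borderline: {value: 10, inclusive: true}
      unstable: {value: 20, inclusive: true}
      in_extremis: {value: 60, inclusive: true}
  - parameter: temperature_core
    pathway: hemorrhage
    direction: low_is_worse
    required: true
    cuts:
      borderline: {value: 34.0, inclusive: true}
      unstable: {value: 31.0, inclusive: true}
      in_extremis: {value: 29.0, inclusive: true}
  - parameter: platelet_count
    pathway: coagulation
    direction: low_is_worse
    required: true
    cuts:
      borderline: {value: 110.0, inclusive: false}
      unstable: {value: 90.0, inclusive: false}
      in_extremis: {value: 70.0, inclusive: false}
  - parameter: chest_ais
    pathway: soft_tissue
    direction: high_is_worse
    required: true
    cuts:
      borderline: {value: 3, inclusive: true}
      unstable: {value: 4, inclusive: true}
      in_extremis: {value: 5, inclusive: true}
  - parameter: abdomen_moore_grade
    pathway: soft_tissue
    direction: high_is_worse
    required: true
    cuts:
      borderline: {value: 4, inclusive: true}
      unstable: {value: 5, inclusive: true}
  - parameter: extremity_soft_tissue_ais
    pathway: soft_tissue
    direction: high_is_worse
    required: true
    cuts:
      borderline: {value: 4, inclusive: true}
      unstable: {value: 5, inclusive: true}
      in_extremis: {value: 6, inclusive: true}
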