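# Clinical Grading System (CGS) - shipped default definition.
#
# Cut values are a reconstruction of the published stable / borderline /
# unstable / in-extremis bands of the source grading table, restricted to
# the parameters available at the end of ER diagnostics (D-dimer, urinary
# output, thoracic trauma score and PaO2/FiO2 are omitted).  Every value is
# overridable by pointing the loader at a custom file.
# Boundary semantics: inclusive=false encodes a "<x" / ">x" comparison.
name: CGS
strata: [stable, borderline, unstable, in_extremis]
aggregation: worst_criterion
criteria:
  - parameter: lactate
    pathway: acid_base
    direction: high_is_worse
    required: true
    cuts:
      borderline: {value: 2.0, inclusive: true}
      unstable: {value: 2.5, inclusive: false}
      in_extremis: {value: 6.0, inclusive: true}
  - parameter: ph
    pathway: acid_base
    direction: low_is_worse
    required: true
    cuts:
      borderline: {value: 7.35, inclusive: false}
      unstable: {value: 7.25, inclusive: false}
      in_extremis: {value: 7.15, inclusive: false}
  - parameter: base_excess
    pathway: acid_base
    direction: low_is_worse
    required: true
    cuts:
      borderline: {value: -2.0, inclusive: false}
      unstable: {value: -6.0, inclusive: false}
      in_extremis: {value: -10.0, inclusive: false}
  - parameter: systolic_bp
    pathway: hemorrhage
    direction: low_is_worse
    required: true
    cuts:
      borderline: {value: 100.0, inclusive: false}
      unstable: {value: 90.0, inclusive: false}
      in_extremis: {value: 60.0, inclusive: false}
  - parameter: prbc_2h
    pathway: hemorrhage
    direction: high_is_worse
    required: true
    cuts:
      borderline: {value: 2, inclusive: true}
      unstable: {value: 5, inclusive: true}
      in_extremis: {value: 15, inclusive: false}
  - parameter: temperature_core
    pathway: hemorrhage
    direction: low_is_worse
    required: true
    cuts:
      borderline: {value: 35.0, inclusive: true}
      unstable: {value: 32.0, inclusive: true}
      in_extremis: {value: 30.0, inclusive: true}
  - parameter: platelet_count
    pathway: coagulation
    direction: low_is_worse
    required: true
    cuts:
      borderline: {value: 110.0, inclusive: false}
      unstable: {value: 90.0, inclusive: false}
      in_extremis: {value: 70.0, inclusive: false}
  - parameter: fibrinogen
    pathway: coagulation
    direction: low_is_worse
    required: true
    cuts:
      borderline: {value: 2.0, inclusive: false}
      unstable: {value: 1.0, inclusive: true}
      in_extremis: {value: 0.8, inclusive: false}
  - parameter: prothrombin_ratio
    pathway: coagulation
    direction: low_is_worse
    required: true
    cuts:
      borderline: {value: 80.0, inclusive: false}
      unstable: {value: 70.0, inclusive: false}
      in_extremis: {value: 50.0, inclusive: false}
  - parameter: chest_ais
    pathway: soft_tissue
    direction: high_is_worse
    required: true
    cuts:
      borderline: {value: 2, inclusive: true}
      unstable: {value: 3, inclusive: true}
      in_extremis: {value: 4, inclusive: true}
  - parameter: abdomen_moore_grade
    pathway: soft_tissue
    direction: high_is_worse
    required: true
    cuts:
      borderline: {value: 3, inclusive: true}
      unstable: {value: 4, inclusive: true}
      in_extremis: {value: 5, inclusive: true}
  - parameter: extremity_soft_tissue_ais
    pathway: soft_tissue
    direction: high_is_worse
    required: true
    cuts:
      borderline: {value: 3, inclusive: true}
      unstable: {value: 4, inclusive: true}
      in_extremis: {value: 5, inclusive: true}
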