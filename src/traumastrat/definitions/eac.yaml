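# Early Appropriate Care (EAC) protocol - shipped default definition.
#
# Dichotomous acid-base rule from the source protocol: a patient is low
# risk when lactate < 4.0 mmol/L AND pH >= 7.25 AND base excess >= -5.5
# mmol/L; violating any one criterion grades high risk.  All values
# overridable.
name: EAC
strata: [low_risk, high_risk]
aggregation: worst_criterion
criteria:
  - parameter: lactate
    pathway: acid_base
    direction: high_is_worse
    required: true
    cuts:
      high_risk: {value: 4.0, inclusive: true}
  - parameter: ph
    pathway: acid_base
    direction: low_is_worse
    required: true
    cuts:
      high_risk: {value: 7.25, inclusive: false}
  - parameter: base_excess
    pathway: acid_base
    direction: low_is_worse
    required: true
    cuts:
      high_risk: {value: -5.5, inclusive: false}
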