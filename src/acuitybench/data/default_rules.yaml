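# RECONSTRUCTED default acuity rule table.
schema: acuitybench-rules/1
description: >
  Three-level neonatal dependency classification (BAPM 2011 categories) over
  daily intervention flags as recorded in register daily reports. The rule list
  is a reconstruction for the six interventions named in the register extract,
  shipped as editable data rather than code. Rules are evaluated top-down,
  first match wins; days matching no rule are special care (SC).
vocabulary:
  - mechanical_respiratory_support
  - invasive_respiratory_support
  - noninvasive_respiratory_support
  - umbilical_line
  - chest_drain
  - parenteral_nutrition
  # non-qualifying flags kept in the vocabulary so register extracts with the
  # wider intervention list load without error
  - phototherapy
  - tube_feeding
  - antibiotics
weights:
  IC: 1.0
  HDC: 0.5
  SC: 0.25
rules:
  - id: ic_invasive_ventilation
    category: IC
    any_of: [invasive_respiratory_support, mechanical_respiratory_support]
  - id: ic_chest_drain
    category: IC
    any_of: [chest_drain]
  # The contested rule: parenteral nutrition with no respiratory support of any
  # kind. The original BAPM table puts these days in intensive care; the adapted
  # variant reclassifies them as high-dependency care. `category` here is a
  # mapping keyed by variant; load_ruleset picks one.
  - id: pn_without_respiratory_support
    category: {adapted: HDC, original: IC}
    all_of: [parenteral_nutrition]
    none_of:
      - invasive_respiratory_support
      - mechanical_respiratory_support
      - noninvasive_respiratory_support
  - id: hdc_noninvasive_support
    category: HDC
    any_of: [noninvasive_respiratory_support]
  - id: hdc_umbilical_line
    category: HDC
    any_of: [umbilical_line]
  - id: hdc_parenteral_nutrition
    category: HDC
    any_of: [parenteral_nutrition]
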