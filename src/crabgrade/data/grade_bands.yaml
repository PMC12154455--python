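# Sex-specific fatness grade bands (percent scale), checked top-down:
# a band matches when K > lower (or K >= lower when lower_inclusive).
# The trailing IV band is the floor.
male:
  - {grade: I, lower: 65.0}
  - {grade: II, lower: 62.0}
  - {grade: III, lower: 58.0}
  - {grade: IV, lower: -.inf}
female:
  - {grade: I, lower: 58.0}
  - {grade: II, lower: 55.0}
  - {grade: III, lower: 51.0, lower_inclusive: true}
  - {grade: IV, lower: -.inf}
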