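# The four standard case definitions: the nine-substring composite over
# gastrointestinal obstruction/perforation, and its obstruction /
# perforation / ileus restrictions. Substrings match case-insensitively
# within PT names drawn from the narrow scope of the three source SMQs.
queries:
  - label: composite
    substrings: [ileus, stenosis, obstruction, obstructive, impaction, perforation, perforated, hypomotility, intussusception]
    source_smqs: ["20000104", "20000105", "20000107"]
  - label: obstruction
    substrings: [obstruction, obstructive, impaction]
    source_smqs: ["20000104", "20000105", "20000107"]
  - label: perforation
    substrings: [perforation, perforated]
    source_smqs: ["20000104", "20000105", "20000107"]
  - label: ileus
    substrings: [ileus]
    source_smqs: ["20000104", "20000105", "20000107"]
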