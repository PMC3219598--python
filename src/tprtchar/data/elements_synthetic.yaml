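AluY:
  diagnostic_sites: []
  family: AluY
AluYa5:
  diagnostic_sites:
  - - 57
    - T
  - - 101
    - C
  - - 150
    - G
  - - 211
    - C
  - - 251
    - T
  family: AluYa5
AluYb8:
  diagnostic_sites:
  - - 30
    - C
  - - 66
    - T
  - - 95
    - G
  - - 123
    - A
  - - 170
    - T
  - - 205
    - T
  - - 240
    - G
  - - 273
    - G
  family: AluYb8
L1:
  diagnostic_sites: []
  family: L1
  l1_subset_site: 5910
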