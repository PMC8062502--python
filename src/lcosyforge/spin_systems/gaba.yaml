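name: GABA
full_name: gamma-aminobutyric acid
source: 1H chemical shifts and J-couplings transcribed from the standard brain-metabolite
  NMR compilation (Govindaraju et al., NMR Biomed 13:129-153, 2000); minor multiplet
  couplings simplified
groups:
- shifts_ppm:
  - 2.284
  - 2.284
  - 1.889
  - 1.889
  - 3.0128
  - 3.0128
  j_hz:
  - - 0
    - 2
    - 7.33
  - - 0
    - 3
    - 7.33
  - - 1
    - 2
    - 7.33
  - - 1
    - 3
    - 7.33
  - - 2
    - 4
    - 7.0
  - - 2
    - 5
    - 7.0
  - - 3
    - 4
    - 7.0
  - - 3
    - 5
    - 7.0
  weight: 1.0
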