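name: Ch
full_name: choline
source: 1H chemical shifts and J-couplings transcribed from the standard brain-metabolite
  NMR compilation (Govindaraju et al., NMR Biomed 13:129-153, 2000); minor multiplet
  couplings simplified
groups:
- shifts_ppm:
  - 3.185
  j_hz: []
  weight: 9.0
- shifts_ppm:
  - 4.054
  - 4.054
  - 3.501
  - 3.501
  j_hz:
  - - 0
    - 2
    - 3.14
  - - 0
    - 3
    - 6.979
  - - 1
    - 2
    - 7.011
  - - 1
    - 3
    - 3.168
  weight: 1.0
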