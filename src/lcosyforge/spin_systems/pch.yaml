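name: PCh
full_name: phosphocholine
source: 1H chemical shifts and J-couplings transcribed from the standard brain-metabolite
  NMR compilation (Govindaraju et al., NMR Biomed 13:129-153, 2000); minor multiplet
  couplings simplified
groups:
- shifts_ppm:
  - 3.208
  j_hz: []
  weight: 9.0
- shifts_ppm:
  - 4.2805
  - 4.2805
  - 3.641
  - 3.641
  j_hz:
  - - 0
    - 2
    - 3.1
  - - 0
    - 3
    - 6.9
  - - 1
    - 2
    - 7.0
  - - 1
    - 3
    - 3.2
  weight: 1.0
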