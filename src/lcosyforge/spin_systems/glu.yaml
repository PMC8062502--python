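name: Glu
full_name: glutamate
source: 1H chemical shifts and J-couplings transcribed from the standard brain-metabolite
  NMR compilation (Govindaraju et al., NMR Biomed 13:129-153, 2000); minor multiplet
  couplings simplified
groups:
- shifts_ppm:
  - 3.7433
  - 2.0375
  - 2.12
  - 2.3378
  - 2.352
  j_hz:
  - - 0
    - 1
    - 7.331
  - - 0
    - 2
    - 4.651
  - - 1
    - 2
    - -14.849
  - - 1
    - 3
    - 6.413
  - - 1
    - 4
    - 8.406
  - - 2
    - 3
    - 8.478
  - - 2
    - 4
    - 6.875
  - - 3
    - 4
    - -15.915
  weight: 1.0
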