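name: NAAG
full_name: N-acetylaspartylglutamate
source: 1H chemical shifts and J-couplings transcribed from the standard brain-metabolite
  NMR compilation (Govindaraju et al., NMR Biomed 13:129-153, 2000); minor multiplet
  couplings simplified
groups:
- shifts_ppm:
  - 2.042
  - 2.042
  - 2.042
  j_hz: []
  weight: 1.0
- shifts_ppm:
  - 4.607
  - 2.721
  - 2.519
  j_hz:
  - - 0
    - 1
    - 4.41
  - - 0
    - 2
    - 9.52
  - - 1
    - 2
    - -15.91
  weight: 1.0
- shifts_ppm:
  - 4.128
  - 1.881
  - 2.049
  - 2.18
  - 2.19
  j_hz:
  - - 0
    - 1
    - 4.61
  - - 0
    - 2
    - 8.2
  - - 1
    - 2
    - -14.28
  - - 1
    - 3
    - 7.0
  - - 1
    - 4
    - 7.9
  - - 2
    - 3
    - 7.9
  - - 2
    - 4
    - 7.0
  - - 3
    - 4
    - -15.6
  weight: 1.0
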