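name: Glc
full_name: glucose (alpha + beta anomers)
source: 1H chemical shifts and J-couplings transcribed from the standard brain-metabolite
  NMR compilation (Govindaraju et al., NMR Biomed 13:129-153, 2000); minor multiplet
  couplings simplified
groups:
- shifts_ppm:
  - 5.216
  - 3.519
  - 3.698
  - 3.395
  - 3.822
  - 3.826
  - 3.749
  j_hz:
  - - 0
    - 1
    - 3.8
  - - 1
    - 2
    - 9.6
  - - 2
    - 3
    - 9.4
  - - 3
    - 4
    - 9.9
  - - 4
    - 5
    - 1.5
  - - 4
    - 6
    - 6.0
  - - 5
    - 6
    - -12.1
  weight: 0.36
- shifts_ppm:
  - 4.63
  - 3.23
  - 3.473
  - 3.387
  - 3.45
  - 3.882
  - 3.707
  j_hz:
  - - 0
    - 1
    - 7.9
  - - 1
    - 2
    - 9.1
  - - 2
    - 3
    - 9.4
  - - 3
    - 4
    - 8.9
  - - 4
    - 5
    - 1.6
  - - 4
    - 6
    - 5.4
  - - 5
    - 6
    - -12.3
  weight: 0.64
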