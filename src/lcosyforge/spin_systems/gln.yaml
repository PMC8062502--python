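name: Gln
full_name: glutamine
source: 1H chemical shifts and J-couplings transcribed from the standard brain-metabolite
  NMR compilation (Govindaraju et al., NMR Biomed 13:129-153, 2000); minor multiplet
  couplings simplified
groups:
- shifts_ppm:
  - 3.753
  - 2.129
  - 2.109
  - 2.432
  - 2.454
  j_hz:
  - - 0
    - 1
    - 5.847
  - - 0
    - 2
    - 6.5
  - - 1
    - 2
    - -14.504
  - - 1
    - 3
    - 9.165
  - - 1
    - 4
    - 6.347
  - - 2
    - 3
    - 6.324
  - - 2
    - 4
    - 9.209
  - - 3
    - 4
    - -15.371
  weight: 1.0
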