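name: GSH
full_name: glutathione
source: 1H chemical shifts and J-couplings transcribed from the standard brain-metabolite
  NMR compilation (Govindaraju et al., NMR Biomed 13:129-153, 2000); minor multiplet
  couplings simplified
groups:
- shifts_ppm:
  - 3.769
  - 3.769
  j_hz: []
  weight: 1.0
- shifts_ppm:
  - 4.5608
  - 2.9264
  - 2.9747
  j_hz:
  - - 0
    - 1
    - 7.09
  - - 0
    - 2
    - 4.71
  - - 1
    - 2
    - -14.06
  weight: 1.0
- shifts_ppm:
  - 3.769
  - 2.159
  - 2.146
  - 2.51
  - 2.56
  j_hz:
  - - 0
    - 1
    - 6.34
  - - 0
    - 2
    - 6.36
  - - 1
    - 2
    - -15.48
  - - 1
    - 3
    - 6.7
  - - 1
    - 4
    - 7.6
  - - 2
    - 3
    - 7.6
  - - 2
    - 4
    - 6.7
  - - 3
    - 4
    - -15.92
  weight: 1.0
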