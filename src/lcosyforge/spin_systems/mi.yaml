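name: mI
full_name: myo-inositol
source: 1H chemical shifts and J-couplings transcribed from the standard brain-metabolite
  NMR compilation (Govindaraju et al., NMR Biomed 13:129-153, 2000); minor multiplet
  couplings simplified
groups:
- shifts_ppm:
  - 3.5217
  - 4.0538
  - 3.5217
  - 3.6144
  - 3.269
  - 3.6144
  j_hz:
  - - 0
    - 1
    - 2.889
  - - 1
    - 2
    - 3.006
  - - 2
    - 3
    - 9.997
  - - 3
    - 4
    - 9.485
  - - 4
    - 5
    - 9.482
  - - 0
    - 5
    - 9.998
  weight: 1.0
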