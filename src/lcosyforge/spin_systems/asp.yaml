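name: Asp
full_name: aspartate
source: 1H chemical shifts and J-couplings transcribed from the standard brain-metabolite
  NMR compilation (Govindaraju et al., NMR Biomed 13:129-153, 2000); minor multiplet
  couplings simplified
groups:
- shifts_ppm:
  - 3.8914
  - 2.8011
  - 2.6533
  j_hz:
  - - 0
    - 1
    - 3.647
  - - 0
    - 2
    - 9.107
  - - 1
    - 2
    - -17.426
  weight: 1.0
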