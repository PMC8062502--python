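name: Lac
full_name: lactate
source: 1H chemical shifts and J-couplings transcribed from the standard brain-metabolite
  NMR compilation (Govindaraju et al., NMR Biomed 13:129-153, 2000); minor multiplet
  couplings simplified
groups:
- shifts_ppm:
  - 4.0974
  - 1.3142
  - 1.3142
  - 1.3142
  j_hz:
  - - 0
    - 1
    - 6.933
  - - 0
    - 2
    - 6.933
  - - 0
    - 3
    - 6.933
  weight: 1.0
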