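name: Tau
full_name: taurine
source: 1H chemical shifts and J-couplings transcribed from the standard brain-metabolite
  NMR compilation (Govindaraju et al., NMR Biomed 13:129-153, 2000); minor multiplet
  couplings simplified
groups:
- shifts_ppm:
  - 3.2459
  - 3.2459
  - 3.4206
  - 3.4206
  j_hz:
  - - 0
    - 2
    - 6.742
  - - 0
    - 3
    - 6.464
  - - 1
    - 2
    - 6.403
  - - 1
    - 3
    - 6.792
  weight: 1.0
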