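name: Thr
full_name: threonine
source: 1H chemical shifts and J-couplings transcribed from the standard brain-metabolite
  NMR compilation (Govindaraju et al., NMR Biomed 13:129-153, 2000); minor multiplet
  couplings simplified
groups:
- shifts_ppm:
  - 3.5785
  - 4.2464
  - 1.3178
  - 1.3178
  - 1.3178
  j_hz:
  - - 0
    - 1
    - 4.917
  - - 1
    - 2
    - 6.35
  - - 1
    - 3
    - 6.35
  - - 1
    - 4
    - 6.35
  weight: 1.0
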