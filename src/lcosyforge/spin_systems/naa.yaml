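name: NAA
full_name: N-acetylaspartate
source: 1H chemical shifts and J-couplings transcribed from the standard brain-metabolite
  NMR compilation (Govindaraju et al., NMR Biomed 13:129-153, 2000); minor multiplet
  couplings simplified
groups:
- shifts_ppm:
  - 2.008
  - 2.008
  - 2.008
  j_hz: []
  weight: 1.0
- shifts_ppm:
  - 4.3817
  - 2.6727
  - 2.4863
  j_hz:
  - - 0
    - 1
    - 3.861
  - - 0
    - 2
    - 9.821
  - - 1
    - 2
    - -15.592
  weight: 1.0
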