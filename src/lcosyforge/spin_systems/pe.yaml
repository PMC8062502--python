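name: PE
full_name: phosphoethanolamine
source: 1H chemical shifts and J-couplings transcribed from the standard brain-metabolite
  NMR compilation (Govindaraju et al., NMR Biomed 13:129-153, 2000); minor multiplet
  couplings simplified
groups:
- shifts_ppm:
  - 3.9765
  - 3.9765
  - 3.216
  - 3.216
  j_hz:
  - - 0
    - 2
    - 3.182
  - - 0
    - 3
    - 6.716
  - - 1
    - 2
    - 7.204
  - - 1
    - 3
    - 2.98
  weight: 1.0
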