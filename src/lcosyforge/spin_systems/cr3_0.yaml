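name: Cr3.0
full_name: creatine (methyl, 3.0 ppm)
source: 1H chemical shifts and J-couplings transcribed from the standard brain-metabolite
  NMR compilation (Govindaraju et al., NMR Biomed 13:129-153, 2000); minor multiplet
  couplings simplified
groups:
- shifts_ppm:
  - 3.027
  - 3.027
  - 3.027
  j_hz: []
  weight: 1.0
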