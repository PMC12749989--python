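# AcrB (E. coli) subdomain residue ranges, author numbering.
# CURATION, NOT GROUND TRUTH: these are approximate boundaries assembled
# from the published AcrB domain architecture; edit to match your model's
# numbering before quantitative use.
subdomains:
  PN1: [[34, 89], [132, 181]]
  PN2: [[90, 131], [182, 263]]
  PC1: [[566, 675]]
  PC2: [[676, 810]]
  TM2: [[336, 367]]
core:
  - [1, 33]
  - [330, 335]
  - [811, 871]
  - [872, 1033]
exit_seed_residues: [124, 758]
proton_lysine: 940
proton_asparagine: 941
proton_aspartates: [407, 408]
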