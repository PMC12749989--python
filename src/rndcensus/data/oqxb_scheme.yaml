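# OqxB (K. pneumoniae) subdomain residue ranges, author numbering.
# CURATION, NOT GROUND TRUTH: approximate boundaries derived by offsetting
# the AcrB architecture to the OqxB numbering (e.g. the proton-network
# triad K946/N947 with titratable D410/D411); edit before quantitative use.
subdomains:
  PN1: [[40, 95], [138, 187]]
  PN2: [[96, 137], [188, 269]]
  PC1: [[572, 681]]
  PC2: [[682, 816]]
  TM2: [[342, 373]]
core:
  - [1, 39]
  - [336, 341]
  - [817, 877]
  - [878, 1040]
exit_seed_residues: [130, 764]
proton_lysine: 946
proton_asparagine: 947
proton_aspartates: [410, 411]
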