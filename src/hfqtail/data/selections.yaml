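# Tail/core residue selections, E. coli numbering.
#
# core:       Sm core residue numbers (ranges "a-b" are inclusive)
# basic_core: basic rim/NTD residues used for the on-target EEC sum
# tail:       acidic CTD tail residues
#
# The "toy" entry matches the coarse-grained bead hexamer produced by
# hfqtail.synthetic_data and has no biological meaning.

"E. coli":
  core: ["1-65"]
  basic_core: [3, 16, 17, 19, 47]
  tail: [97, 99, 100, 102]

"P. aeruginosa":
  core: ["1-65"]
  basic_core: [3, 5, 16, 17, 19, 47]
  tail: [94, 97]

"L. monocytogenes":
  core: ["1-65"]
  basic_core: [2, 16, 17, 19, 35]
  tail: [100, 102]

"B. subtilis":
  core: ["1-65"]
  basic_core: [2, 16, 17, 37]
  tail: [100, 102]

"S. aureus":
  core: ["1-65"]
  basic_core: [10, 16, 41]
  tail: [65, 67, 99, 101, 102]

"toy":
  core: ["1-12"]
  basic_core: [3, 5, 7]
  tail: [21, 22, 23, 24]
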