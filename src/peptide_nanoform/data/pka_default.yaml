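# Default pKa table for ionizable groups of short amphipathic peptides.
# Terminal pKa values depend on the flanking residue; "n_terminus" entries
# keyed by the leading residue take precedence over the plain default.
c_terminus: 2.18
n_terminus: 9.13
n_terminus_by_residue:
  F: 9.13
  K: 8.95
side_chains:
  E: 4.25
  K: 10.53
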