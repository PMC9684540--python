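# Connector ABEGO menus per flanking-element class.  Strings are drawn
# uniformly when a loop segment declares no menu of its own; lengths outside
# the loop's declared range are skipped.
alpha_beta:   # helix -> strand
  - "GB"
  - "GBB"
  - "BAB"
  - "GBA"
beta_alpha:   # strand -> helix
  - "AB"
  - "GB"
  - "GBB"
  - "BAAB"
beta_beta:    # strand -> strand (hairpins)
  - "GG"
  - "EA"
  - "AAG"
  - "BGBB"
alpha_alpha:  # helix -> helix
  - "GB"
  - "BAAB"
  - "GBA"
  - "BB"
generic:
  - "GB"
  - "GG"
  - "BA"
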