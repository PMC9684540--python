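# Simplified beta-grasp demonstration document.  The helix-to-second-strand
# constraint is lengthened to 9 A; all other constraints keep the 8 A default.
foldsmith: 1
segments:
  - {name: B1, kind: strand, length: [4, 6]}
  - {name: L1, kind: loop, length: [2, 4]}
  - {name: A1, kind: helix, length: [10, 14]}
  - {name: L2, kind: loop, length: [2, 4]}
  - {name: B2, kind: strand, length: [4, 6]}
  - {name: L3, kind: loop, length: [2, 4]}
  - {name: B3, kind: strand, length: [4, 6]}
pairings:
  - {type: strand, first: B1, second: B2, orientation: antiparallel, register: [-2, 2]}
  - {type: strand, first: B2, second: B3, orientation: antiparallel, register: [-2, 2]}
  - {type: helix_sheet, helix: A1, strands: [B1, B2]}
sheets:
  - [B1, B2, B3]
constraints:
  - {a: [A1, C-end], b: [B2, N-end], target: 9}
  - {a: [A1, midpoint], b: [B1, midpoint]}
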