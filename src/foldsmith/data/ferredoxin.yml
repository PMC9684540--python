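# Ferredoxin-like beta-alpha-beta-beta-alpha-beta fold.
# Four-strand sheet in spatial order B2 B1 B4 B3 with two crossing helices.
foldsmith: 1
segments:
  - {name: B1, kind: strand, length: [4, 6]}
  - {name: L1, kind: loop, length: [2, 4]}
  - {name: A1, kind: helix, length: [10, 16]}
  - {name: L2, kind: loop, length: [2, 4]}
  - {name: B2, kind: strand, length: [4, 6]}
  - {name: L3, kind: loop, length: [2, 4]}
  - {name: B3, kind: strand, length: [4, 6]}
  - {name: L4, kind: loop, length: [2, 4]}
  - {name: A2, kind: helix, length: [10, 16]}
  - {name: L5, kind: loop, length: [2, 4]}
  - {name: B4, kind: strand, length: [4, 6]}
pairings:
  - {type: strand, first: B1, second: B2, orientation: parallel, register: [-2, 2]}
  - {type: strand, first: B1, second: B4, orientation: antiparallel, register: [-2, 2]}
  - {type: strand, first: B3, second: B4, orientation: parallel, register: [-2, 2]}
  - {type: helix_sheet, helix: A1, strands: [B1, B2]}
  - {type: helix_sheet, helix: A2, strands: [B3, B4]}
sheets:
  - [B2, B1, B4, B3]
constraints:
  - {a: [A1, midpoint], b: [B1, midpoint]}
  - {a: [A2, midpoint], b: [B4, midpoint]}
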