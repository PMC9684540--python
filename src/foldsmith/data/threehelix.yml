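# Three-helix bundle: up-down-up antiparallel helices.
foldsmith: 1
segments:
  - {name: H1, kind: helix, length: [12, 16]}
  - {name: L1, kind: loop, length: [2, 4]}
  - {name: H2, kind: helix, length: [12, 16]}
  - {name: L2, kind: loop, length: [2, 4]}
  - {name: H3, kind: helix, length: [12, 16]}
pairings:
  - {type: helix, first: H1, second: H2, orientation: antiparallel}
  - {type: helix, first: H2, second: H3, orientation: antiparallel}
constraints:
  - {a: [H1, midpoint], b: [H2, midpoint], target: 10, sd: 2}
  - {a: [H2, midpoint], b: [H3, midpoint], target: 10, sd: 2}
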