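<FoldDefinition version="foldsmith/1">
  <Segment name="H1" kind="helix" min="12" max="16"/>
  <Segment name="L1" kind="loop" min="2" max="4"/>
  <Segment name="H2" kind="helix" min="12" max="16"/>
  <Segment name="L2" kind="loop" min="2" max="4"/>
  <Segment name="H3" kind="helix" min="12" max="16"/>
  <HelixPairing first="H1" second="H2" orientation="antiparallel"/>
  <HelixPairing first="H2" second="H3" orientation="antiparallel"/>
  <Constraint a="H1:midpoint" b="H2:midpoint" target="10" sd="2"/>
  <Constraint a="H2:midpoint" b="H3:midpoint" target="10" sd="2"/>
</FoldDefinition>
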