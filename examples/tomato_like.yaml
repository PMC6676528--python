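# Tripling, speciation, then one extra WGD in branch A only -- the
# configuration in which the post-speciation amplification factor
# F_A = 1 + u2 of the branch-A WGD is estimable by regression.
model:
  type: scenario
  M1: 1000
  events:
    - {kind: wgd, time: 90, ploidy: 3, u2: 0.25}
    - {kind: speciation, time: 55, u2: 0.6}
  branch_a:
    events:
      - {kind: wgd, time: 20, ploidy: 2, u2: 0.75}
      - {kind: observation, time: 0}
  branch_b:
    events:
      - {kind: observation, time: 0}
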