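# A whole-genome tripling followed by a speciation (coupled survival:
# u2 is the probability that both daughter genomes keep a gene through
# the first post-speciation interval).  Ortholog comparison of the two
# daughter species.
model:
  type: scenario
  M1: 1000
  events:
    - {kind: wgd, time: 80, ploidy: 3, u2: 0.2}   # u3 defaults to u2^2
    - {kind: speciation, time: 40, u2: 0.7}
  branch_a:
    events:
      - {kind: observation, time: 0}
  branch_b:
    events:
      - {kind: observation, time: 0}
similarity:
  decay: {amplitude: 1.0, rate_per_my: 0.009}
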