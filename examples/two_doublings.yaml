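# Two successive whole-genome doublings observed at the present.
# Times are My before present; u2 is the probability that both copies
# of a gene survive the interval after the event (u0 = 0 assumed).
model:
  type: schedule
  M1: 1000
  events:
    - {kind: wgd, time: 65, ploidy: 2, u2: 0.35}
    - {kind: wgd, time: 30, ploidy: 2, u2: 0.5}
    - {kind: observation, time: 0}
similarity:
  decay: {amplitude: 1.0, rate_per_my: 0.009}
  sd: {intercept: 0.075, slope: -0.06}
fit:
  bin_width: 0.01
  window: 5
  min_prominence: 0.05
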