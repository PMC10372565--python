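# Quarter-size study box: 25 seeded cells growing to 750 at terminal
# density. Omitted keys take the published defaults (see docs/methods.md).
L: 600
alpha: 2.0
k_r: 120
seed: 1
snapshot_stride: 4000
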