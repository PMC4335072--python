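shape: {kind: rectangle, width: 12, height: 8}
amputation: {kind: half_plane, axis: y, op: ge, value: 4}
kernel: {family: polynomial, n: 2.0}
config: {rule: 3b, epsilon: 1.0e-14}
output_dir: out
render: true
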