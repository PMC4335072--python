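shape: {kind: ellipse, semi_axes: [5.0, 3.0]}
amputation: {kind: half_plane, axis: x, op: ge, value: 3}
kernel: {family: polynomial, n: 2.0}
config: {rule: 3a}
output_dir: out_ellipse
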