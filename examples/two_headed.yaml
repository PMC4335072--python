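shape: {kind: glyph, id: two_headed}
amputation: {kind: half_plane, axis: y, op: ge, value: 6}
kernel: {family: polynomial, n: 2.0}
config: {rule: 3b}
output_dir: out_two_headed
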