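# substituent fragments (<=5 heavy atoms), attachment [*:1]; [H] = unsubstituted
[*:1][H]
[*:1]F
[*:1]Cl
[*:1]Br
[*:1]C
[*:1]CC
[*:1]CCC
[*:1]C(C)C
[*:1]O
[*:1]OC
[*:1]OCC
[*:1]N
[*:1]NC
[*:1]C#N
[*:1]C(F)(F)F
[*:1]C(=O)C
[*:1]CO
[*:1]N(C)C
[*:1]OC(C)C
[*:1]CCO
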