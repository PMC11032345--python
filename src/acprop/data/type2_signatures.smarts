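# demo type-II kinase-inhibitor signature substructures (SMARTS, one per line)
c[NX3H1]C(=O)[NX3H1]c  # diaryl urea linker
c[NX3H1]C(=O)c1cccc(c1)C(F)(F)F  # 3-(trifluoromethyl)benzamide
c[NX3H1]C(=S)[NX3H1]c  # diaryl thiourea linker
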