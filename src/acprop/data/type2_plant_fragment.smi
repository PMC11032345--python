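# fragment grafted onto synthetic decoy molecules; matches the first demo signature
[*:1]Nc1ccc(NC(=O)Nc2ccccc2)cc1
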