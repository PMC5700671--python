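prefix
F00
F01
F02
F03
G30
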