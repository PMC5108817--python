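G0012
G0025
G0030
G0031
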