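BG00011
BG00020
BG00021
BG00054
BG00076
BG00080
BG00103
BG00118
BG00124
BG00150
BG00234
BG00250
BG00251
G0001
G0004
G0005
G0006
G0010
G0014
G0015
G0020
G0021
G0022
G0026
G0032
G0034
G0035
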