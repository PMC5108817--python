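gene	value
ESR1	35
G0001	5
G0003	24
G0004	4
G0005	26
G0006	6
G0007	1
G0008	1
G0010	17
G0011	10
G0012	2
G0013	24
G0014	16
G0015	15
G0016	37
G0018	8
G0019	46
G0020	63
G0021	46
G0022	25
G0023	6
G0024	5
G0025	27
G0026	6
G0027	33
G0028	18
G0029	15
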