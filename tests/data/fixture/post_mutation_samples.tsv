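gene	value
ESR1	5
G0001	13
G0002	36
G0004	10
G0005	13
G0006	21
G0007	37
G0008	21
G0009	24
G0010	18
G0011	2
G0012	9
G0013	14
G0014	22
G0015	10
G0016	27
G0017	39
G0019	39
G0020	11
G0021	15
G0022	12
G0023	4
G0024	7
G0025	25
G0026	10
G0027	9
G0028	25
G0029	10
G0030	9
G0031	24
G0032	4
G0033	11
G0034	17
G0035	2
G0039	17
G0040	17
G0041	12
G0042	9
G0043	11
G0044	10
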