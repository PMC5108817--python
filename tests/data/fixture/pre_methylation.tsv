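gene	value
ESR1	1.212210307
G0001	1.340042837
G0002	0.4096443296
G0003	0.5576349903
G0004	2.218404686
G0005	0.7570446823
G0006	0.7811083358
G0007	1.581085257
G0008	0.8954075037
G0009	0.4490851025
G0010	1.412146103
G0011	1.348086508
G0012	1.349081171
G0013	0.6972947587
G0016	0.5923232112
G0017	1.522699731
G0018	1.549704935
G0019	0.8955161934
G0020	1.00783534
G0021	0.9964018371
G0022	0.4515774113
G0023	0.9970514539
G0024	0.7430427516
G0026	0.5458205133
G0027	1.281202947
G0028	1.242530965
G0029	1.185487423
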