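gene	value
ESR1	1.010338149
G0001	0.7267137639
G0002	1.532265496
G0003	1.434331258
G0004	0.8371465306
G0005	0.510813907
G0006	0.7462746541
G0007	1.166512268
G0008	0.7671666621
G0009	1.668681219
G0010	1.196628551
G0012	0.8441960612
G0013	3.078475177
G0014	0.7996825226
G0015	1.247356076
G0017	1.251849904
G0018	0.9060007266
G0019	1.220269465
G0020	1.557053761
G0021	0.7380929574
G0022	1.29404333
G0023	1.117185157
G0024	0.4969378668
G0026	0.7247771616
G0027	0.6366682914
G0028	1.272782108
G0029	1.365189768
G0030	1.276771843
G0032	1.733865007
G0033	0.3522278577
G0034	1.782357017
G0035	0.7149076346
G0036	1.341465397
G0037	0.21230986
G0039	1.581147766
G0040	1.59876042
G0041	0.5462558123
G0042	1.217864687
G0043	0.8777629946
G0044	1.070703031
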