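gene_a	gene_b	p_value
ESR1	G0001	0.03742861808
ESR1	G0002	0.0493982838
ESR1	G0004	0.03916605965
ESR1	G0005	0.02543670795
ESR1	G0006	0.04711479423
ESR1	G0011	0.02277224315
ESR1	G0013	0.02025168052
ESR1	G0014	0.02049652998
ESR1	G0016	0.04653004016
ESR1	G0017	0.03614756815
ESR1	G0019	0.03613555395
ESR1	G0021	0.02253553437
ESR1	G0022	0.0005489291632
ESR1	G0023	0.02461796823
ESR1	G0024	0.01239068356
ESR1	G0026	0.03457852943
ESR1	G0027	0.03066293291
ESR1	G0028	0.005525504407
G0001	G0002	0.04943219542
G0001	G0003	0.01499347068
G0002	G0004	0.03029151456
G0002	G0007	0.0288258048
G0002	G0008	0.01044448834
G0002	G0012	0.01546937177
G0002	G0013	0.004886158261
G0002	G0027	0.02782378094
G0003	G0009	0.04546604537
G0004	G0010	0.0463771839
G0004	G0021	0.03416432454
G0004	G0028	0.01461895959
G0005	G0011	0.01000053581
G0005	G0016	0.02452935641
G0008	G0023	0.006938092259
G0008	G0025	0.02660431666
G0009	G0018	0.0007195609796
G0009	G0020	0.03524796741
G0009	G0029	0.0497484318
G0013	G0015	0.04105819207
G0020	G0022	0.03761678861
G0024	G0026	0.005218342356
G0008	G0021	0.6782716903
G0005	G0025	0.2263427264
G0017	G0027	0.2192335149
G0012	G0018	0.07829769468
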