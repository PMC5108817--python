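gene_a	gene_b	p_value
ESR1	G0003	0.03638164927
ESR1	G0015	0.04323653656
ESR1	G0016	0.02744380538
G0001	G0006	0.03958010176
G0001	G0007	0.007874734131
G0001	G0014	0.03992057383
G0001	G0015	0.01226097219
G0001	G0019	0.03207823612
G0002	G0003	0.04077802218
G0003	G0005	0.02834057723
G0003	G0009	0.04006160231
G0003	G0015	0.01961412564
G0004	G0010	0.00354797609
G0004	G0022	0.03789466844
G0005	G0011	0.001492882259
G0006	G0009	0.0166103499
G0006	G0016	0.01707055881
G0006	G0018	0.02189275538
G0006	G0028	0.04486638755
G0007	G0008	0.0003773695089
G0007	G0009	0.04806740316
G0007	G0011	0.0267279024
G0007	G0012	0.02909721289
G0007	G0014	0.04027493033
G0007	G0017	0.01625042697
G0007	G0022	0.02653048875
G0007	G0024	0.02028764871
G0007	G0026	0.01934406288
G0007	G0027	0.01433653523
G0008	G0014	0.002000589944
G0008	G0021	0.02272501699
G0008	G0022	0.04812016743
G0009	G0014	0.0110670837
G0009	G0015	0.04090366441
G0009	G0018	0.03990760484
G0009	G0024	0.02884604661
G0012	G0015	0.03305308073
G0012	G0024	0.0002515149065
G0013	G0014	0.04722012929
G0014	G0016	0.01263919987
G0014	G0017	0.004442193291
G0014	G0018	0.03617635999
G0014	G0019	0.01222161063
G0014	G0021	0.04901998146
G0014	G0024	0.005149086669
G0014	G0027	0.01633216485
G0014	G0028	0.004420780276
G0015	G0022	0.03958774175
G0015	G0028	0.02677311233
G0015	G0029	0.03907682242
G0016	G0023	0.03354988755
G0018	G0024	0.007950110011
G0018	G0025	0.01538482196
G0018	G0027	0.04693824224
G0022	G0024	0.00292242291
G0024	G0025	0.03705368022
G0024	G0027	0.01682600962
G0024	G0029	0.02725708816
G0025	G0028	0.02727276756
G0009	G0027	0.7917139429
G0007	G0019	0.3724108252
G0004	G0012	0.8447360922
G0011	G0018	0.1949759153
G0022	G0027	0.8793173828
G0003	G0012	0.9862198174
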