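gene_a	gene_b	p_value
ESR1	G0028	0.04676724219
G0001	G0008	0.02271151772
G0001	G0009	0.03975181663
G0001	G0029	0.007521542069
G0002	G0007	0.006670345943
G0002	G0028	0.006032758315
G0003	G0010	0.0325562337
G0003	G0022	0.00726403677
G0003	G0024	0.04652368604
G0003	G0029	0.007076362788
G0004	G0016	0.03873844842
G0004	G0029	0.04323465429
G0005	G0012	0.04184099187
G0005	G0029	0.009415792511
G0006	G0021	0.02674401176
G0007	G0015	0.007509217921
G0007	G0029	0.03524553409
G0008	G0009	0.04869255122
G0008	G0016	0.01196487704
G0008	G0026	0.0165727833
G0009	G0012	0.02980966241
G0011	G0014	0.04440141189
G0011	G0017	0.009570413651
G0011	G0024	0.04258549458
G0011	G0025	0.04797338751
G0011	G0028	0.02106841698
G0012	G0029	0.01315969041
G0013	G0017	0.01677501985
G0013	G0024	0.003335305759
G0013	G0028	0.0477351771
G0014	G0029	0.02748076863
G0019	G0024	0.009319063501
G0024	G0027	0.03155352158
G0024	G0028	0.004452392051
G0024	G0029	0.02332128881
G0027	G0028	0.01125602304
G0028	G0029	0.009337728027
G0008	G0010	0.2682389422
G0018	G0019	0.347586446
G0019	G0027	0.7386816153
G0007	G0027	0.7237686233
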