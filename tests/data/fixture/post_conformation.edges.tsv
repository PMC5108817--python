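gene_a	gene_b	p_value
ESR1	G0001	0.01576756626
ESR1	G0002	0.03374711373
ESR1	G0004	0.02736426979
ESR1	G0005	0.01571060129
ESR1	G0006	0.0366053419
ESR1	G0011	0.02279937772
ESR1	G0013	0.02388470492
ESR1	G0014	0.01404799341
ESR1	G0016	0.04977778283
ESR1	G0017	0.01552181209
ESR1	G0019	0.02447083274
ESR1	G0021	0.03190547773
ESR1	G0022	0.03083580432
ESR1	G0023	0.003488866657
ESR1	G0024	0.02333130593
ESR1	G0026	0.009162393105
ESR1	G0027	0.02154946283
ESR1	G0028	0.03751577016
ESR1	G0030	0.02605029667
ESR1	G0031	0.02485572508
ESR1	G0032	0.0266378462
ESR1	G0034	0.0479660141
ESR1	G0035	0.04576211915
ESR1	G0036	0.02897281116
ESR1	G0038	0.04616639074
ESR1	G0039	0.01416207068
ESR1	G0040	0.04320377329
ESR1	G0042	0.02557224609
ESR1	G0043	0.002109820071
ESR1	G0044	0.04301021293
G0001	G0002	0.005210694983
G0001	G0003	0.04755228083
G0001	G0039	0.002295423321
G0002	G0004	0.04076139287
G0002	G0007	0.04307557267
G0002	G0008	0.01033017311
G0002	G0012	0.02478946472
G0002	G0013	0.04809534761
G0002	G0027	0.001020396686
G0002	G0030	0.01274767946
G0002	G0033	0.005147629271
G0002	G0034	0.03083819683
G0002	G0035	0.01936372068
G0002	G0036	0.04393282116
G0002	G0037	0.04994444706
G0002	G0038	0.04942134855
G0002	G0042	0.01364806181
G0002	G0043	0.0301183011
G0003	G0009	0.04516912182
G0004	G0010	0.0141255311
G0004	G0021	0.0411251675
G0004	G0028	0.009970228488
G0004	G0031	0.0342266385
G0004	G0039	0.008855356426
G0005	G0011	0.02199433233
G0005	G0016	0.04565215478
G0005	G0031	0.02337341337
G0005	G0032	0.02745250221
G0005	G0036	0.03658138227
G0006	G0042	0.02658091433
G0008	G0023	0.01344479268
G0008	G0025	0.0495294524
G0008	G0030	0.02516168764
G0008	G0032	0.03452337813
G0008	G0033	0.03967516699
G0008	G0039	0.02756228534
G0008	G0041	0.01773385406
G0008	G0043	0.003304679092
G0009	G0018	0.04046360988
G0009	G0020	0.04329299937
G0009	G0029	0.03224463217
G0013	G0015	0.002794797524
G0014	G0040	0.02616057889
G0016	G0033	0.01157739238
G0017	G0038	0.04149057878
G0017	G0040	0.01013428943
G0020	G0022	0.03233278802
G0020	G0034	0.001246898437
G0020	G0035	0.002195005218
G0022	G0040	0.02264525315
G0024	G0026	0.008450328217
G0028	G0041	0.01089846317
G0031	G0038	0.04534386463
G0031	G0044	0.00919251816
G0032	G0037	0.04494391911
G0032	G0042	0.02673343387
G0033	G0036	0.009119953684
G0033	G0037	0.03635602164
G0033	G0044	0.00445435706
G0040	G0041	0.01016611651
G0019	G0030	0.2087584701
G0011	G0029	0.2141696015
G0012	G0013	0.06576148085
G0030	G0044	0.2923807323
G0017	G0033	0.3020223623
G0015	G0024	0.3244476958
G0002	G0020	0.4743651439
G0005	G0017	0.7969536281
G0010	G0041	0.7185470692
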