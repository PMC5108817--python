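gene_a	gene_b	p_value
ESR1	G0003	0.01877590793
ESR1	G0014	0.04817665038
ESR1	G0015	0.01132600688
ESR1	G0016	0.03623031885
ESR1	G0021	0.01084773921
ESR1	G0022	0.02317489965
ESR1	G0042	0.02813874416
G0001	G0006	0.04008983567
G0001	G0007	0.001079698809
G0001	G0008	0.04496308825
G0001	G0009	0.03922513328
G0001	G0014	0.01997245312
G0001	G0015	0.03874486192
G0001	G0018	0.03765430511
G0001	G0019	0.0316144961
G0001	G0021	0.04099024408
G0001	G0022	0.02651990476
G0001	G0027	0.03168572529
G0001	G0028	0.04929851662
G0001	G0033	0.03727735164
G0001	G0038	0.001523738262
G0002	G0003	0.03194474165
G0002	G0013	0.02899453289
G0002	G0014	0.005790812761
G0002	G0023	0.004386048472
G0002	G0026	0.02390343246
G0002	G0043	0.0218092155
G0003	G0005	0.02631908194
G0003	G0008	0.02455698565
G0003	G0009	0.01656432778
G0003	G0015	0.01456593526
G0003	G0016	0.00891762319
G0003	G0018	0.007828266872
G0003	G0022	0.008197983345
G0003	G0025	0.02866833738
G0003	G0034	0.03529413195
G0003	G0036	0.03464925399
G0004	G0007	0.02709005561
G0004	G0009	0.03813742554
G0004	G0010	0.03343156919
G0004	G0019	0.0008969991685
G0004	G0022	0.02638388364
G0004	G0024	0.003258842248
G0004	G0027	0.01925964688
G0004	G0033	0.04525783033
G0004	G0036	0.03309790684
G0004	G0038	0.04740524982
G0004	G0043	0.02270884264
G0005	G0011	0.02012299198
G0005	G0015	0.003187803673
G0005	G0040	0.001672254162
G0005	G0041	0.0311823989
G0006	G0008	0.01822140705
G0006	G0009	0.04444462846
G0006	G0016	0.04699641485
G0006	G0018	0.02918720751
G0006	G0025	0.005319361061
G0006	G0028	0.02404235918
G0007	G0008	0.03752515352
G0007	G0009	0.03583402518
G0007	G0011	0.02240162576
G0007	G0012	0.04079907533
G0007	G0014	0.04703318644
G0007	G0017	0.03025879657
G0007	G0022	0.0293013748
G0007	G0024	0.001862265877
G0007	G0025	0.01960932558
G0007	G0026	0.01120127096
G0007	G0027	0.01154222311
G0007	G0029	0.02563989405
G0007	G0032	0.02799151223
G0008	G0011	0.04811852685
G0008	G0014	0.02291268294
G0008	G0018	0.03635342451
G0008	G0021	0.03730284658
G0008	G0022	0.03580482988
G0008	G0023	0.04302716585
G0008	G0041	0.04218931859
G0009	G0014	0.03008637636
G0009	G0015	0.03611253453
G0009	G0018	0.0223961172
G0009	G0024	0.01941520089
G0009	G0027	0.03655177259
G0009	G0030	0.03061608975
G0009	G0035	0.03105197813
G0010	G0012	0.03620001598
G0010	G0032	0.0225898435
G0010	G0040	0.004721938066
G0011	G0015	0.04783504475
G0012	G0014	0.01449658338
G0012	G0015	0.0363027823
G0012	G0022	0.03725912707
G0012	G0024	0.03073599206
G0012	G0037	0.01451596949
G0012	G0044	0.01503945258
G0013	G0014	0.01340219903
G0013	G0037	0.04236406279
G0014	G0016	0.007907574148
G0014	G0017	0.02367059091
G0014	G0018	0.01046923024
G0014	G0019	0.01123954519
G0014	G0021	0.0243679007
G0014	G0022	0.01821813211
G0014	G0024	0.009016366967
G0014	G0027	0.002828216751
G0014	G0028	0.01159829823
G0014	G0038	0.03705567897
G0014	G0042	0.02024347894
G0014	G0043	0.01120977707
G0014	G0044	0.01465102573
G0015	G0018	0.0002660789712
G0015	G0022	0.003669775748
G0015	G0028	0.02081859905
G0015	G0029	0.03386702239
G0015	G0038	0.006762190479
G0015	G0039	0.0407825378
G0015	G0042	0.00809538518
G0015	G0044	0.01338039661
G0016	G0023	0.008789910215
G0016	G0025	0.01740429286
G0016	G0030	0.02734515764
G0016	G0036	0.03606091253
G0016	G0037	0.04147289513
G0016	G0039	0.03885489106
G0017	G0039	0.01822540507
G0018	G0021	0.01796630629
G0018	G0024	0.04156623551
G0018	G0025	0.03277011558
G0018	G0027	0.02297438948
G0021	G0042	0.04088799048
G0022	G0024	0.03334319436
G0022	G0025	0.02798378475
G0022	G0026	0.04772269783
G0022	G0029	0.02666798902
G0022	G0031	0.008405581227
G0022	G0037	0.02164993331
G0023	G0039	0.03272954084
G0024	G0025	0.006550247314
G0024	G0026	0.009442594431
G0024	G0027	0.03527109093
G0024	G0028	0.0194832461
G0024	G0029	0.02672638262
G0024	G0031	0.02045258518
G0024	G0032	0.03353734422
G0024	G0036	0.0408135046
G0024	G0038	0.0154661267
G0024	G0042	0.03061382889
G0025	G0027	0.03067448109
G0025	G0028	0.0320264724
G0025	G0034	0.002091650899
G0025	G0038	0.02512984223
G0025	G0039	0.009962833538
G0025	G0044	0.03407918964
G0026	G0043	0.03380635605
G0027	G0029	0.0151752846
G0027	G0032	0.0150587399
G0027	G0034	0.02271697792
G0027	G0038	0.02255481673
G0028	G0039	0.04973779924
G0029	G0031	0.03297468593
G0029	G0034	0.02081569838
G0029	G0043	0.03637226353
G0030	G0037	0.03773314793
G0030	G0044	0.03734072458
G0031	G0041	0.01060731916
G0032	G0033	0.005785560838
G0032	G0036	0.02526601342
G0033	G0034	0.04854091886
G0033	G0043	0.02340352157
G0035	G0039	0.04833744266
G0035	G0042	0.02602017409
G0036	G0038	0.01946114555
G0036	G0044	0.01746393419
G0038	G0042	0.004521998931
G0038	G0044	0.02888630208
G0039	G0040	0.03415736153
G0040	G0044	0.02388799974
G0042	G0043	0.02652275521
G0023	G0040	0.5262346473
G0034	G0035	0.5232981076
G0010	G0022	0.9939995662
G0002	G0022	0.5428539443
G0026	G0030	0.4868068297
G0012	G0030	0.3671624958
G0016	G0021	0.9177435979
G0007	G0033	0.3031136039
G0006	G0029	0.3041364322
G0005	G0024	0.4197947307
G0004	G0015	0.3056133537
G0006	G0042	0.9319959396
G0001	G0042	0.4705683161
G0001	G0012	0.2717009166
G0020	G0025	0.3386625343
G0006	G0021	0.8384107469
G0005	G0009	0.398770047
G0033	G0038	0.8212909418
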