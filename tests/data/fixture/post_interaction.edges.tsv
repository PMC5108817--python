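gene_a	gene_b	p_value
ESR1	G0010	0.02803558494
ESR1	G0011	0.02679641271
ESR1	G0028	0.02864656663
ESR1	G0035	0.04752557491
ESR1	G0041	0.003862625515
G0001	G0003	0.0466140481
G0001	G0008	0.02256001161
G0001	G0009	0.03793141949
G0001	G0024	0.0465200411
G0001	G0029	0.04399775243
G0001	G0033	0.01818614077
G0001	G0034	0.01911689057
G0001	G0042	0.02905034843
G0001	G0043	0.04165058355
G0002	G0006	0.02196843916
G0002	G0007	0.03360939589
G0002	G0028	0.005239343001
G0002	G0034	0.01464353462
G0002	G0035	0.0375395093
G0003	G0010	0.02189296254
G0003	G0012	0.01026942554
G0003	G0013	0.0009423002859
G0003	G0016	0.01831186266
G0003	G0017	0.01040391475
G0003	G0018	0.0279307103
G0003	G0022	0.03861707042
G0003	G0023	0.02933405023
G0003	G0024	0.01446744063
G0003	G0026	0.03368584879
G0003	G0028	0.04769886803
G0003	G0029	0.001732941794
G0003	G0030	0.03887452245
G0003	G0035	0.0166768219
G0003	G0044	0.02154253898
G0004	G0013	0.03107840704
G0004	G0016	0.01290465959
G0004	G0029	0.0334472308
G0005	G0012	0.006803315086
G0005	G0021	0.04820871703
G0005	G0029	0.04164798048
G0005	G0036	0.03716305871
G0005	G0040	0.01882894707
G0006	G0011	0.01549623523
G0006	G0013	0.01926598969
G0006	G0021	0.04155562994
G0006	G0024	0.01915103528
G0006	G0029	0.0360304339
G0006	G0030	0.001654251048
G0006	G0034	0.03923339638
G0006	G0035	0.02096326645
G0007	G0012	0.04523056997
G0007	G0013	0.02133184088
G0007	G0015	0.02311251734
G0007	G0018	0.001713879034
G0007	G0029	0.03131013039
G0007	G0034	0.03470200793
G0007	G0035	0.04846956453
G0008	G0009	0.0114190101
G0008	G0011	0.0466347114
G0008	G0016	0.007975148979
G0008	G0022	0.04063485135
G0008	G0025	0.04627759414
G0008	G0026	0.03847286344
G0008	G0029	0.04899121652
G0008	G0030	0.02162613001
G0009	G0012	0.01141945299
G0009	G0028	0.04844336422
G0009	G0030	0.02444371979
G0009	G0035	0.03717583861
G0010	G0016	0.04300579166
G0010	G0024	0.01500558287
G0010	G0034	0.03330993701
G0011	G0014	0.03473955158
G0011	G0016	0.002266219848
G0011	G0017	0.01803971727
G0011	G0022	0.002708877894
G0011	G0024	0.0432923256
G0011	G0025	0.006244715341
G0011	G0026	0.02893559094
G0011	G0028	0.02706209612
G0011	G0029	0.03957816456
G0011	G0035	0.01708056154
G0011	G0043	0.007414601582
G0012	G0018	0.01863649872
G0012	G0020	0.03669593744
G0012	G0028	0.03933520655
G0012	G0029	0.03285753684
G0012	G0030	0.04314402644
G0012	G0034	0.02036246277
G0012	G0040	0.02518478474
G0012	G0042	0.04301960176
G0013	G0017	0.04304315399
G0013	G0018	0.0381997992
G0013	G0020	0.02224839462
G0013	G0024	0.009295770077
G0013	G0028	0.02699619017
G0013	G0029	0.0101772823
G0013	G0044	0.0188648646
G0014	G0029	0.04394638158
G0014	G0043	0.02119320182
G0015	G0033	0.03205444521
G0015	G0035	0.01181133764
G0015	G0036	0.02564025982
G0016	G0018	0.02711829867
G0016	G0027	0.04175378054
G0016	G0029	0.03183100542
G0016	G0034	0.00718553001
G0016	G0035	0.02904457447
G0016	G0038	0.04054391759
G0016	G0040	0.04582394685
G0016	G0042	0.02968339476
G0017	G0018	0.03958313583
G0018	G0021	0.006478958036
G0018	G0025	0.02000791223
G0018	G0026	0.03044480173
G0018	G0029	0.02344034831
G0018	G0033	0.02214260478
G0018	G0035	0.02524176047
G0018	G0038	0.03403710614
G0019	G0024	0.007603683009
G0021	G0024	0.008577326394
G0021	G0029	0.003682636628
G0021	G0043	0.03837509155
G0022	G0024	0.005360064201
G0022	G0027	0.0426150463
G0022	G0029	0.03596486259
G0022	G0034	0.02898903717
G0022	G0035	0.01242540561
G0022	G0044	0.01885283157
G0024	G0026	0.04026488007
G0024	G0027	0.02840848041
G0024	G0028	0.04063869782
G0024	G0029	0.02143202918
G0024	G0030	0.01091363005
G0024	G0032	0.03547485169
G0024	G0033	0.01144612987
G0024	G0034	0.02237982946
G0024	G0035	0.005847511416
G0024	G0036	0.04686412022
G0024	G0043	0.02096299955
G0024	G0044	0.003941563085
G0025	G0029	0.0122676001
G0025	G0033	0.02102209235
G0026	G0029	0.03864365035
G0026	G0032	0.04664110143
G0026	G0044	0.02260861053
G0027	G0028	0.04214837443
G0028	G0029	0.01467193883
G0028	G0035	0.02545038883
G0028	G0044	0.02307546999
G0029	G0030	0.04080611662
G0029	G0031	0.00235815669
G0029	G0033	0.02118943684
G0029	G0034	0.03110403994
G0029	G0035	0.02391703918
G0029	G0036	0.01298153062
G0029	G0038	0.0217348039
G0029	G0039	0.01232168872
G0029	G0044	0.01669005006
G0030	G0031	0.03211229628
G0030	G0034	0.02906070432
G0031	G0038	0.03195492409
G0032	G0042	0.03958405546
G0033	G0035	0.01713873472
G0034	G0035	0.02487707104
G0034	G0038	0.02584074669
G0034	G0040	0.02573924328
G0034	G0043	0.006910133317
G0034	G0044	0.007186015244
G0035	G0037	0.04715239261
G0035	G0038	0.002326185111
G0035	G0044	0.0424462834
G0038	G0040	0.04975100634
G0040	G0044	0.01107499452
G0018	G0020	0.4462692028
G0024	G0037	0.1512982842
G0012	G0023	0.08585273838
G0007	G0017	0.9046348639
G0025	G0040	0.2281956183
G0006	G0027	0.2109519623
G0027	G0029	0.2366601181
G0014	G0027	0.2116297107
G0016	G0037	0.9645089798
G0008	G0014	0.2811176448
G0009	G0016	0.554111363
G0027	G0031	0.650562308
G0002	G0024	0.6306735685
G0036	G0042	0.08619126461
G0008	G0023	0.4946355987
G0036	G0041	0.6766131085
G0015	G0023	0.6442467514
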