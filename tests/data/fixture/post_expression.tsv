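gene	value
ESR1	1.907117797
G0001	0.8022917951
G0002	0.5580814003
G0003	0.7973655063
G0004	1.234971498
G0005	0.597121884
G0006	1.350024941
G0007	0.742419346
G0008	0.7639705097
G0009	0.4273103563
G0010	0.6935110807
G0011	0.5488034102
G0012	1.824922311
G0013	0.5079871789
G0014	0.576376568
G0016	0.978769861
G0017	0.7604456839
G0018	0.7166442284
G0019	1.410521005
G0020	0.6357851951
G0021	1.24827661
G0022	0.9955164884
G0023	0.8915099649
G0024	1.968258461
G0025	0.9293607128
G0026	1.018617308
G0027	0.72588229
G0028	0.7310201658
G0029	1.435497674
G0030	0.4603269494
G0032	0.6516711986
G0033	1.468077503
G0034	0.9824097387
G0035	1.327627585
G0036	0.7705303013
G0037	2.515890112
G0040	0.8832305604
G0041	1.41876598
G0043	0.8945041749
G0044	0.8097661085
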