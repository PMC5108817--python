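gene	value
ESR1	1.291538613
G0001	0.9126238689
G0002	2.615871005
G0003	0.8325106633
G0004	0.6185442208
G0005	1.877751155
G0006	1.301129088
G0007	0.8746977931
G0008	0.5962565036
G0010	1.303278682
G0011	2.009658791
G0012	1.162504568
G0013	1.989179831
G0014	0.613730528
G0016	2.046970136
G0017	0.8513678964
G0018	1.090916786
G0019	1.474010723
G0021	0.8629882368
G0022	2.307804389
G0023	0.9139261075
G0024	1.595557215
G0025	0.5521527001
G0026	1.239938521
G0027	1.467154754
G0028	0.386831163
G0029	1.733544935
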