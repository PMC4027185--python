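# name=SRSF1_syn alphabet=ACGT
# synthetic stand-in SR-protein position weight matrix
-1.8058	-1.1438	1.7538	-0.4324
-1.9345	-0.9012	0.4861	-1.1941
0.2675	-0.8004	1.6600	-1.5410
1.8908	-0.4188	-1.0085	-0.5841
-1.0071	-0.7199	2.0869	-0.9455
-1.4581	0.6285	1.9192	-2.7110
-1.7753	-2.3384	3.2702	-1.1247
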