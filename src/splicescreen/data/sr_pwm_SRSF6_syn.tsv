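# name=SRSF6_syn alphabet=ACGT
# synthetic stand-in SR-protein position weight matrix
1.7592	-1.1705	-2.1542	0.3567
0.2196	-2.0805	2.1376	-1.2229
1.3840	-0.8959	0.5325	-1.0142
-0.1230	-0.7035	1.3254	-0.1845
-0.0205	-1.7675	2.7455	-2.2678
1.6930	-0.4230	-1.0558	-1.9347
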