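# name=SRSF5_syn alphabet=ACGT
# synthetic stand-in SR-protein position weight matrix
0.0210	1.2769	1.4889	-1.6332
2.4854	-2.0917	-1.3753	-0.4873
-1.6026	0.3070	1.3725	-0.8993
-1.6171	-1.7121	1.8289	-0.2789
2.5421	-1.7971	-1.4461	0.4250
1.2680	-1.6825	-0.5437	-0.6241
1.9083	-1.0070	-0.1770	-3.2606
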