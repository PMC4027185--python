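# name=SRSF2_syn alphabet=ACGT
# synthetic stand-in SR-protein position weight matrix
-2.0886	0.0531	2.6245	-0.6785
1.9824	0.7399	-1.8490	-0.0476
-0.4664	-1.3838	2.2523	-1.9627
1.9445	0.2948	-1.3505	-0.2288
2.2706	-0.3758	-1.2887	-0.9076
-1.6578	-0.2751	1.8834	-0.7175
-1.5174	-0.8877	2.9022	0.3869
2.2367	-0.7221	-0.4884	-1.1206
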