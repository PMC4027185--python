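# name=fas_hex3_synthetic
# synthetic stand-in silencer hexamer set with log-odds scores
AAAATT	1.051
AATGTT	1.071
ACCTGT	2.401
AGCTTG	2.266
AGGCCA	0.997
ATCGTC	2.531
ATGCGT	2.253
ATGGGA	1.939
ATGGGT	2.786
ATTAGT	2.341
ATTTGA	0.576
ATTTTC	0.683
CAGCTT	1.185
CCATGT	2.387
CCGAGT	2.076
CGTGTG	1.214
CTGGCT	0.716
CTGTTG	1.412
CTGTTT	0.948
GAACTT	2.025
GAAGTT	2.577
GACTTA	1.969
GAGTAA	1.315
GAGTTT	1.715
GATAGG	2.456
GATGTA	1.857
GATTGG	0.531
GCGGCC	1.645
GCTAAT	2.660
GCTTTC	1.273
GGATGG	0.921
GGGTCG	1.028
GGTAGT	2.045
GGTATC	1.164
GGTGTC	2.590
GGTTAT	2.165
GGTTGT	2.550
GTAAAT	1.008
GTATTA	2.609
GTCTCG	2.101
GTGGCA	0.646
GTGGCT	0.905
GTGTGG	1.834
GTGTGT	1.182
GTGTTT	0.727
GTTAAA	2.766
GTTATA	2.813
GTTGGC	1.707
GTTTGT	0.830
GTTTTG	2.078
TAATGT	1.449
TAGGAC	1.747
TAGGGG	2.137
TAGTCG	0.947
TAGTTG	2.985
TATATA	1.136
TATATT	2.044
TATCCG	0.510
TATTTG	2.750
TATTTT	2.310
TCAAAT	0.671
TCAACT	0.609
TCCTGG	0.745
TCGAGC	2.998
TCTCTG	0.728
TGAAAT	0.625
TGGCTT	0.921
TGGTGC	0.503
TGGTTG	1.895
TGTAGT	1.636
TGTATA	1.369
TGTCTA	0.723
TGTGTT	1.644
TGTTAA	0.663
TGTTAT	1.100
TGTTTT	1.452
TTAAGA	2.080
TTACAT	2.521
TTAGTG	1.550
TTCGAG	1.007
TTCTGT	1.865
TTGACC	2.388
TTGGAC	2.289
TTGGGG	1.213
TTGGGT	2.313
TTGGTG	0.944
TTGGTT	1.833
TTGTTG	2.580
TTGTTT	1.230
TTTATA	2.617
TTTCCG	1.961
TTTCGT	1.331
TTTGCC	2.885
TTTGGA	1.718
TTTGTC	1.300
TTTTAT	2.967
TTTTGA	0.866
TTTTGG	0.896
TTTTTG	1.567
TTTTTT	2.265
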