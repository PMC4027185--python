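# name=rescue_ese_synthetic
# synthetic stand-in enhancer hexamer set (238 members)
AAAAAA
AAAACT
AAACGA
AAACGG
AAACGT
AAACTT
AAAGAA
AAAGAG
AAAGGG
AAATTC
AACAAA
AACAGC
AACAGG
AACAGT
AAGAAC
AAGAAG
AAGAAT
AAGAGC
AAGAGG
AAGCGA
AAGGAA
AAGGGG
AAGTGG
AATAGA
AATAGG
AATATT
AATGAT
AATGCG
AATGGG
AATGTG
AATTAC
AATTGC
ACAAAA
ACAGGG
ACAGTA
ACATTC
ACGAGG
ACGCGG
ACGGGA
ACGGTC
ACGGTT
ACGTGT
AGAAAA
AGAAAG
AGAAGG
AGAGAA
AGAGAG
AGAGAT
AGAGCG
AGAGCT
AGAGGT
AGAGTT
AGCAGA
AGCAGT
AGCCGA
AGCGAG
AGGAAA
AGGGAC
AGGGGA
AGGGGG
AGGGGT
AGGGTG
AGGTAT
AGGTGA
AGGTGG
AGTAAT
AGTATA
AGTATT
AGTCGG
AGTGGC
AGTTTG
ATAAAG
ATAAGA
ATACAA
ATACAC
ATACGA
ATATAA
ATATTA
ATGGAA
ATGGAG
ATGGGG
ATGTGT
ATGTTA
ATTAAG
ATTCCA
ATTGGC
ATTTAG
ATTTTA
CAAATA
CAACGT
CAAGCA
CAAGGA
CAAGTG
CAATAT
CAATGA
CAGAGT
CAGATG
CAGGTA
CAGTAC
CAGTAG
CAGTTC
CATGGA
CCAAGG
CCAGGA
CCGACG
CCGGTG
CGAGGA
CGAGTG
CGCGGA
CGCGGC
CGCGGG
CGGAGG
CGGATC
CGGCGA
CGGGCG
CGGTTG
CGTAGA
CGTCGA
CTAAGA
CTAAGG
CTACTG
CTAGAA
CTCCAA
CTGCAT
CTGTAT
CTGTCC
CTTAGA
CTTCAC
GAAAAT
GAACAA
GAACTG
GAAGAA
GAATCG
GACAGG
GACGAT
GACGGC
GACGGT
GACTAT
GAGAAA
GAGAAC
GAGAAT
GAGAGT
GAGGAA
GAGGCA
GAGGTG
GAGTGG
GATAGA
GATGAT
GATGCT
GATTGA
GCAAAA
GCAAAT
GCAATA
GCACGA
GCAGCA
GCGAAG
GCGATG
GCGTGA
GGAAAC
GGAACG
GGAAGA
GGAAGG
GGAGAA
GGAGAG
GGAGGC
GGATTG
GGCAAG
GGCAGA
GGCGTA
GGGAGA
GGGAGC
GGGAGG
GGGAGT
GGGATA
GGGATG
GGGGGA
GGGTGA
GGTAAT
GGTATG
GGTCAT
GGTGGA
GGTGGG
GGTTGG
GGTTTA
GTACCT
GTACTT
GTGGAG
GTGGCC
GTGGGA
GTGGGG
GTTGCG
GTTGTG
TAAACG
TAAAGT
TAAATA
TAACAC
TAAGAG
TAAGGA
TAAGTC
TAATCA
TAATGG
TAATTA
TACGTA
TAGAAG
TAGAGA
TAGATC
TAGGGA
TAGTGG
TATAAA
TATATG
TATGAA
TATGTG
TCAAAG
TCATTT
TCGCGT
TCGGGA
TGAAGA
TGAAGG
TGACGA
TGAGTT
TGCAGG
TGCTAC
TGGACG
TGGAGA
TGGATA
TGGCTG
TGGGGG
TGGTAA
TGGTGT
TGTAAC
TGTACG
TGTGGA
TTAACT
TTAGAC
TTCTAC
TTGGCA
TTGTGC
TTTAGG
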