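panel,marker,dye,forward_primer,reverse_primer,allele_no,size_min,size_max,he,ho,pic
1,Brz0182,NED,ACGTTATTGGACTTGGGTGA,AGCCTGACCAAATTCTTGTG,10,252,328,0.823,0.545,0.868
1,Brz0097,HEX,TAATTTGTTCCACCCACAGG,GTGACAGAGTTCGGGAGCTA,5,234,242,0.705,0.375,0.747
2,Brz0075,6-FAM,GAAGCTGCAAAGGCTGAGT,GGAGGAGAGAGAAGAGCAAGA,8,129,153,0.809,0.727,0.839
2,Brz0148,6-FAM,GCTCTTGACCTTGACGATGT,TGCACTTGAGAGAGACGAAA,8,248,274,0.787,0.909,0.800
2,Brz0083,HEX,CATGATATTTGCCTGTCAAGG,AGCACCGGTGATGTGAATA,6,233,249,0.765,0.778,0.788
3,Brz0017,HEX,TTCCATTTATTTGCCTGTTCA,ATTTTCCCTATCCGACCTTTC,11,134,160,0.840,1.000,0.864
3,Brz0116,HEX,TCAAGAAATGGACTCCCAAA,TCTAGGTCATGCAAGCCATT,9,223,271,0.803,0.900,0.827
3,Brz0047,6-FAM,TGTGAGACATAAACCATTGGAA,AATGGGTGCTGGAAATGTAAC,7,150,170,0.731,0.556,0.762
4,Brz0021,HEX,CAGCTGAAAGTTCCCAAAAAT,CTGAATGATAAAGGGTGCAAA,9,151,183,0.770,0.400,0.816
4,Brz0087,NED,TTCCCCCACTACTCATCTCA,AACAGCACACCGTAGCAAGT,6,239,273,0.716,1.000,0.748
5,Brz0065,6-FAM,AGCTAAGCAAATTTCAAGAACG,TAATGTGGAACATTGCCCTAA,12,130,166,0.829,0.700,0.875
5,Brz0130,6-FAM,TCCTTTCATGAACCCCTGTA,CATCGCACGCTTATATGACA,9,242,266,0.820,0.636,0.858
5,Brz0131,HEX,TGCAATGACATTAAATCAACC,GCTGCAACACAAACAAAATAA,6,254,264,0.712,0.714,0.744
6,Brz0147,HEX,CTGAGGACGCTCCTACTGAA,TTGATTTCAACACCCCAACT,10,240,288,0.825,0.700,0.868
6,Brz0031,6-FAM,CCCCCATTTAACACCATAGTT,GCTCAAAATGCAATGTACGTG,7,144,156,0.770,0.667,0.804
7,Brz0177,6-FAM,TGGAGTTGAGGCTTTAGGAA,GTGTTTGGAAACCACTTGCT,6,291,319,0.725,0.125,0.795
7,Brz0107,6-FAM,AGAGGAATTGACTTGGAAAAA,GCATGCACGTAAATTTTCACT,6,227,247,0.747,0.444,0.788
7,Brz0004,6-FAM,TTGTTGTGGTACACCGGTACT,CAAAACCTGAATCACCATGTC,6,113,155,0.703,0.222,0.745
8,Brz0118,NED,AGGAGGTCCAAATCACCAAT,CGTCAGCAATTCGTACCAC,10,237,263,0.812,0.636,0.849
8,Brz0219,HEX,GCAGTTCTTGCTTTTTCAGG,TCTCCTTATGCAAGGCTTC,6,294,304,0.768,0.818,0.778
8,Brz0156,6-FAM,GCCATGATGTTTCATTGGTT,TTTTGCACCTTTCATTGCTT,7,239,265,0.752,0.636,0.770
9,Brz0142,6-FAM,GCTGGGTTATGCTAATGCAA,TCAAGCATGAACATTGAAACA,10,241,287,0.823,0.875,0.871
9,Brz0180,HEX,CACACGGTCCATCTTGATTT,TCCATAATGCATTGTCTTGAAA,7,285,305,0.751,0.091,0.800
9,Brz0089,NED,CAAACCTATTCCACGGTCAA,TGGACAATGCTATTCAAACG,7,224,248,0.710,0.571,0.759
10,Brz0048,HEX,GAATCTAAGCAGCGGATCAAT,TCACAAGAAGGTCCTCACAAG,9,139,161,0.813,0.818,0.839
10,Brz0206,NED,GAAGTGGCAAGACACACACA,TGAGCTTTTCGTCTCTCCTG,7,278,302,0.757,0.600,0.783
10,Brz0038,6-FAM,CTGAAAATAAGAGCCGTCCAT,ATAAGGTGAGCCACAACTGAG,6,140,154,0.772,0.909,0.778
11,Brz0171,6-FAM,TTGTCTCACTTGTGCACTCC,GCTAGCAGGTAGCAAGATGG,7,312,348,0.725,0.250,0.787
11,Brz0015,6-FAM,AATAGAAAACGTGAGCCCATT,TCCACCAATATGATTCAAACG,6,144,156,0.764,0.636,0.783
11,Brz0152,NED,ATGCTGCACTTACTGGTTCA,GGCTATCAATTCGAAGACCA,6,228,248,0.748,0.667,0.774
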