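# Seed-site counts in a genome-wide corpus of experimentally verified human
# miRNA-gene interactions (655 miRNAs), with the mean count over 50
# mononucleotide shuffles of the same region sequences.  Background means are
# given to the precision they were published at (integers).
seed_type	region	observed	background_mean
2t8A1	promoter	1235	911
2t8	promoter	3105	2639
2t7A1	promoter	2657	2422
2t7	promoter	7296	7014
1t8GU	promoter	3734	3068
2t8A1	5utr	171	141
2t8	5utr	628	489
2t7A1	5utr	463	391
2t7	5utr	1594	1415
1t8GU	5utr	730	547
2t8A1	cds	1153	904
2t8	cds	3116	2331
2t7A1	cds	2729	2331
2t7	cds	6494	5997
1t8GU	cds	3343	2655
2t8A1	3utr	2366	1069
2t8	3utr	4103	2593
2t7A1	3utr	3204	2513
2t7	3utr	6920	6060
1t8GU	3utr	3797	3175
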