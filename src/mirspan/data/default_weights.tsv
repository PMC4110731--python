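# Default seed-site weight table, derived from a genome-wide corpus of
# experimentally verified human miRNA-gene interactions versus a
# 50-replicate mononucleotide-shuffle background.  Reference cell
# (weight 1): 2t8A1 sites in 3'UTRs.  Usable without building a corpus.
seed_type	region	snr	weight
2t8A1	promoter	1.355	0.293
2t8	promoter	1.177	0.146
2t7A1	promoter	1.097	0.080
2t7	promoter	1.040	0.033
1t8GU	promoter	1.217	0.179
2t8A1	5utr	1.213	0.176
2t8	5utr	1.284	0.234
2t7A1	5utr	1.184	0.151
2t7	5utr	1.126	0.104
1t8GU	5utr	1.333	0.275
2t8A1	cds	1.275	0.227
2t8	cds	1.337	0.277
2t7A1	cds	1.171	0.141
2t7	cds	1.083	0.068
1t8GU	cds	1.259	0.214
2t8A1	3utr	2.214	1.000
2t8	3utr	1.583	0.480
2t7A1	3utr	1.275	0.227
2t7	3utr	1.142	0.117
1t8GU	3utr	1.196	0.161
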