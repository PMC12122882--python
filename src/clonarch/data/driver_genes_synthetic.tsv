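symbol	role	chrom	start	end	hotspot_codons	regulatory_start	regulatory_end
CTNNB1	oncogene	3	41000000	41050000	33,37,41,45
MYCN	oncogene	2	16000000	16010000	44
FOXR2	oncogene	8	55000000	55005000		54950000	55000000
TERT	oncogene	5	1250000	1300000		1295000	1296000
TP53	recessive	17	7570000	7590000
REST	recessive	4	57770000	57800000
WT1	recessive	11	32400000	32460000
AMER1	recessive	12	63400000	63430000
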