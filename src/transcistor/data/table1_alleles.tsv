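# Published allele-frequency table for exon 2 of ovine DRB1 in 109 Scottish
# Blackface rams (218 chromosomes). frequency_percent as printed, 1 decimal.
allele_accession	frequency_percent	number	ipd_name
Y10248	23.1	01	DRB1*0101
AB017204	18.1	02	0901
U00216	10.2	03	0501
AB017218	6.5	04	1201
AB017230	5.1	05	0302
AF036561	4.6	06	0308
U00206	4.2	07	0102
AB061323	3.7	08	0301
AF036562	2.3	09	0304
AB017206	2.3	10	1101
FJ213447	2.3	11	0802
Y10245	1.9	12	2201
AF126441	1.4	13	N/A
AB017210	1.4	14	N/A
AB017228	1.4	15	N/A
U00212	0.9	16	N/A
FJ213448	0.9	17	1002
Z92728	0.9	18	N/A
Z92726	0.9	19	N/A
U00219	0.9	20	N/A
AB061372	0.9	21	0801
AB017212	0.9	22	1301
U00235	0.5	23	N/A
U00215	0.5	24	N/A
U00209	0.5	25	N/A
U00204	0.5	26	N/A
AY227049	0.5	27	1401
AF126434	0.5	28	N/A
AF036560	0.5	29	N/A
AB017226	0.5	30	1601
AB017216	0.5	31	N/A
AB017214	0.5	32	0402
AB017211	0.5	33	N/A
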