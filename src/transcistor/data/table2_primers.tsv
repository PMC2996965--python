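# Published allele-specific primer panel for ovine DRB1 exon 2, transcribed
# as printed (bold markup dropped; the allele-discrimination set is the label
# suffix). Coordinates are 1-based inclusive in the reference alignment;
# reverse primers are written 5'->3' with descending coordinates. Three rows
# (F4, F5, "F6 a/t") print a 19-position span for an 18-mer; load with
# coord_policy="anchor3" to repair from the 3' terminus.
label	orientation	sequence	ref_start	ref_end
F1 c/t	forward	GARMGAGTGTCRTTTCTY	13	30
F2 c/t	forward	GAGTGTCRTTTCTYAAAY	17	34
F3 g/c	forward	TTTCTYAAAYGGGACS	25	40
F4 ac	forward	GGACSGAGAGGGTGCGGC	35	53
F5 ct	forward	GGACSGAGCGGGTGCGGT	35	53
F6 a/t	forward	GACSGAGMGGGTGCGGYW	36	54
F6 a/c	forward	GGGTGCGGYWSCTGGAM	45	61
F7 a/t/c	forward	CTGGAMAGATACTWCH	56	71
F8 a/t	forward	HMTAAYGGAGAAGAGW	71	86
F9 a/t/c	forward	HMTAAYGGAGAAGAGWH	71	87
F10 a/g	forward	GACTGGGGCGAGTWYCGR	104	121
F11 g/c	forward	TGGAACAGCCAGAAGGGAS	158	176
R1 g/a/t	reverse	CTTCTGGCTGTTCCAD	172	157
R2 a/g	reverse	CTTCTGGCTGTTCCADTR	172	155
R3 c/t	reverse	CTGGCTGTTCCADTRCTY	169	152
R4 ct	reverse	CTGTTCCADTRGTYRGCKCT	165	146
R5 tc	reverse	CTGTTCCADTRGTYRGCKTC	165	146
R6 g/a/c	reverse	CTGCAGTACGTGTCCACV	216	199
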