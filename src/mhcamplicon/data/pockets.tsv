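# Binding-pocket residue masks (1-based amino-acid positions within the
# translated exon-2 peptide). Editable config: positions are placeholders
# consistent with the published pocket composition by count (15 aa over
# DQA pockets P1/P6/P9; 19 aa over DQB pockets P1/P4/P6/P7/P9) and are
# validated against those totals at load.
locus	pocket	position
DQA	P1	9
DQA	P1	24
DQA	P1	31
DQA	P1	32
DQA	P1	43
DQA	P1	52
DQA	P1	62
DQA	P6	11
DQA	P6	65
DQA	P6	66
DQA	P6	68
DQA	P6	69
DQA	P9	72
DQA	P9	73
DQA	P9	76
DQB	P1	83
DQB	P1	84
DQB	P1	85
DQB	P1	86
DQB	P1	87
DQB	P4	13
DQB	P4	26
DQB	P4	70
DQB	P4	71
DQB	P4	74
DQB	P4	78
DQB	P6	9
DQB	P6	11
DQB	P6	30
DQB	P7	28
DQB	P7	47
DQB	P7	61
DQB	P9	37
DQB	P9	57
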