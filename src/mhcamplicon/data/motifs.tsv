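# Proximal-promoter regulatory motif consensi. These are editable data,
# seeded from model-species MHC class II promoter literature; windows count
# bp upstream of the transcription start (the 3' end of the scanned
# sequence). max_mm is the Hamming mismatch tolerance.
locus	motif	consensus	window_start	window_end	max_mm
ALL	W	TTCCCCTAGCAACAG	95	145	2
ALL	X1	CCTAGCAACAGATG	70	120	2
ALL	X2	TGCGTCATCTCAA	60	105	2
ALL	Y	CTGATTGGCCAA	40	90	2
DQA	T	TCTTGATTCTGTCT	0	200	2
DQA	NFKB	GGGACTTTCC	120	200	2
DQA	W2	TTCCCCTAGCAACAG	140	200	2
DQB	TTAA	CTTTAAGGTTGA	10	60	2
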