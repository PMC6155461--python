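locus	allele	ATL	ML	NIRL	SIRL
DQAP	Tutr-DQAP1*01	4	6	0	0
DQAP	Tutr-DQAP1*02	12	5	2	14
DQAP	Tutr-DQAP1*03	2	0	2	2
DQAP	Tutr-DQAP1*04	3	2	1	0
DQAP	Tutr-DQAP1*05	1	0	0	0
DQAP	Tutr-DQAP1*06	18	23	29	44
DQAE	Tutr-DQA1*01	7	16	15	27
DQAE	Tutr-DQA1*02	10	15	18	27
DQAE	Tutr-DQA1*03	2	1	2	2
DQAE	Tutr-DQA1*04	8	2	0	4
DQAE	Tutr-DQA1*05	5	2	1	0
DQAE	Tutr-DQA1*06	2	0	0	0
DQAE	Tutr-DQA1*07	1	1	0	0
DQAE	Tutr-DQA1*08	7	7	0	0
DQAE	Tutr-DQA1*09	1	0	0	0
DQAE	Tutr-DQA1*10	1	0	0	0
DQBP	Tutr-DQBP*01	3	4	6	6
DQBP	Tutr-DQBP*02	6	15	17	26
DQBP	Tutr-DQBP*03	1	2	3	14
DQBP	Tutr-DQBP*04	1	0	0	0
DQBP	Tutr-DQBP*05	15	12	4	4
DQBP	Tutr-DQBP*06	17	4	0	6
DQBP	Tutr-DQBP*07	1	1	0	0
DQBE	Tutr-DQB1*01	6	2	0	4
DQBE	Tutr-DQB1*02	0	1	0	0
DQBE	Tutr-DQB1*03	2	0	0	0
DQBE	Tutr-DQB1*04	3	11	16	26
DQBE	Tutr-DQB1*05	1	0	0	0
DQBE	Tutr-DQB1*06	5	2	1	0
DQBE	Tutr-DQB1*07	6	6	0	0
DQBE	Tutr-DQB1*08	1	2	2	10
DQBE	Tutr-DQB1*09	2	1	2	2
DQBE	Tutr-DQB1*10	4	11	13	16
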