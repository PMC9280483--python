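name	position	anchor	anchor_cr	repeat_length
Bat25	chr4:55598012-55598436	TTTGA(T+)GAGAA	TTCTC(A+)TCAAA	25
Bat26	chr2:47641360-47641786	CAGGT(A+)GGGTT	AACCC(T+)ACCTG	27
Mono27	chr2:39536490-39536916	CAGGA(T+)GAGGC	GCCTC(A+)TCCTG	27
NR21	chr14:23652147-23652567	TTGCT(A+)GGCCA	TGGCC(T+)AGCAA	21
NR24	chr2:95849162-95849585	TCCTA(T+)GTGAG	CTCAC(A+)TAGGA	23
NR27	chr11:102193309-102193734	CTGGT(A+)GCCAC	GTGGC(T+)ACCAG	26
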