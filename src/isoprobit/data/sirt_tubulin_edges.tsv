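# Curated causal interaction network linking SIRT1 and SIRT3 with tubulin
# (SIGNOR-style edge semantics: up / down / physical / unknown).
# Columns: source<TAB>effect<TAB>target
SIRT1	up	AKT
AKT	up	S1PR1
AKT	unknown	LTB4R2
S1PR1	up	GNAI1
S1PR1	up	GNAO1
LTB4R2	up	GNAI1
GNAI1	up	Tubulin
GNAO1	up	Tubulin
SIRT3	down	PDHA1
PDHA1	physical	PDH
PDH	up	Acetyl-CoA
Acetyl-CoA	up	Hexadecanoic acid
Acetyl-CoA	up	Malonyl-CoA
Malonyl-CoA	up	Hexadecanoic acid
Hexadecanoic acid	up	FFAR1
FFAR1	up	GNAI1
FFAR1	up	GNAO1
SIRT3	up	CYP11A1
CYP11A1	up	Pregnenolone
Pregnenolone	up	17α-Hydroxypregnenolone
Pregnenolone	up	Progesterone
17α-Hydroxypregnenolone	up	Dehydroepiandrosterone
Progesterone	up	11-Deoxycorticosterone
Dehydroepiandrosterone	up	NR3C1
11-Deoxycorticosterone	up	NR3C1
NR3C1	up	CEBPA
NR3C1	up	CEBPB
CEBPA	up	S100A9
CEBPB	up	S100A9
S100A9	up	Tubulin
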