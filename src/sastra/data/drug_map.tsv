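target	drug	notes
EGFR	erlotinib	EGFR tyrosine-kinase inhibitor
EGFR	lapatinib	dual EGFR/HER2 inhibitor
EGFR_pY1068	erlotinib	phospho-EGFR targeted via EGFR inhibition
HER2	lapatinib	dual EGFR/HER2 inhibitor
S6K	LY2584702	p70 S6 kinase inhibitor
pS6	LY2584702	S6 phosphorylation blocked via S6K inhibition
ACC	TOFA	acetyl-CoA carboxylase inhibitor
ACC_pS79	TOFA	phospho-ACC targeted via ACC inhibition
cMet	crizotinib	cMet inhibitor
PD-1	pembrolizumab	anti-PD-1 antibody
Src_pY416	dasatinib	Src-family kinase inhibitor
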