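# rtphylo group signature table, v1 — one row per controlled-vocabulary label
# patterns: semicolon-separated "spec@region" motif requirements
# active_site_variants: allowed catalytic tetrads (empty = not checked)
# absent_domains: domains expected missing (corroboration only)
group	patterns	active_site_variants	absent_domains
group_II
GII-A
GII-B
GII-C
GII-D
GII-E
GII-F
GII-CL
GII-ML
GII-g1
GII-g2
GII-g3
GII-g4
GII-g5
GII-g6
retron	VTG@region_Y;NAxxH@region_X
DGR	[IVL]Gx(3)SQ@4	YVDD,YMDD
Abi		YRDD,YVDD	0,2a,7
AbiK		YRDD,YVDD	0,2a,7
Abi-P2		YRDD,YVDD	0,2a,7
UN1
UN2
UN3
UN4
UN5
UG1
UG7
UG8
UG9
CRISPR-RT		YADD,FADD
CRISPR-RT1		YADD,FADD
CRISPR-RT2		YADD,FADD
CRISPR-RT3		YADD,FADD
CRISPR-RT4		YADD,FADD
CRISPR-RT5		YADD,FADD
CRISPR-RT6		YADD,FADD
CRISPR-RT7		YADD,FADD
G2L4		YIDD
UG2
UG3
UG4
UG5
UG6
UG10		YVDD
UG11
UNC
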